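"""Co-occurring hashtag tables with space-relative stem exclusion.

Within a space, a tweet's eligible co-tags are its normalized hashtags
minus the space's own synonym family, minus any tag sharing a word stem
with that family (prefix match, e.g. ``gluten*`` inside the gluten-free
space), minus listed abbreviations (``gf``).  Exclusion is space-relative:
``celiac`` is a perfectly good co-tag of the gluten-free space and vice
versa.

The reported percentage is conditional: of the group's tweets that carry
at least one eligible co-tag, the share carrying the given tag.  Column
sums are unconstrained (tags co-occur).
"""

from __future__ import annotations

import pandas as pd

from .activity_groups import GROUP_ORDER, ActivityPartition
from .affinity_spaces import AffinitySpace, AffinitySpaceSpec, normalized_tags
from .corpus_model import TweetRecord
from .errors import UndefinedMetricError

__all__ = ["eligible_cotags", "cooccurrence_table"]


def eligible_cotags(tweet: TweetRecord, spec: AffinitySpaceSpec) -> set[str]:
    """Normalized co-occurring tags of a tweet, after the space's exclusions."""
    stems = tuple(spec.exclusion_stems)
    out = set()
    for tag in normalized_tags(tweet):
        if tag in spec.synonym_tags or tag in spec.excluded_abbreviations:
            continue
        if stems and tag.startswith(stems):
            continue
        out.add(tag)
    return out


def cooccurrence_table(
    space: AffinitySpace,
    partition: ActivityPartition,
    spec: AffinitySpaceSpec | None = None,
    top_n: int = 15,
    denominator: str = "cotagged",
) -> dict[str, pd.DataFrame]:
    """Per-group ranked table of co-tag conditional percentages.

    For each activity group, the denominator is the number of the group's
    tweets with at least one eligible co-tag (``denominator="cotagged"``,
    the primary definition) or the group's full tweet count
    (``denominator="all"``, for sensitivity analysis).  Each tag's percent
    is the share of denominator tweets whose eligible co-tag set contains
    it, to 1 decimal; rows are ranked by percent descending, ties
    alphabetical, truncated to ``top_n``.

    Raises :class:`UndefinedMetricError` for a group with tweets but a zero
    denominator; groups with no tweets at all yield an empty table.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if denominator not in ("cotagged", "all"):
        raise ValueError("denominator must be 'cotagged' or 'all'")
    spec = spec or space.spec
    out: dict[str, pd.DataFrame] = {}
    for group in GROUP_ORDER:
        members = partition.members(group)
        tweets = [t for t in space.tweets if t.author_id in members]
        cotag_sets = [s for t in tweets if (s := eligible_cotags(t, spec))]
        denom = len(cotag_sets) if denominator == "cotagged" else len(tweets)
        if denom == 0:
            if not tweets:
                out[group] = pd.DataFrame(columns=["hashtag", "pct"])
                continue
            raise UndefinedMetricError(
                f"group {group!r} has no tweets with eligible co-tags"
            )
        counts: dict[str, int] = {}
        for s in cotag_sets:
            for tag in s:
                counts[tag] = counts.get(tag, 0) + 1
        rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        out[group] = pd.DataFrame(
            [(tag, round(100.0 * c / denom, 1)) for tag, c in rows],
            columns=["hashtag", "pct"],
        )
    return out
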