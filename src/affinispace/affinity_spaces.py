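"""Hashtag normalization, affinity-space construction, overlap and volume.

An affinity space is the set of original posts carrying any tag from a
configured synonym family (e.g. ``#glutenfree``, ``#gluten-free``,
``#glutenfreediet`` all mark the gluten-free space).  Tags are compared
case-insensitively with hyphens and underscores removed, so every spelling
of a synonym collapses to one key.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timezone

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from .corpus_model import Corpus, TweetRecord, UserRecord
from .errors import OutOfWindowError, TagRejectedError, UndefinedMetricError

__all__ = [
    "normalize_tag",
    "normalized_tags",
    "AffinitySpaceSpec",
    "AffinitySpace",
    "OverlapReport",
    "build_space",
    "cross_overlap",
    "tweets_per_day",
    "GLUTENFREE_SPEC",
    "CELIAC_SPEC",
]


def normalize_tag(raw: str) -> str:
    """Canonical form of a hashtag: lowercase, no leading ``#``, ``-``/``_`` removed.

    ``"#Gluten_Free"``, ``"#gluten-free"`` and ``"glutenfree"`` all map to
    ``"glutenfree"``.  Raises :class:`TagRejectedError` if nothing remains.
    """
    s = raw.strip().lstrip("#").lower().replace("-", "").replace("_", "")
    if not s:
        raise TagRejectedError(f"tag {raw!r} is empty after normalization")
    return s


def normalized_tags(tweet: TweetRecord) -> set[str]:
    """The tweet's hashtags as a normalized set; empty-normalizing tags dropped."""
    out: set[str] = set()
    for raw in tweet.hashtags:
        try:
            out.add(normalize_tag(raw))
        except TagRejectedError:
            continue
    return out


class AffinitySpaceSpec(BaseModel):
    """Definition of one space: label, synonym family, co-tag exclusions.

    ``exclusion_stems`` and ``excluded_abbreviations`` feed the
    co-occurrence analysis: any co-tag sharing a stem with the space's own
    tag family (or listed as a known abbreviation of it, such as ``gf``) is
    not counted as a co-occurring topic.
    """

    model_config = ConfigDict(frozen=True)

    label: str
    synonym_tags: frozenset[str]
    exclusion_stems: tuple[str, ...] = ()
    excluded_abbreviations: frozenset[str] = frozenset()

    @field_validator("synonym_tags", mode="before")
    @classmethod
    def _normalize_synonyms(cls, v):
        tags = frozenset(normalize_tag(t) for t in v)
        if not tags:
            raise ValueError("synonym_tags must be non-empty")
        return tags

    @field_validator("exclusion_stems", mode="before")
    @classmethod
    def _lower_stems(cls, v):
        return tuple(s.lower() for s in v)

    @field_validator("excluded_abbreviations", mode="before")
    @classmethod
    def _normalize_abbrevs(cls, v):
        return frozenset(normalize_tag(t) for t in v)


#: Bundled default space definitions for the two celiac-disease /
#: gluten-free-diet communities the package ships as its demo subject.
GLUTENFREE_SPEC = AffinitySpaceSpec(
    label="glutenfree",
    synonym_tags=["glutenfree", "gluten-free", "glutenfreediet", "gluten_free"],
    exclusion_stems=("gluten",),
    excluded_abbreviations=["gf"],
)

CELIAC_SPEC = AffinitySpaceSpec(
    label="celiac",
    synonym_tags=[
        "celiac",
        "celiacdisease",
        "celiacs",
        "celiacsdisease",
        "coeliac",
        "coeliacdisease",
    ],
    exclusion_stems=("celiac", "coeliac"),
)


@dataclass(frozen=True)
class AffinitySpace:
    """The tweets of one space plus its posting users (with profiles)."""

    spec: AffinitySpaceSpec
    tweets: tuple[TweetRecord, ...]
    posting_users: frozenset[str]
    users: dict[str, UserRecord]

    def __len__(self) -> int:
        return len(self.tweets)


def build_space(corpus: Corpus, spec: AffinitySpaceSpec) -> AffinitySpace:
    """Select the corpus tweets whose normalized tag set meets the synonym family.

    The corpus is expected to be pre-filtered to original posts.
    """
    selected = tuple(
        t for t in corpus.tweets if normalized_tags(t) & spec.synonym_tags
    )
    posters = frozenset(t.author_id for t in selected)
    return AffinitySpace(
        spec=spec,
        tweets=selected,
        posting_users=posters,
        users={uid: corpus.users_by_id[uid] for uid in posters},
    )


@dataclass(frozen=True)
class OverlapReport:
    """Cross-listing between two spaces, as percentages of the first space."""

    tweet_pct: float
    user_pct: float


def cross_overlap(a: AffinitySpace, b: AffinitySpace) -> OverlapReport:
    """Share of ``a``'s tweets (and posting users) also belonging to ``b``.

    Both spaces must come from the same corpus so tweet ids are comparable.
    Percentages are reported to 1 decimal.
    """
    if not a.tweets:
        raise UndefinedMetricError(f"space {a.spec.label!r} is empty")
    b_ids = {t.tweet_id for t in b.tweets}
    shared_tweets = sum(1 for t in a.tweets if t.tweet_id in b_ids)
    shared_users = len(a.posting_users & b.posting_users)
    return OverlapReport(
        tweet_pct=round(100.0 * shared_tweets / len(a.tweets), 1),
        user_pct=round(100.0 * shared_users / len(a.posting_users), 1),
    )


def tweets_per_day(
    space: AffinitySpace, window_start: date, window_end: date
) -> tuple[float, float]:
    """Mean and sample SD of daily post counts over an inclusive date window.

    Every calendar day in the window contributes, including days with zero
    posts.  A tweet dated outside the window raises
    :class:`OutOfWindowError`.  Returns ``(mean, sd)`` at full precision
    (reports render 1 decimal); the SD is 0.0 for a one-day window.
    """
    if window_start > window_end:
        raise ValueError("window_start must be on or before window_end")
    days = pd.date_range(window_start, window_end, freq="D").date
    dates = [t.created_at.astimezone(timezone.utc).date() for t in space.tweets]
    outside = [d for d in dates if d < window_start or d > window_end]
    if outside:
        raise OutOfWindowError(
            f"{len(outside)} tweet(s) dated outside "
            f"[{window_start}, {window_end}], e.g. {outside[0]}"
        )
    counts = pd.Series(dates).value_counts().reindex(days, fill_value=0)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    return mean, sd
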