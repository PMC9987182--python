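"""Biography keyword extraction and the self-descriptor frequency tables.

Profile biographies are split into lowercase tokens on non-alphanumeric
boundaries, stop words are dropped, and each account contributes its
*distinct* token set — "mom mom mom" identifies one mom.  Frequency tables
count accounts per keyword within each activity group.  Targeted searches
cover medical-expertise terms, terminal degrees and family-role words, plus
a prefix-stem co-mention check (e.g. how often "doctor" bios also mention a
naturopath-/homeopath- word).
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .affinity_spaces import AffinitySpace
from .activity_groups import GROUP_ORDER, ActivityPartition
from .errors import UndefinedMetricError

__all__ = [
    "STOP_WORDS",
    "KeywordLexicon",
    "default_lexicon",
    "tokenize_bio",
    "keyword_table",
    "pct_tweets_by_keyword_users",
    "name_field_search",
    "stem_comention",
]

# A compact standard English stop-word list (function words only; no domain
# terms), sufficient for profile-biography token filtering.
STOP_WORDS: frozenset[str] = frozenset(
    """
    a about above after again against all am an and any are aren as at be
    because been before being below between both but by can cannot could
    did do does doing down during each few for from further had has have
    having he her here hers herself him himself his how i if in into is it
    its itself just me more most my myself no nor not now of off on once
    only or other our ours ourselves out over own same she should so some
    such than that the their theirs them themselves then there these they
    this those through to too under until up very was we were what when
    where which while who whom why will with you your yours yourself
    yourselves
    """.split()
)

# Self-descriptor vocabulary bundled as the default curated lexicon: the
# role words the bundled demo communities actually use in their profiles.
_CURATED_SELF_DESCRIPTORS = frozenset(
    """
    advocate artist author blogger chef coach creator dad dietitian doctor
    editor enthusiast fan father foodie founder host husband lover md mom
    mother mum owner phd photographer physician student teacher vegan wife
    writer
    """.split()
)

_TOKEN_SPLIT_RE = re.compile(r"[^0-9a-z]+")


class KeywordLexicon(BaseModel):
    """Stop words, curated self-descriptors, targeted term sets and stems.

    ``targeted_sets`` names groups of search terms (medical expertise,
    degree, family roles); ``stem_sets`` names lowercase prefixes used for
    co-mention analysis.  All entries are lowercase; stop words may not
    overlap the targeted sets.
    """

    model_config = ConfigDict(frozen=True)

    stop_words: frozenset[str] = STOP_WORDS
    curated: frozenset[str] = _CURATED_SELF_DESCRIPTORS
    targeted_sets: Mapping[str, frozenset[str]] = {}
    stem_sets: Mapping[str, frozenset[str]] = {}

    @field_validator("stop_words", "curated", mode="before")
    @classmethod
    def _lower_set(cls, v):
        return frozenset(w.lower() for w in v)

    @field_validator("targeted_sets", "stem_sets", mode="before")
    @classmethod
    def _lower_sets(cls, v):
        return {k: frozenset(w.lower() for w in ws) for k, ws in dict(v).items()}

    @model_validator(mode="after")
    def _disjoint(self):
        for name, terms in self.targeted_sets.items():
            clash = terms & self.stop_words
            if clash:
                raise ValueError(
                    f"targeted set {name!r} overlaps stop words: {sorted(clash)}"
                )
        return self


def default_lexicon() -> KeywordLexicon:
    """The bundled lexicon: standard stop words, demo self-descriptors and
    the targeted medical/degree/family search sets."""
    return KeywordLexicon(
        targeted_sets={
            "medical_terms": {"doctor", "physician", "dietitian", "phd", "md"},
            "female_family": {"mom", "mother", "mum", "wife"},
            "male_family": {"dad", "father", "husband"},
        },
        stem_sets={"alt_medicine": {"naturopath", "homeopath"}},
    )


def tokenize_bio(text: str, lexicon: KeywordLexicon | None = None) -> set[str]:
    """Distinct lowercase keyword tokens of a biography.

    Splits on any non-alphanumeric character; drops stop words and empty
    tokens.  Idempotent on its own space-joined output.
    """
    lexicon = lexicon or default_lexicon()
    tokens = _TOKEN_SPLIT_RE.split(text.lower())
    return {t for t in tokens if t and t not in lexicon.stop_words}


def _group_token_sets(
    space: AffinitySpace, partition: ActivityPartition, lexicon: KeywordLexicon
) -> dict[str, list[set[str]]]:
    by_group: dict[str, list[set[str]]] = {g: [] for g in GROUP_ORDER}
    for uid, group in partition.group_of.items():
        bio = space.users[uid].description
        by_group[group].append(tokenize_bio(bio, lexicon))
    return by_group


def keyword_table(
    space: AffinitySpace,
    partition: ActivityPartition,
    lexicon: KeywordLexicon | None = None,
    top_n: int = 15,
    keywords: Iterable[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-group table of accounts whose biography contains each keyword.

    ``keywords`` defaults to the lexicon's curated self-descriptor list;
    pass a targeted set for the medical/degree tables.  Rows are ranked by
    account count descending, ties broken alphabetically; the top ``top_n``
    rows are returned per activity group.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    lexicon = lexicon or default_lexicon()
    vocab = sorted(set(w.lower() for w in (keywords or lexicon.curated)))
    by_group = _group_token_sets(space, partition, lexicon)
    out: dict[str, pd.DataFrame] = {}
    for group, token_sets in by_group.items():
        counts = {kw: sum(1 for ts in token_sets if kw in ts) for kw in vocab}
        rows = sorted(
            ((kw, c) for kw, c in counts.items() if c > 0),
            key=lambda kv: (-kv[1], kv[0]),
        )[:top_n]
        out[group] = pd.DataFrame(rows, columns=["keyword", "accounts_n"])
    return out


def pct_tweets_by_keyword_users(
    space: AffinitySpace,
    keyword_set: Iterable[str],
    lexicon: KeywordLexicon | None = None,
) -> float:
    """Percent of the space's posts authored by accounts whose bio matches.

    An account matches when its biography token set intersects
    ``keyword_set``.  Reported to 1 decimal; an empty space raises
    :class:`UndefinedMetricError`.
    """
    if not space.tweets:
        raise UndefinedMetricError(f"space {space.spec.label!r} is empty")
    lexicon = lexicon or default_lexicon()
    kws = {w.lower() for w in keyword_set}
    matching_users = {
        uid
        for uid, user in space.users.items()
        if tokenize_bio(user.description, lexicon) & kws
    }
    hit = sum(1 for t in space.tweets if t.author_id in matching_users)
    return round(100.0 * hit / len(space.tweets), 1)


def name_field_search(
    space: AffinitySpace,
    keyword_set: Iterable[str],
    lexicon: KeywordLexicon | None = None,
) -> float:
    """Percent of posting users whose display *name* contains a keyword.

    The name field is tokenized exactly like a biography.  No distractor
    filtering is attempted (a "Doctor Who" fan account matches "doctor").
    """
    if not space.posting_users:
        return 0.0
    lexicon = lexicon or default_lexicon()
    kws = {w.lower() for w in keyword_set}
    matched = sum(
        1
        for user in space.users.values()
        if tokenize_bio(user.name, lexicon) & kws
    )
    return round(100.0 * matched / len(space.posting_users), 1)


def stem_comention(
    space: AffinitySpace,
    anchor_keyword: str,
    stem_set: Iterable[str],
    lexicon: KeywordLexicon | None = None,
) -> float:
    """Among bios containing ``anchor_keyword``, percent also carrying a
    token that starts with any of the given prefixes.

    Raises :class:`UndefinedMetricError` when no bio contains the anchor.
    """
    lexicon = lexicon or default_lexicon()
    anchor = anchor_keyword.lower()
    stems = tuple(s.lower() for s in stem_set)
    anchor_bios = [
        ts
        for user in space.users.values()
        if anchor in (ts := tokenize_bio(user.description, lexicon))
    ]
    if not anchor_bios:
        raise UndefinedMetricError(f"no biography contains {anchor_keyword!r}")
    if not stems:
        return 0.0
    hit = sum(
        1 for ts in anchor_bios if any(t.startswith(stems) for t in ts)
    )
    return round(100.0 * hit / len(anchor_bios), 1)
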