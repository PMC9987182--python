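"""90-9-1 participation-inequality classification and group summaries.

Posting users of a space are ranked by original-post count and split into
superusers (the top 1%), contributors (the next 9%) and lurkers (the
remaining 90%).  Membership is decided by the post count at the boundary
rank, so users tied with the boundary are promoted into the higher-activity
group; the superuser group can therefore exceed an exact 1% of users.

Boundary ranks: with N posting users, the 1% rank is ``ceil(0.01*N)``
(guaranteeing at least one superuser) and the cumulative 10% rank is
``floor(0.10*N)``, floored so that the contributor band matches the
"next 9%" reading on communities whose rank distribution has a sharp drop
at the decile.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .affinity_spaces import AffinitySpace
from .errors import UndefinedMetricError

__all__ = [
    "GROUP_ORDER",
    "ActivityPartition",
    "GroupSummary",
    "classify_90_9_1",
    "summarize",
    "posting_ratios",
]

#: Group labels from most to least active.
GROUP_ORDER = ("superuser", "contributor", "lurker")


@dataclass(frozen=True)
class ActivityPartition:
    """Assignment of every posting user to an activity group.

    ``r1``/``r2`` are the 1-based boundary ranks used; ``c1``/``c2`` the
    post counts found at those ranks (the membership thresholds).
    """

    group_of: dict[str, str]
    tweet_counts: dict[str, int]
    r1: int
    r2: int
    c1: int
    c2: int

    def members(self, group: str) -> frozenset[str]:
        return frozenset(u for u, g in self.group_of.items() if g == group)

    def sizes(self) -> dict[str, int]:
        sizes = dict.fromkeys(GROUP_ORDER, 0)
        for g in self.group_of.values():
            sizes[g] += 1
        return sizes


def classify_90_9_1(space: AffinitySpace) -> ActivityPartition:
    """Partition a space's posting users into superusers/contributors/lurkers.

    Users are ranked by post count descending (ties ordered by user_id for
    determinism; ordering does not affect membership).  All users whose
    count reaches the boundary count are promoted, so groups are unions of
    whole count-classes and the activity ordering
    ``min(superuser counts) >= max(contributor counts) >= max(lurker
    counts)`` always holds.
    """
    counts = Counter(t.author_id for t in space.tweets)
    if not counts:
        raise UndefinedMetricError("space has no posting users")
    n = len(counts)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    r1 = math.ceil(0.01 * n)
    r2 = max(r1, math.floor(0.10 * n))
    c1 = ranked[r1 - 1][1]
    c2 = ranked[r2 - 1][1]
    group_of: dict[str, str] = {}
    for uid, c in ranked:
        if c >= c1:
            group_of[uid] = "superuser"
        elif c >= c2:
            group_of[uid] = "contributor"
        else:
            group_of[uid] = "lurker"
    return ActivityPartition(
        group_of=group_of, tweet_counts=dict(counts), r1=r1, r2=r2, c1=c1, c2=c2
    )


@dataclass(frozen=True)
class GroupSummary:
    """Per-group activity statistics for one space.

    ``stats`` maps group label to a dict with keys ``n`` (users),
    ``tweet_count``, ``pct_tweets``, ``mean`` and ``sd`` (sample SD of
    per-user post counts, 0.0 for groups of one).  ``pct_tweets``, ``mean``
    and ``sd`` are kept at full precision; :meth:`to_frame` renders the
    1-decimal presentation.
    """

    space_label: str
    total_tweets: int
    stats: dict[str, dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in GROUP_ORDER:
            if g not in self.stats:
                continue
            s = self.stats[g]
            rows.append(
                {
                    "group": g,
                    "users_n": int(s["n"]),
                    "tweets_n": int(s["tweet_count"]),
                    "tweets_pct": round(s["pct_tweets"], 1),
                    "tweets_per_user_mean": round(s["mean"], 1),
                    "tweets_per_user_sd": round(s["sd"], 1),
                }
            )
        return pd.DataFrame(rows)


def summarize(space: AffinitySpace, partition: ActivityPartition) -> GroupSummary:
    """Per-group user counts, tweet shares and tweets-per-user moments."""
    total = len(space.tweets)
    per_user = pd.Series(partition.tweet_counts, dtype=float)
    groups = pd.Series(partition.group_of)
    stats: dict[str, dict[str, float]] = {}
    for g in GROUP_ORDER:
        members = groups.index[groups == g]
        if len(members) == 0:
            stats[g] = {"n": 0, "tweet_count": 0, "pct_tweets": 0.0, "mean": 0.0, "sd": 0.0}
            continue
        counts = per_user.loc[members]
        tweet_count = int(counts.sum())
        stats[g] = {
            "n": len(members),
            "tweet_count": tweet_count,
            "pct_tweets": 100.0 * tweet_count / total,
            "mean": float(counts.mean()),
            "sd": float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
        }
    return GroupSummary(space_label=space.spec.label, total_tweets=total, stats=stats)


def posting_ratios(summary: GroupSummary) -> dict[str, float]:
    """Pairwise ratios of mean posts-per-user between adjacent groups.

    Returns ``superuser_vs_contributor`` and ``contributor_vs_lurker``,
    each to 1 decimal, computed from the unrounded group means.  A ratio
    whose denominator group is empty (mean 0) raises
    :class:`UndefinedMetricError`.
    """
    out: dict[str, float] = {}
    for num, den, key in (
        ("superuser", "contributor", "superuser_vs_contributor"),
        ("contributor", "lurker", "contributor_vs_lurker"),
    ):
        mean_num = summary.stats[num]["mean"]
        mean_den = summary.stats[den]["mean"]
        if mean_den == 0:
            raise UndefinedMetricError(f"group {den!r} has no posts; ratio undefined")
        out[key] = round(mean_num / mean_den, 1)
    return out
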