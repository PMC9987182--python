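"""Seeded synthetic tweet-corpus generator.

Two constructors:

* :func:`generate` draws a corpus with the statistical structure the
  analysis assumes — heavy-tailed per-user posting counts (discrete
  lognormal truncated at one post), role-tagged biographies, one anchor
  synonym per tweet plus independent Bernoulli co-tags over a finite
  vocabulary, a planted link-domain distribution, a retweet fraction and
  uniform timestamps over the collection window.

* :func:`from_table` deterministically reconstructs a corpus from a printed
  activity summary (per-group user counts and tweet shares), allocating
  tweets as evenly as possible within each group while keeping every member
  of a higher-activity group strictly above every member of a lower one.

All randomness flows from one ``numpy`` generator seeded from the config;
no global state.
"""

from __future__ import annotations

from datetime import date, datetime, timedelta, timezone

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .corpus_model import Corpus, TweetRecord, UserRecord
from .errors import InfeasibleTableError

__all__ = [
    "RoleSpec",
    "ActivityModel",
    "AnchorSpaceSpec",
    "SyntheticConfig",
    "GroupRow",
    "TableSpec",
    "generate",
    "from_table",
    "CELIAC_ACTIVITY_TABLE",
    "GLUTENFREE_ACTIVITY_TABLE",
    "default_demo_config",
]

#: Default collection window: the 8-month window the bundled demo emulates.
DEFAULT_WINDOW = (date(2019, 10, 27), date(2020, 6, 8))


class RoleSpec(BaseModel):
    """One author role: label, population share, biography keyword pool.

    Each pool keyword enters a role member's biography independently with
    ``inclusion_prob``.
    """

    model_config = ConfigDict(frozen=True)

    label: str
    proportion: float = Field(ge=0.0, le=1.0)
    keywords: tuple[str, ...] = ()
    inclusion_prob: float = Field(default=0.0, ge=0.0, le=1.0)


class ActivityModel(BaseModel):
    """Heavy-tailed per-user post-count law: lognormal, rounded, floored at 1.

    ``location``/``scale`` are the underlying normal's mean and SD of
    log-counts; the defaults give a median near one post with a long right
    tail, matching the highly positively skewed activity observed in
    hashtag communities.
    """

    model_config = ConfigDict(frozen=True)

    name: str = "lognormal"
    location: float = 0.0
    scale: float = Field(default=1.2, gt=0.0)

    @model_validator(mode="after")
    def _known_model(self):
        if self.name != "lognormal":
            raise ValueError(f"unknown activity model {self.name!r}")
        return self


class AnchorSpaceSpec(BaseModel):
    """The anchor tag family every generated tweet carries one member of."""

    model_config = ConfigDict(frozen=True)

    label: str
    tags: dict[str, float]

    @model_validator(mode="after")
    def _positive_weights(self):
        if not self.tags or any(w <= 0 for w in self.tags.values()):
            raise ValueError("anchor tags need positive emission weights")
        return self


class SyntheticConfig(BaseModel):
    """Full generator configuration; see module docstring for semantics."""

    model_config = ConfigDict(frozen=True)

    seed: int = Field(ge=0)
    n_users: int = Field(gt=0)
    window_start: date = DEFAULT_WINDOW[0]
    window_end: date = DEFAULT_WINDOW[1]
    activity: ActivityModel = ActivityModel()
    retweet_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    roles: tuple[RoleSpec, ...] = (RoleSpec(label="generic", proportion=1.0),)
    anchor: AnchorSpaceSpec
    cotag_probs: dict[str, float] = {}
    url_emission_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    domain_probs: dict[str, float] = {}

    @model_validator(mode="after")
    def _check(self):
        if self.window_start > self.window_end:
            raise ValueError("window_start must not be after window_end")
        total = sum(r.proportion for r in self.roles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"role proportions sum to {total}, expected 1")
        for tag, p in self.cotag_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"co-tag probability for {tag!r} outside [0,1]")
        if self.domain_probs:
            s = sum(self.domain_probs.values())
            if any(p < 0 for p in self.domain_probs.values()) or abs(s - 1.0) > 1e-6:
                raise ValueError("domain_probs must be a distribution summing to 1")
        elif self.url_emission_prob > 0:
            raise ValueError("url_emission_prob > 0 requires domain_probs")
        return self


def _uniform_instants(rng: np.random.Generator, n: int, start: date, end: date) -> np.ndarray:
    """Seconds offsets, uniform over the inclusive [start, end] date window."""
    span = (end - start).days + 1
    return rng.uniform(0.0, span * 86400.0, size=n)


def generate(config: SyntheticConfig) -> Corpus:
    """Draw a corpus from the configured generative model (seed-deterministic).

    Every user posts at least once.  Each tweet carries exactly one anchor
    synonym (sampled by emission weight) plus an independent Bernoulli draw
    per co-tag vocabulary entry; with probability ``url_emission_prob`` it
    links one domain drawn from ``domain_probs``.
    """
    rng = np.random.default_rng(config.seed)
    n_users = config.n_users

    counts = np.maximum(
        1,
        np.rint(
            rng.lognormal(config.activity.location, config.activity.scale, n_users)
        ).astype(np.int64),
    )

    role_labels = [r.label for r in config.roles]
    role_idx = rng.choice(
        len(role_labels), size=n_users, p=[r.proportion for r in config.roles]
    )

    users: list[UserRecord] = []
    for i in range(n_users):
        role = config.roles[role_idx[i]]
        kws = [k for k in role.keywords if rng.random() < role.inclusion_prob]
        users.append(
            UserRecord.model_construct(
                user_id=f"u{i:06d}",
                name=f"User {i}",
                description=" ".join(kws),
            )
        )

    n_tweets = int(counts.sum())
    anchor_tags = list(config.anchor.tags)
    anchor_w = np.array([config.anchor.tags[t] for t in anchor_tags], dtype=float)
    anchor_w /= anchor_w.sum()
    anchor_draw = rng.choice(len(anchor_tags), size=n_tweets, p=anchor_w)

    cotag_vocab = list(config.cotag_probs)
    if cotag_vocab:
        cotag_p = np.array([config.cotag_probs[t] for t in cotag_vocab])
        cotag_draw = rng.random((n_tweets, len(cotag_vocab))) < cotag_p
    retweet_draw = rng.random(n_tweets) < config.retweet_fraction
    url_draw = rng.random(n_tweets) < config.url_emission_prob
    if config.domain_probs:
        domains = list(config.domain_probs)
        dom_p = np.array([config.domain_probs[d] for d in domains])
        dom_draw = rng.choice(len(domains), size=n_tweets, p=dom_p / dom_p.sum())
    offsets = _uniform_instants(rng, n_tweets, config.window_start, config.window_end)

    t0 = datetime.combine(config.window_start, datetime.min.time(), tzinfo=timezone.utc)
    author_per_tweet = np.repeat(np.arange(n_users), counts)
    tweets: list[TweetRecord] = []
    for k in range(n_tweets):
        tags = [anchor_tags[anchor_draw[k]]]
        if cotag_vocab:
            tags.extend(t for j, t in enumerate(cotag_vocab) if cotag_draw[k, j])
        urls: tuple[str, ...] = ()
        if url_draw[k] and config.domain_probs:
            urls = (f"https://{domains[dom_draw[k]]}/p/{k}",)
        tweets.append(
            TweetRecord.model_construct(
                tweet_id=f"t{k:08d}",
                author_id=f"u{author_per_tweet[k]:06d}",
                created_at=t0 + timedelta(seconds=float(offsets[k])),
                text=" ".join("#" + t for t in tags),
                hashtags=tuple(tags),
                urls=urls,
                is_retweet=bool(retweet_draw[k]),
            )
        )
    return Corpus(tweets=tweets, users=users)


class GroupRow(BaseModel):
    """One activity group of a printed summary: label, users, tweet share."""

    model_config = ConfigDict(frozen=True)

    label: str
    user_count: int = Field(gt=0)
    tweet_share_pct: float = Field(gt=0.0)


class TableSpec(BaseModel):
    """A printed activity summary: groups ordered most → least active.

    Tweet shares are percentages of ``total_tweets`` and must sum to 100
    within 0.1.  ``anchor_tag`` is the hashtag stamped on every
    reconstructed tweet so the corpus lands in the intended space.
    """

    model_config = ConfigDict(frozen=True)

    groups: tuple[GroupRow, ...]
    total_tweets: int = Field(gt=0)
    anchor_tag: str = "topic"
    window_start: date = DEFAULT_WINDOW[0]
    window_end: date = DEFAULT_WINDOW[1]

    @model_validator(mode="after")
    def _shares(self):
        s = sum(g.tweet_share_pct for g in self.groups)
        if abs(s - 100.0) > 0.1:
            raise ValueError(f"tweet shares sum to {s}, expected 100 ± 0.1")
        if self.total_tweets < sum(g.user_count for g in self.groups):
            raise InfeasibleTableError(
                "total_tweets is too small for every user to post once"
            )
        return self


def _allocate_counts(n_users: int, n_tweets: int) -> list[int]:
    """Most-even integer split; the first ``remainder`` users get one extra."""
    q, r = divmod(n_tweets, n_users)
    return [q + 1] * r + [q] * (n_users - r)


def from_table(spec: TableSpec, seed: int = 0) -> Corpus:
    """Deterministically rebuild a corpus matching a printed group summary.

    Each group's tweet total is ``floor(share/100 * total + 0.5)``; within
    a group, tweets are spread as evenly as possible (remainder to the
    first users in id order).  Raises :class:`InfeasibleTableError` when
    the shares would force some member of a higher-activity group to post
    no more than a member of a lower one, or a user below one post.

    ``seed`` only jitters timestamps; counts and memberships are exact.
    """
    rng = np.random.default_rng(seed)
    group_tweets = [
        int(np.floor(g.tweet_share_pct / 100.0 * spec.total_tweets + 0.5))
        for g in spec.groups
    ]
    per_user: list[list[int]] = []
    for g, n_t in zip(spec.groups, group_tweets):
        if n_t < g.user_count:
            raise InfeasibleTableError(
                f"group {g.label!r}: {n_t} tweets cannot give "
                f"{g.user_count} users one post each"
            )
        per_user.append(_allocate_counts(g.user_count, n_t))
    for (hi, hi_counts), (lo, lo_counts) in zip(
        zip(spec.groups, per_user), list(zip(spec.groups, per_user))[1:]
    ):
        if min(hi_counts) <= max(lo_counts):
            raise InfeasibleTableError(
                f"group {hi.label!r} (min {min(hi_counts)}) does not stay "
                f"strictly above group {lo.label!r} (max {max(lo_counts)})"
            )

    users: list[UserRecord] = []
    tweets: list[TweetRecord] = []
    t0 = datetime.combine(spec.window_start, datetime.min.time(), tzinfo=timezone.utc)
    n_total = sum(group_tweets)
    offsets = np.sort(_uniform_instants(rng, n_total, spec.window_start, spec.window_end))
    k = 0
    for gi, (g, counts) in enumerate(zip(spec.groups, per_user)):
        for ui, c in enumerate(counts):
            uid = f"g{gi}-{ui:06d}"
            users.append(UserRecord.model_construct(user_id=uid, name="", description=""))
            for _ in range(c):
                tweets.append(
                    TweetRecord.model_construct(
                        tweet_id=f"t{k:08d}",
                        author_id=uid,
                        created_at=t0 + timedelta(seconds=float(offsets[k])),
                        text=f"#{spec.anchor_tag}",
                        hashtags=(spec.anchor_tag,),
                        urls=(),
                        is_retweet=False,
                    )
                )
                k += 1
    return Corpus(tweets=tweets, users=users)


#: Bundled demo reconstruction specs: the observed 90-9-1 structure of the
#: two celiac-disease / gluten-free-diet communities over their 8-month
#: collection window (user counts and percent-of-space tweet shares).
CELIAC_ACTIVITY_TABLE = TableSpec(
    groups=(
        GroupRow(label="superuser", user_count=44, tweet_share_pct=28.7),
        GroupRow(label="contributor", user_count=394, tweet_share_pct=35.2),
        GroupRow(label="lurker", user_count=3945, tweet_share_pct=36.1),
    ),
    total_tweets=15_602,
    anchor_tag="celiac",
)

GLUTENFREE_ACTIVITY_TABLE = TableSpec(
    groups=(
        GroupRow(label="superuser", user_count=1_718, tweet_share_pct=25.5),
        GroupRow(label="contributor", user_count=16_947, tweet_share_pct=25.2),
        GroupRow(label="lurker", user_count=145_246, tweet_share_pct=49.3),
    ),
    total_tweets=334_907,
    anchor_tag="glutenfree",
)


def default_demo_config(seed: int = 7, n_users: int = 2_000) -> SyntheticConfig:
    """A small end-to-end demo configuration exercising every pipeline stage."""
    return SyntheticConfig(
        seed=seed,
        n_users=n_users,
        retweet_fraction=0.3,
        roles=(
            RoleSpec(
                label="self_promoter",
                proportion=0.25,
                keywords=("blogger", "writer", "author", "vegan", "foodie"),
                inclusion_prob=0.4,
            ),
            RoleSpec(
                label="family",
                proportion=0.25,
                keywords=("mom", "mother", "wife", "dad", "husband"),
                inclusion_prob=0.35,
            ),
            RoleSpec(
                label="clinician",
                proportion=0.05,
                keywords=("doctor", "dietitian", "physician", "phd", "md"),
                inclusion_prob=0.5,
            ),
            RoleSpec(label="general", proportion=0.45),
        ),
        anchor=AnchorSpaceSpec(
            label="glutenfree",
            tags={"glutenfree": 0.8, "glutenfreediet": 0.2},
        ),
        cotag_probs={
            "vegan": 0.18,
            "dairyfree": 0.06,
            "keto": 0.03,
            "recipe": 0.05,
            "celiac": 0.03,
            "gluten": 0.02,
            "gf": 0.02,
        },
        url_emission_prob=0.25,
        domain_probs={
            "instagram.com": 0.35,
            "youtu.be": 0.15,
            "celiac.com": 0.12,
            "bit.ly": 0.08,
            "blog.example.com": 0.14,
            "nonprofit.org": 0.10,
            "health.example.gov": 0.01,
            "pinterest.com": 0.05,
        },
    )
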