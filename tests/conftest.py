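from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import settings

from affinispace.corpus_model import Corpus, TweetRecord, UserRecord
from affinispace.synthetic_corpus import AnchorSpaceSpec, SyntheticConfig

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")

T0 = datetime(2020, 1, 15, 12, 0, tzinfo=timezone.utc)


def make_tweet(i, author="u1", tags=(), urls=(), retweet=False, when=T0):
    return TweetRecord(
        tweet_id=f"t{i}",
        author_id=author,
        created_at=when,
        text=" ".join("#" + t for t in tags),
        hashtags=tuple(tags),
        urls=tuple(urls),
        is_retweet=retweet,
    )


def make_corpus(tweets, bios=None, names=None):
    """Corpus with one auto-created user per distinct author_id."""
    bios = bios or {}
    names = names or {}
    authors = sorted({t.author_id for t in tweets})
    users = [
        UserRecord(user_id=a, name=names.get(a, ""), description=bios.get(a, ""))
        for a in authors
    ]
    return Corpus(tweets=list(tweets), users=users)


@pytest.fixture
def tweet_factory():
    return make_tweet


@pytest.fixture
def corpus_factory():
    return make_corpus


def simple_synth_config(**overrides) -> SyntheticConfig:
    """A small planted-parameter generator config that tests tweak per case."""
    base = dict(
        seed=11,
        n_users=2_000,
        anchor=AnchorSpaceSpec(label="celiac", tags={"celiac": 1.0}),
    )
    base.update(overrides)
    return SyntheticConfig(**base)
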