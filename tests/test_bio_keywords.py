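"""Biography tokenization, keyword tables and targeted profile searches."""

import random

import pytest

from affinispace.activity_groups import classify_90_9_1
from affinispace.affinity_spaces import AffinitySpaceSpec, build_space
from affinispace.bio_keywords import (
    default_lexicon,
    keyword_table,
    name_field_search,
    pct_tweets_by_keyword_users,
    stem_comention,
    tokenize_bio,
)
from affinispace.errors import UndefinedMetricError
from affinispace.synthetic_corpus import RoleSpec, generate

from conftest import make_corpus, make_tweet, simple_synth_config

SPEC = AffinitySpaceSpec(label="a", synonym_tags=["aa"])


def space_with_bios(bios, names=None):
    """One 1-tweet user per bio entry."""
    tweets = [make_tweet(i, author=uid, tags=["aa"]) for i, uid in enumerate(bios)]
    corpus = make_corpus(tweets, bios=bios, names=names)
    return build_space(corpus, SPEC)


class TestTokenizeBio:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Mom, blogger & writer", {"mom", "blogger", "writer"}),
            ("", set()),
            ("a and the", set()),
            ("Vegan-blogger; MOM!!", {"vegan", "blogger", "mom"}),
            ("PhD (nutrition) 2021", {"phd", "nutrition", "2021"}),
        ],
    )
    def test_examples(self, text, expected):
        assert tokenize_bio(text) == expected

    def test_idempotent_on_rejoined_output(self):
        tokens = tokenize_bio("Mom, blogger & writer. Doctor-to-be!")
        assert tokenize_bio(" ".join(sorted(tokens))) == tokens


class TestKeywordTable:
    def test_counts_accounts_not_posts(self):
        bios = {f"u{i}": ("blogger mom" if i < 5 else "fan") for i in range(44)}
        # one user posts many times; still one account
        tweets = [make_tweet(i, author=f"u{i % 44}", tags=["aa"]) for i in range(100)]
        space = build_space(make_corpus(tweets, bios=bios), SPEC)
        part = classify_90_9_1(space)
        tables = keyword_table(space, part, top_n=15)
        total = {}
        for table in tables.values():
            for kw, n in table.itertuples(index=False):
                total[kw] = total.get(kw, 0) + n
        assert total["blogger"] == 5
        assert total["mom"] == 5
        assert total["fan"] == 39

    def test_no_matches_gives_empty_table(self):
        space = space_with_bios({"u1": "zzz qqq"})
        tables = keyword_table(space, classify_90_9_1(space))
        assert all(table.empty for table in tables.values())

    def test_top_n_must_be_positive(self):
        space = space_with_bios({"u1": "blogger"})
        with pytest.raises(ValueError):
            keyword_table(space, classify_90_9_1(space), top_n=0)

    def test_matches_brute_force_on_small_corpus(self):
        rng = random.Random(9)
        vocab = ["blogger", "mom", "vegan", "writer", "fan", "doctor"]
        bios = {
            f"u{i:03d}": " ".join(rng.sample(vocab, rng.randint(0, 3)))
            for i in range(200)
        }
        space = space_with_bios(bios)
        part = classify_90_9_1(space)
        tables = keyword_table(space, part, top_n=50)
        lex = default_lexicon()
        for group, table in tables.items():
            expected = {}
            for uid in part.members(group):
                for kw in vocab:
                    if kw in tokenize_bio(bios[uid], lex):
                        expected[kw] = expected.get(kw, 0) + 1
            got = dict(zip(table["keyword"], table["accounts_n"]))
            assert got == expected

    def test_counts_bounded_by_group_size(self):
        cfg = simple_synth_config(
            n_users=500,
            roles=(
                RoleSpec(label="r", proportion=1.0,
                         keywords=("blogger", "mom"), inclusion_prob=0.5),
            ),
            anchor={"label": "a", "tags": {"aa": 1.0}},
        )
        space = build_space(generate(cfg), SPEC)
        part = classify_90_9_1(space)
        sizes = part.sizes()
        for group, table in keyword_table(space, part).items():
            assert all(n <= sizes[group] for n in table["accounts_n"])


class TestTargetedSearches:
    def test_pct_tweets_by_keyword_users(self):
        bios = {"u1": "dietitian", "u2": "", "u3": ""}
        tweets = [make_tweet(i, author="u1", tags=["aa"]) for i in range(2)]
        tweets += [make_tweet(i + 2, author=f"u{2 + i % 2}", tags=["aa"]) for i in range(8)]
        space = build_space(make_corpus(tweets, bios=bios), SPEC)
        assert pct_tweets_by_keyword_users(space, {"dietitian", "md"}) == 20.0

    def test_pct_tweets_no_match_is_zero(self):
        space = space_with_bios({"u1": "blogger"})
        assert pct_tweets_by_keyword_users(space, {"physician"}) == 0.0

    def test_pct_tweets_empty_space_undefined(self):
        space = build_space(make_corpus([]), SPEC)
        with pytest.raises(UndefinedMetricError):
            pct_tweets_by_keyword_users(space, {"md"})

    def test_name_field_search_rate(self):
        bios = {f"u{i:03d}": "" for i in range(200)}
        names = {"u000": "Jane Smith, PhD"}
        space = space_with_bios(bios, names=names)
        assert name_field_search(space, {"phd"}) == 0.5

    def test_name_field_distractors_count(self):
        space = space_with_bios({"u1": ""}, names={"u1": "Doctor Who Fan"})
        assert name_field_search(space, {"doctor"}) == 100.0

    def test_name_field_empty_keyword_set(self):
        space = space_with_bios({"u1": ""}, names={"u1": "Doc"})
        assert name_field_search(space, set()) == 0.0

    def test_stem_comention_rate(self):
        bios = {f"u{i:02d}": "doctor" for i in range(20)}
        bios["u00"] = "doctor naturopathic medicine"
        space = space_with_bios(bios)
        assert stem_comention(space, "doctor", {"naturopath", "homeopath"}) == 5.0

    def test_stem_comention_empty_stems(self):
        space = space_with_bios({"u1": "doctor"})
        assert stem_comention(space, "doctor", set()) == 0.0

    def test_stem_comention_no_anchor_undefined(self):
        space = space_with_bios({"u1": "blogger"})
        with pytest.raises(UndefinedMetricError):
            stem_comention(space, "doctor", {"naturopath"})

    def test_planted_comention_rate_recovered(self):
        cfg = simple_synth_config(
            n_users=1_000,
            roles=(
                RoleSpec(label="doc", proportion=0.5,
                         keywords=("doctor",), inclusion_prob=1.0),
                RoleSpec(label="naturo", proportion=0.5,
                         keywords=("doctor", "naturopathy"), inclusion_prob=1.0),
            ),
        )
        # every user mentions doctor; half also a naturopath- stem word
        from affinispace.affinity_spaces import CELIAC_SPEC

        space = build_space(generate(cfg), CELIAC_SPEC)
        rate = stem_comention(space, "doctor", {"naturopath"})
        assert rate == pytest.approx(50.0, abs=4.8)  # 3 sigma on role assignment
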