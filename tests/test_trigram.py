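"""Trigram model training, probabilities, surprisal, and serialization."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from infodist.trigram import (
    TrigramModel,
    UnseenNgramError,
    conditional_probability,
    train_trigram_model,
    utterance_surprisal,
)
from tests.conftest import corpus_from_token_lists, make_utterance


def brute_force_tally(token_lists):
    """Independent oracle: plain-dict n-gram tally with per-utterance restart."""
    uni, bi, bi_ctx, tri, tri_ctx = {}, {}, {}, {}, {}
    for toks in token_lists:
        for w in toks:
            uni[w] = uni.get(w, 0) + 1
        for i in range(1, len(toks)):
            bi[(toks[i - 1], toks[i])] = bi.get((toks[i - 1], toks[i]), 0) + 1
            bi_ctx[toks[i - 1]] = bi_ctx.get(toks[i - 1], 0) + 1
        for i in range(2, len(toks)):
            key = (toks[i - 2], toks[i - 1], toks[i])
            tri[key] = tri.get(key, 0) + 1
            ctx = (toks[i - 2], toks[i - 1])
            tri_ctx[ctx] = tri_ctx.get(ctx, 0) + 1
    return uni, bi, bi_ctx, tri, tri_ctx


FOUR_UTTS = [["a", "b", "c"], ["a", "b", "c"], ["a", "b", "d"], ["a", "b", "d"]]


class TestTraining:
    def test_counts_match_four_utterance_example(self):
        model = train_trigram_model(corpus_from_token_lists(FOUR_UTTS))
        assert model.continuation_counts[("a", "b", "c")] == 2
        assert model.context_counts[("a", "b")] == 4
        assert conditional_probability(model, "a", "b", "c") == 0.5

    def test_counts_equal_brute_force_tally(self, tiny_fixture):
        corpus, _ = tiny_fixture
        token_lists = [list(u.tokens) for u in corpus.utterances()]
        uni, bi, bi_ctx, tri, tri_ctx = brute_force_tally(token_lists)
        model = train_trigram_model(corpus)
        assert model.unigram_counts == uni
        assert model.bigram_counts == bi
        assert model.bigram_context_counts == bi_ctx
        assert model.continuation_counts == tri
        assert model.context_counts == tri_ctx

    def test_repeated_utterance_gives_probability_one(self):
        corpus = corpus_from_token_lists([["x", "y", "z", "w"]] * 5)
        model = train_trigram_model(corpus)
        for (w2, w1, w) in model.continuation_counts:
            assert conditional_probability(model, w2, w1, w) == 1.0

    def test_order_invariance(self):
        m1 = train_trigram_model(corpus_from_token_lists(FOUR_UTTS))
        m2 = train_trigram_model(corpus_from_token_lists(FOUR_UTTS[::-1]))
        assert m1.continuation_counts == m2.continuation_counts
        assert m1.unigram_counts == m2.unigram_counts

    def test_empty_corpus_rejected(self):
        from infodist.corpus import Corpus

        with pytest.raises(ValueError, match="empty"):
            train_trigram_model(Corpus(language_label="none", conversations=()))

    @given(
        st.lists(
            st.lists(st.sampled_from("abcde"), min_size=3, max_size=8),
            min_size=1,
            max_size=20,
        )
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_per_context_probabilities_normalize(self, token_lists):
        model = train_trigram_model(corpus_from_token_lists(token_lists))
        for ctx, total in model.context_counts.items():
            mass = sum(
                c / total
                for (w2, w1, _), c in model.continuation_counts.items()
                if (w2, w1) == ctx
            )
            assert mass == pytest.approx(1.0)


class TestSurprisal:
    def test_surprisal_values_and_flags(self):
        model = train_trigram_model(corpus_from_token_lists(FOUR_UTTS))
        seq = utterance_surprisal(model, make_utterance(["a", "b", "c"]))
        assert len(seq.values) == 3
        assert seq.context_complete == (False, False, True)
        # P(c | a, b) = 0.5 → 1 bit
        assert seq.values[2] == pytest.approx(1.0)

    def test_zero_surprisal_iff_deterministic(self):
        corpus = corpus_from_token_lists([["p", "q", "r", "s", "t", "u", "v", "w"]] * 3)
        model = train_trigram_model(corpus)
        seq = utterance_surprisal(model, next(corpus.utterances()))
        assert all(v == 0.0 for v, flag in zip(seq.values, seq.context_complete) if flag)

    def test_nats_equal_bits_times_ln2(self):
        corpus = corpus_from_token_lists(FOUR_UTTS)
        bits = utterance_surprisal(train_trigram_model(corpus, log_base=2), make_utterance(["a", "b", "c"]))
        nats = utterance_surprisal(
            train_trigram_model(corpus, log_base=math.e), make_utterance(["a", "b", "c"])
        )
        for vb, vn in zip(bits.values, nats.values):
            assert vn == pytest.approx(vb * math.log(2))

    def test_unseen_triple_raises_by_default_inf_when_permissive(self):
        model = train_trigram_model(corpus_from_token_lists(FOUR_UTTS))
        with pytest.raises(UnseenNgramError):
            conditional_probability(model, "a", "b", "zzz")
        seq = utterance_surprisal(model, make_utterance(["a", "b", "zzz"]), unseen="inf")
        assert math.isinf(seq.values[2])

    def test_all_values_nonnegative(self, tiny_fixture):
        corpus, _ = tiny_fixture
        model = train_trigram_model(corpus)
        for utt in corpus.utterances():
            assert all(v >= 0 for v in utterance_surprisal(model, utt).values)


class TestSerialization:
    def test_json_round_trip(self, tmp_path, tiny_fixture):
        corpus, _ = tiny_fixture
        model = train_trigram_model(corpus)
        path = model.to_json(tmp_path / "model.json")
        back = TrigramModel.from_json(path)
        assert back.continuation_counts == model.continuation_counts
        assert back.unigram_counts == model.unigram_counts
        assert back.log_base == model.log_base
        # deterministic bytes for reproducible hashing
        p2 = model.to_json(tmp_path / "model2.json")
        assert path.read_bytes() == p2.read_bytes()


def test_estimation_improves_with_corpus_size_matched_seeds():
    """Trigram recovery of true surprisal sharpens as the corpus grows."""
    from infodist.calibration import surprisal_recovery

    small = surprisal_recovery(seed=3, n_utterances=800)
    large = surprisal_recovery(seed=3, n_utterances=4000)
    assert large["correlation"] > small["correlation"]
    assert large["correlation"] >= 0.9
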