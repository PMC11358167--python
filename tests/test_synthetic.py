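"""Generator determinism, entropy calibration, and ground-truth alignment."""

import numpy as np
import pytest

from infodist.corpus import clean_corpus
from infodist.synthetic import (
    CalibrationError,
    GeneratorConfig,
    expected_surprisal_diff,
    generate_corpus,
    make_fixture,
    max_feasible_delta,
    read_ground_truth,
    true_surprisal,
    write_ground_truth,
)

SMALL = dict(n_dyads=5, utterances_per_conversation=20)


class TestDeterminism:
    def test_same_seed_reproduces_corpus_exactly(self):
        cfg = GeneratorConfig(seed=77, **SMALL)
        c1, g1 = generate_corpus(cfg)
        c2, g2 = generate_corpus(cfg)
        assert c1 == c2
        assert g1.surprisal == g2.surprisal
        assert g1.tags == g2.tags

    def test_different_seeds_differ(self):
        c1, _ = generate_corpus(GeneratorConfig(seed=1, **SMALL))
        c2, _ = generate_corpus(GeneratorConfig(seed=2, **SMALL))
        assert c1 != c2


class TestCalibration:
    def test_expected_diff_by_mode(self):
        for mode, sign in [("back", 1.0), ("front", -1.0)]:
            cfg = GeneratorConfig(loading_mode=mode, delta_bits=0.7, **SMALL)
            assert expected_surprisal_diff(cfg) == pytest.approx(sign * 0.7)
        assert expected_surprisal_diff(
            GeneratorConfig(loading_mode="flat", delta_bits=0.0, **SMALL)
        ) == 0.0

    def test_true_surprisal_expectation_matches_target(self):
        # sample mean of true surprisal per half ≈ calibrated entropies
        cfg = GeneratorConfig(
            loading_mode="back", delta_bits=1.0, n_dyads=20, utterances_per_conversation=100, seed=5
        )
        corpus, gt = generate_corpus(cfg)
        diffs = []
        for utt in corpus.utterances():
            ts = gt.surprisal[utt.utterance_id]
            cut = len(ts) // 2
            if len(ts) >= 8:
                diffs.append(np.mean(ts[cut:]) - np.mean(ts[:cut]))
        assert np.mean(diffs) == pytest.approx(1.0, abs=0.1)

    def test_infeasible_delta_names_feasible_maximum(self):
        cfg_kwargs = dict(loading_mode="back", **SMALL)
        feasible = max_feasible_delta(GeneratorConfig(delta_bits=0.0, **cfg_kwargs))
        with pytest.raises(CalibrationError, match="feasible maximum"):
            generate_corpus(GeneratorConfig(delta_bits=feasible + 0.5, **cfg_kwargs))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(loading_mode="sideways")
        with pytest.raises(ValueError):
            GeneratorConfig(delta_bits=-0.1)
        with pytest.raises(ValueError):
            GeneratorConfig(vocab_size=30)


class TestStructure:
    def test_speakers_alternate_and_corpus_is_valid(self):
        corpus, _ = generate_corpus(GeneratorConfig(seed=3, **SMALL))
        for conv in corpus.conversations:
            speakers = [u.speaker_id for u in conv.utterances]
            assert all(a != b for a, b in zip(speakers, speakers[1:]))
            assert len(set(speakers)) == 2

    def test_durations_follow_speech_rate(self):
        cfg = GeneratorConfig(seed=3, words_per_second=2.5, **SMALL)
        corpus, _ = generate_corpus(cfg)
        for utt in corpus.utterances():
            assert utt.duration_ms == max(1, round(1000 * utt.n_tokens / 2.5))

    def test_cleaning_leaves_fillerless_corpus_unchanged(self):
        corpus, _ = generate_corpus(GeneratorConfig(seed=4, **SMALL))
        cleaned = clean_corpus(corpus)
        assert [u.tokens for u in cleaned.utterances()] == [
            u.tokens for u in corpus.utterances()
        ]

    def test_filler_injection_removed_by_cleaning_realigns_ground_truth(self):
        cfg = GeneratorConfig(seed=4, filler_rate=0.15, **SMALL)
        corpus, gt = generate_corpus(cfg)
        assert any("uh" in u.tokens for u in corpus.utterances())
        cleaned = clean_corpus(corpus)
        for utt in cleaned.utterances():
            ts = gt.surprisal[utt.utterance_id]
            assert len(ts) == utt.n_tokens
            assert utt.tags == gt.tags[utt.utterance_id]

    def test_pos_rates_match_configured_targets(self):
        cfg = GeneratorConfig(
            loading_mode="back",
            delta_bits=0.5,
            pos_enrichment=0.06,
            n_dyads=50,
            utterances_per_conversation=100,
            seed=8,
        )
        corpus, gt = generate_corpus(cfg)
        # NOUN rate difference between dense (last) and sparse (first)
        # halves should track the configured enrichment
        first_n = last_n = first_tot = last_tot = 0
        for utt in corpus.utterances():
            cut = utt.n_tokens // 2
            tags = utt.tags
            first_n += sum(1 for t in tags[:cut] if t == "NOUN")
            last_n += sum(1 for t in tags[cut:] if t == "NOUN")
            first_tot += cut
            last_tot += len(tags) - cut
        realized = last_n / last_tot - first_n / first_tot
        assert realized == pytest.approx(0.06, abs=0.02)

    def test_true_surprisal_lookup_and_foreign_utterance(self, tiny_fixture):
        corpus, gt = tiny_fixture
        utt = next(corpus.utterances())
        assert len(true_surprisal(gt, utt)) == utt.n_tokens
        from tests.conftest import make_utterance

        with pytest.raises(LookupError):
            true_surprisal(gt, make_utterance(["x"] * 8, utterance_id="foreign"))


class TestFixtures:
    def test_tiny_fixture_is_small(self, tiny_fixture):
        corpus, _ = tiny_fixture
        assert corpus.n_utterances <= 20

    def test_reference_suite_composition(self, reference_suite):
        modes = {c.language_label: g.config.loading_mode for c, g in reference_suite}
        assert sum(1 for m in modes.values() if m == "back") == 3
        assert sum(1 for m in modes.values() if m == "front") == 3
        ftos = {g.config.loading_mode: g.config.fto_mean_ms for _, g in reference_suite}
        assert ftos["back"] - ftos["front"] == pytest.approx(100.0)

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            make_fixture("bogus")

    def test_ground_truth_sidecar_round_trip(self, tmp_path, tiny_fixture):
        corpus, gt = tiny_fixture
        path = write_ground_truth(gt, tmp_path / "truth.jsonl")
        back = read_ground_truth(path)
        assert back.surprisal.keys() == gt.surprisal.keys()
        uid = next(iter(gt.surprisal))
        assert back.surprisal[uid] == pytest.approx(gt.surprisal[uid])
        assert back.config == gt.config
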