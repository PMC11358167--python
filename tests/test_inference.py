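"""Mixed-model comparisons: recovery, calibration, and contract checks."""

import numpy as np
import pandas as pd
import pytest

from infodist import inference as inf
from infodist.calibration import loading_table_for
from infodist.loading import filter_utterances, corpus_loading_table
from infodist.pos import unit_stats_table
from infodist.synthetic import GeneratorConfig, generate_corpus
from infodist.timing import fto_table
from infodist.trigram import train_trigram_model


def make_language(mode, seed, n_dyads=15, utts=20, **kw):
    cfg = GeneratorConfig(
        language_label=f"{mode}{seed}",
        n_dyads=n_dyads,
        utterances_per_conversation=utts,
        loading_mode=mode,
        delta_bits=0.0 if mode == "flat" else 0.5,
        seed=seed,
        **kw,
    )
    return generate_corpus(cfg)


class TestHalfEffectLrt:
    def test_injected_positive_half_effect_detected(self):
        cfg = GeneratorConfig(
            language_label="inj",
            n_dyads=50,
            utterances_per_conversation=40,
            loading_mode="back",
            delta_bits=0.5,
            seed=7,
        )
        corpus, _ = generate_corpus(cfg)
        res = inf.lrt_half_effect(inf.half_long_table(loading_table_for(corpus)))
        assert res.significant and res.alpha_used == 0.008
        assert inf.half_effect_estimate(res) > 0
        assert res.df == 1 and res.chisq > 0

    def test_single_dyad_fails_loudly(self):
        corpus, _ = make_language("flat", 1, n_dyads=1, utts=30)
        long = inf.half_long_table(loading_table_for(corpus))
        with pytest.raises(ValueError, match="at least 2 dyads"):
            inf.lrt_half_effect(long)

    def test_default_alpha_is_bonferroni_for_six_languages(self):
        assert inf.BONFERRONI_ALPHA == pytest.approx(0.05 / 6, abs=5e-4)


class TestCrossLanguage:
    def test_contrast_count_is_k_choose_2(self):
        tables = [
            loading_table_for(make_language(m, s)[0])
            for m, s in [("back", 1), ("front", 2), ("flat", 3)]
        ]
        comp, contrasts = inf.cross_language_model(pd.concat(tables, ignore_index=True))
        assert len(contrasts) == 3  # k(k-1)/2 with k=3
        assert comp.df == 2
        pairs = {tuple(sorted(c.pair)) for c in contrasts}
        assert len(pairs) == 3

    def test_identical_generation_rarely_significant(self):
        # null calibration at reduced scale: identically generated
        # languages should almost never differ
        n_sig = 0
        runs = 10
        for i in range(runs):
            tables = [
                loading_table_for(
                    make_language("flat", seed=100 + 3 * i + j, n_dyads=10, utts=20)[0]
                ).assign(language=f"lang{j}")
                for j in range(3)
            ]
            comp, _ = inf.cross_language_model(pd.concat(tables, ignore_index=True))
            n_sig += comp.significant
        assert n_sig <= 3


@pytest.fixture(scope="module")
def two_group_tables():
    """Loading + unit tables for one back- and one front-loaded language."""
    ltabs, utabs = [], []
    for mode, seed in [("back", 31), ("front", 32)]:
        corpus, _ = make_language(
            mode, seed, n_dyads=15, utts=25, pos_enrichment=0.05, verb_surprisal_coupling=0.4
        )
        model = train_trigram_model(corpus)
        filt = filter_utterances(corpus)
        ltabs.append(corpus_loading_table(filt, model))
        utabs.append(unit_stats_table(filt, model, loading_group=mode))
    return (
        pd.concat(ltabs, ignore_index=True),
        pd.concat(utabs, ignore_index=True),
    )


class TestUnitModels:
    def test_sum_coding_columns_balance(self):
        import patsy

        data = pd.DataFrame({"unit": ["NOUN", "VERB"] * 10})
        mat = patsy.dmatrix("C(unit, Sum)", data)
        assert np.asarray(mat)[:, 1].sum() == pytest.approx(0.0)

    def test_verb_noun_surprisal_contrast_recovered(self, two_group_tables):
        _, unit_table = two_group_tables
        res = inf.unit_surprisal_model(unit_table)
        unit_terms = [t for t in res.fixed_effects if "unit" in t and ":" not in t]
        assert unit_terms, "grammatical unit retained in the model"
        # sum coding over (NOUN, VERB): the coded column is +1 for NOUN,
        # so verbs > nouns in surprisal means a negative coefficient
        est = res.fixed_effects[unit_terms[0]][0]
        data = unit_table.dropna(subset=["mean_unit_surprisal"])
        means = data.groupby("unit")["mean_unit_surprisal"].mean()
        assert (means["VERB"] > means["NOUN"]) == (est < 0)

    def test_rate_squeeze_stays_inside_unit_interval(self):
        y = np.array([0.0, 0.2, 1.0, 0.0])
        sq = inf.squeeze_unit_interval(y)
        assert (sq > 0).all() and (sq < 1).all()

    def test_rate_model_runs_and_reports_interaction_lrt(self, two_group_tables):
        _, unit_table = two_group_tables
        res = inf.unit_rate_model(unit_table)
        assert res.df == 4
        assert 0 <= res.p_value <= 1
        assert res.chisq >= 0


class TestBackwardsSelect:
    @staticmethod
    def simulate(n=600, beta=None, seed=0):
        rng = np.random.default_rng(seed)
        beta = beta or {}
        df = pd.DataFrame(
            {
                "dyad": [f"d{i % 10}" for i in range(n)],
                "speaker": [f"d{i % 10}_s{(i // 10) % 2}" for i in range(n)],
                "rate": rng.uniform(0, 0.6, n),
                "surprisal": rng.normal(2.5, 0.8, n),
                "half": rng.choice(["first", "last"], n),
                "unit": rng.choice(["NOUN", "VERB"], n),
            }
        )
        half_c = np.where(df["half"] == "first", 1.0, -1.0)
        df["diff"] = (
            beta.get("rate", 0.0) * df["rate"]
            + beta.get("surprisal", 0.0) * df["surprisal"]
            + beta.get("half:surprisal", 0.0) * half_c * df["surprisal"]
            + rng.normal(0, 0.5, n)
        )
        return df

    def test_pure_main_effects_prune_interactions(self):
        # stop-at-first-significant can halt early on a chance hit among
        # the 11 null interactions, so require that most are pruned and
        # the true main effects survive
        df = self.simulate(beta={"rate": 1.0, "surprisal": 0.5}, seed=1)
        res = inf.backwards_select(df)
        n_removed = sum(s["removed"] for s in res.steps)
        assert n_removed >= 7
        assert "rate" in res.fixed_effects and "surprisal" in res.fixed_effects
        assert res.significant  # mains carry real signal

    def test_genuine_interaction_is_retained(self):
        df = self.simulate(beta={"surprisal": 0.3, "half:surprisal": 0.5}, seed=2)
        res = inf.backwards_select(df)
        assert any(
            set(t.split(":")) >= {"surprisal"} and "half" in t for t in res.fixed_effects if ":" in t
        )

    def test_removal_order_deterministic(self):
        df = self.simulate(beta={"rate": 0.8}, seed=3)
        r1 = inf.backwards_select(df)
        r2 = inf.backwards_select(df)
        assert [s["term"] for s in r1.steps] == [s["term"] for s in r2.steps]


class TestFtoModel:
    def test_independent_surprisal_predictors_nonsignificant(self):
        tables = []
        for mode, seed in [("back", 61), ("front", 62)]:
            corpus, _ = make_language(mode, seed, n_dyads=20, utts=30)
            model = train_trigram_model(corpus)
            tables.append(fto_table(corpus, model, loading_group=mode))
        res = inf.fto_model(pd.concat(tables, ignore_index=True))
        # FTO is generated independently of surprisal
        assert res.surprisal_halves.p_value > 0.05
        assert res.surprisal_halves.df == 2
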