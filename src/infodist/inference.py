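"""Mixed-effects model comparisons over loading, unit, and timing tables.

This module owns the statistical workflow of the analysis: nested
model comparisons by likelihood-ratio test (LRT) on maximum-likelihood
fits, per-language tests of the utterance-half effect at a
Bonferroni-corrected threshold, the cross-language surprisal-
difference model with Tukey-adjusted pairwise contrasts, sum-coded
grammatical-unit models for per-half surprisal and (beta-family)
rates, backwards selection for the surprisal-difference interaction
model, and the floor-transfer-offset model.

Estimation is delegated to statsmodels (``MixedLM`` for linear mixed
models, ``BetaModel`` for the rate model); the formulas, coding
schemes, comparison logic and decision rules live here. Random
structure is intercept-only with speaker nested in dyad (random slopes
are omitted by default; they are prone to singular fits at these
designs). Every LRT compares nested models fit by ML (not REML) on
identical rows, so χ² ≥ 0 always.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.othermod.betareg import BetaModel
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelComparisonResult",
    "ContrastResult",
    "FtoModelResults",
    "BONFERRONI_ALPHA",
    "half_long_table",
    "lrt_half_effect",
    "half_effect_estimate",
    "cross_language_model",
    "unit_surprisal_model",
    "unit_rate_model",
    "backwards_select",
    "fto_model",
    "squeeze_unit_interval",
]

#: Per-language alpha after Bonferroni correction across the six
#: language corpora: 0.05 / 6 ≈ 0.008.
BONFERRONI_ALPHA = 0.008

_NESTED_VC = {"speaker": "0 + C(speaker)"}


@dataclass
class ModelComparisonResult:
    """Outcome of one nested-model likelihood-ratio comparison."""

    model_label: str
    chisq: float
    df: int
    p_value: float
    fixed_effects: dict[str, tuple[float, float, float]]  # term -> (est, se, t)
    alpha_used: float
    converged: bool
    n_obs: int = 0
    steps: list[dict] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_used

    def __post_init__(self) -> None:
        if self.chisq < -1e-8:
            raise ValueError(f"negative LRT statistic: {self.chisq}")
        self.chisq = max(0.0, self.chisq)


@dataclass(frozen=True)
class ContrastResult:
    """One Tukey-adjusted pairwise contrast between groups."""

    pair: tuple[str, str]
    estimate: float
    se: float
    z_ratio: float
    adjusted_p: float
    adjustment: str = "tukey"


@dataclass
class FtoModelResults:
    """Loading-group and surprisal-half FTO model comparisons."""

    group: ModelComparisonResult
    surprisal_halves: ModelComparisonResult


def _check_grouping(data: pd.DataFrame) -> None:
    if data["dyad"].nunique() < 2:
        raise ValueError(
            "mixed model requires at least 2 dyads; refusing to silently drop "
            "the random-effects structure"
        )


def _fit_mixed(formula: str, data: pd.DataFrame, nested_speaker: bool = True):
    """ML fit of a linear mixed model with dyad (and speaker-in-dyad) intercepts."""
    vc = _NESTED_VC if nested_speaker else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(
            formula,
            data,
            groups=data["dyad"],
            re_formula="1",
            vc_formula=vc,
        )
        # Powell reliably reaches the optimum when variance components
        # sit on the zero boundary, where gradient methods stall early.
        res = model.fit(reml=False, method="powell", maxiter=2000, disp=False)
    return res


def _fixed_effects(res) -> dict[str, tuple[float, float, float]]:
    out = {}
    with warnings.catch_warnings():
        # boundary variance estimates can make some SEs NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        for term in res.fe_params.index:
            est = float(res.fe_params[term])
            se = float(res.bse_fe[term])
            out[term] = (est, se, est / se if se > 0 else np.nan)
    return out


def _lrt(res_null, res_alt, df: int) -> tuple[float, float]:
    chisq = max(0.0, 2.0 * float(res_alt.llf - res_null.llf))
    return chisq, float(stats.chi2.sf(chisq, df))


def half_long_table(loading_table: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide loading table into one row per utterance-half.

    The response column is ``mean_surprisal`` and ``half`` is
    ``first``/``last``; identifier columns are carried along.
    """
    id_cols = [
        c
        for c in ("language", "dyad", "speaker", "conversation_id", "utterance_id", "n_words")
        if c in loading_table.columns
    ]
    long = loading_table.melt(
        id_vars=id_cols,
        value_vars=["mean_first", "mean_last"],
        var_name="half",
        value_name="mean_surprisal",
    )
    long["half"] = long["half"].map({"mean_first": "first", "mean_last": "last"})
    return long.sort_values(id_cols + ["half"]).reset_index(drop=True)


def lrt_half_effect(
    long_table: pd.DataFrame,
    language: str | None = None,
    alpha: float = BONFERRONI_ALPHA,
) -> ModelComparisonResult:
    """Per-language test of the utterance-half effect on mean surprisal.

    Compares, by LRT, a null mixed model (response = per-half mean
    surprisal, fixed effect of number of words, dyad/speaker nested
    random intercepts) against the same model plus utterance half.
    A positive half estimate means back-loading (last > first). The
    default alpha is the Bonferroni-corrected 0.008 used when the test
    runs across six languages.
    """
    data = long_table if language is None else long_table[long_table["language"] == language]
    data = data.dropna(subset=["mean_surprisal"]).copy()
    _check_grouping(data)
    res0 = _fit_mixed("mean_surprisal ~ n_words", data)
    res1 = _fit_mixed("mean_surprisal ~ n_words + C(half, Treatment('first'))", data)
    chisq, p = _lrt(res0, res1, df=1)
    return ModelComparisonResult(
        model_label=f"half_effect[{language or data['language'].iloc[0]}]",
        chisq=chisq,
        df=1,
        p_value=p,
        fixed_effects=_fixed_effects(res1),
        alpha_used=alpha,
        converged=bool(res0.converged and res1.converged),
        n_obs=len(data),
    )


def half_effect_estimate(result: ModelComparisonResult) -> float:
    """The utterance-half fixed-effect estimate (last − first) of a fit."""
    for term, (est, _, _) in result.fixed_effects.items():
        if "half" in term and "[T." in term:
            return est
    raise KeyError("no utterance-half term in fixed effects")


def _tukey_p(z: float, k: int, df: float) -> float:
    # Tukey adjustment over the family of all k(k-1)/2 pairwise
    # contrasts: refer |z|*sqrt(2) to the studentized range.
    q = abs(z) * np.sqrt(2.0)
    return float(np.clip(stats.studentized_range.sf(q, k, df), 0.0, 1.0))


def cross_language_model(
    diff_table: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[ModelComparisonResult, list[ContrastResult]]:
    """Cross-language model of the surprisal difference Δ.

    Tests, by LRT, whether language predicts Δ (last-half minus
    first-half mean surprisal per utterance) over a base model with
    (centered) words-per-utterance and dyad/speaker nested intercepts,
    then computes all pairwise language contrasts with Tukey-adjusted
    p values and z ratios.
    """
    data = diff_table.dropna(subset=["diff"]).copy()
    langs = sorted(data["language"].unique())
    if len(langs) < 2:
        raise ValueError("cross-language model requires at least 2 languages")
    _check_grouping(data)
    data["n_words_c"] = data["n_words"] - data["n_words"].mean()
    res0 = _fit_mixed("diff ~ n_words_c", data)
    res1 = _fit_mixed("diff ~ n_words_c + C(language)", data)
    k = len(langs)
    chisq, p = _lrt(res0, res1, df=k - 1)
    comparison = ModelComparisonResult(
        model_label="cross_language_diff",
        chisq=chisq,
        df=k - 1,
        p_value=p,
        fixed_effects=_fixed_effects(res1),
        alpha_used=alpha,
        converged=bool(res0.converged and res1.converged),
        n_obs=len(data),
    )

    # pairwise contrasts from the treatment-coded language coefficients
    fe = res1.fe_params
    cov = res1.cov_params().loc[fe.index, fe.index]
    coef = {langs[0]: 0.0}
    names: dict[str, str | None] = {langs[0]: None}
    for lang in langs[1:]:
        term = f"C(language)[T.{lang}]"
        coef[lang] = float(fe[term])
        names[lang] = term
    df_resid = max(float(len(data) - len(fe)), 1.0)
    contrasts = []
    for la, lb in itertools.combinations(langs, 2):
        vec = pd.Series(0.0, index=fe.index)
        if names[la] is not None:
            vec[names[la]] = 1.0
        if names[lb] is not None:
            vec[names[lb]] -= 1.0
        est = float(coef[la] - coef[lb])
        se = float(np.sqrt(vec @ cov @ vec))
        z = est / se if se > 0 else np.nan
        contrasts.append(
            ContrastResult(
                pair=(la, lb),
                estimate=est,
                se=se,
                z_ratio=z,
                adjusted_p=_tukey_p(z, k, df_resid),
            )
        )
    return comparison, contrasts


def _sum_coded(term: str) -> str:
    return f"C({term}, Sum)"


def unit_surprisal_model(
    unit_table: pd.DataFrame,
    alpha: float = 0.05,
) -> ModelComparisonResult:
    """Stepwise-forward model of per-half grammatical-unit surprisal.

    Response: mean unit surprisal per utterance half for NOUN and VERB
    rows. Predictors (sum coded) are added step-wise — grammatical
    unit, loading group (front/back), utterance half, then the two-way
    interaction block, then the three-way interaction — with an LRT at
    every step; non-significant additions are left out. The returned
    comparison is the final accepted step's LRT, with the whole trail
    in ``steps``.
    """
    data = unit_table.dropna(subset=["mean_unit_surprisal"]).copy()
    _check_grouping(data)
    u, g, h = _sum_coded("unit"), _sum_coded("loading_group"), _sum_coded("half")
    step_terms = [
        ([u], "grammatical_unit"),
        ([g], "loading_group"),
        ([h], "utterance_half"),
        ([f"{u}:{g}", f"{u}:{h}", f"{g}:{h}"], "two_way_interactions"),
        ([f"{u}:{g}:{h}"], "three_way_interaction"),
    ]
    current_terms: list[str] = []
    current = _fit_mixed("mean_unit_surprisal ~ 1", data)
    steps = []
    last_chisq, last_df, last_p = 0.0, 1, 1.0
    for terms, label in step_terms:
        candidate_terms = current_terms + terms
        cand = _fit_mixed("mean_unit_surprisal ~ " + " + ".join(candidate_terms), data)
        chisq, p = _lrt(current, cand, df=len(terms))
        accepted = p < alpha
        steps.append(
            {"step": label, "chisq": chisq, "df": len(terms), "p": p, "accepted": accepted}
        )
        if accepted:
            current_terms, current = candidate_terms, cand
            last_chisq, last_df, last_p = chisq, len(terms), p
    return ModelComparisonResult(
        model_label="unit_surprisal_stepwise",
        chisq=last_chisq,
        df=last_df,
        p_value=last_p,
        fixed_effects=_fixed_effects(current),
        alpha_used=alpha,
        converged=bool(current.converged),
        n_obs=len(data),
        steps=steps,
    )


def squeeze_unit_interval(y: np.ndarray) -> np.ndarray:
    """Compress proportions into the open interval (0, 1).

    The standard (y·(n−1) + 0.5)/n transformation, so a beta family
    can be fit to data containing exact 0s and 1s.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    return (y * (n - 1) + 0.5) / n


def unit_rate_model(
    unit_table: pd.DataFrame,
    alpha: float = 0.05,
) -> ModelComparisonResult:
    """Beta-family model of per-half grammatical-unit rates.

    Rates (unit count over words in the half) are squeezed into (0, 1)
    and fit with a logit-link beta regression on the sum-coded
    grammatical unit × loading group × utterance half factorial; the
    LRT compares the full factorial against main effects only (the
    interaction structure, 4 df). This model is fixed-effects only:
    no beta-family mixed estimator is available, so the dyad/speaker
    intercepts of the other models are omitted here.
    """
    data = unit_table.copy()
    data["rate_sq"] = squeeze_unit_interval(data["rate"].to_numpy())
    u, g, h = _sum_coded("unit"), _sum_coded("loading_group"), _sum_coded("half")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_full = BetaModel.from_formula(f"rate_sq ~ {u} * {g} * {h}", data).fit(disp=False)
        res_main = BetaModel.from_formula(f"rate_sq ~ {u} + {g} + {h}", data).fit(disp=False)
    chisq = max(0.0, 2.0 * float(res_full.llf - res_main.llf))
    p = float(stats.chi2.sf(chisq, 4))
    fe = {}
    for term in res_full.params.index:
        if term.startswith("precision"):
            continue
        est = float(res_full.params[term])
        se = float(res_full.bse[term])
        fe[term] = (est, se, est / se if se > 0 else np.nan)
    return ModelComparisonResult(
        model_label="unit_rate_beta",
        chisq=chisq,
        df=4,
        p_value=p,
        fixed_effects=fe,
        alpha_used=alpha,
        converged=bool(getattr(res_full, "mle_retvals", {}).get("converged", True)),
        n_obs=len(data),
    )


def unit_diff_table(unit_table: pd.DataFrame, loading_table: pd.DataFrame) -> pd.DataFrame:
    """Join per-half unit statistics with the utterance-level Δ.

    Produces the input of :func:`backwards_select`: one row per
    utterance-half-unit with columns diff, rate, surprisal (the unit's
    mean surprisal in that half), half, unit, dyad, speaker.
    """
    left = unit_table.rename(columns={"mean_unit_surprisal": "surprisal"})
    right = loading_table[["utterance_id", "diff"]]
    out = left.merge(right, on="utterance_id", how="inner")
    return out[
        ["language", "dyad", "speaker", "utterance_id", "half", "unit", "rate", "surprisal", "diff"]
    ]


def _interaction_terms(mains: list[str]) -> list[str]:
    terms = list(mains)
    for order in (2, 3, 4):
        for combo in itertools.combinations(mains, order):
            terms.append(":".join(combo))
    return terms


def backwards_select(
    data: pd.DataFrame,
    alpha: float = 0.05,
) -> ModelComparisonResult:
    """Backwards model building for the surprisal-difference model.

    Starts from the full model — response Δ (per-utterance surprisal
    difference); fixed effects rate, word surprisal, utterance half
    and grammatical unit plus all 2-, 3- and 4-way interactions;
    dyad/speaker nested random intercepts — and repeatedly removes the
    candidate term with the lowest contribution (smallest log-
    likelihood drop per degree of freedom on removal), respecting
    marginality: a term is removable only while no retained higher-
    order interaction contains it. A removal is kept when the LRT
    against the retaining model is non-significant; the first
    significant removal stops the search. The reported comparison is
    the final model against the random-effects-only base.

    Expected columns: diff, rate, surprisal, half, unit, dyad, speaker.
    """
    data = data.dropna(subset=["diff", "rate", "surprisal"]).copy()
    _check_grouping(data)
    mains = ["rate", "surprisal", _sum_coded("half"), _sum_coded("unit")]
    terms = _interaction_terms(mains)
    removed: list[str] = []

    def fit(term_list: list[str]):
        rhs = " + ".join(term_list) if term_list else "1"
        return _fit_mixed("diff ~ " + rhs, data)

    current = fit(terms)
    steps = []
    while terms:
        # marginality: only terms not nested inside a retained interaction
        candidates = [
            t
            for t in terms
            if not any(
                set(t.split(":")) < set(other.split(":")) for other in terms if other != t
            )
        ]
        fits = {t: fit([x for x in terms if x != t]) for t in candidates}
        contrib = {t: float(current.llf - fits[t].llf) for t in candidates}
        weakest = min(candidates, key=lambda t: (contrib[t], t))
        chisq = max(0.0, 2.0 * contrib[weakest])
        p = float(stats.chi2.sf(chisq, 1))
        steps.append({"term": weakest, "chisq": chisq, "df": 1, "p": p, "removed": p >= alpha})
        if p >= alpha:
            terms = [t for t in terms if t != weakest]
            removed.append(weakest)
            current = fits[weakest]
        else:
            break
    base = fit([])
    chisq, p = _lrt(base, current, df=max(len(terms), 1))
    return ModelComparisonResult(
        model_label="surprisal_diff_backwards",
        chisq=chisq,
        df=max(len(terms), 1),
        p_value=p,
        fixed_effects=_fixed_effects(current),
        alpha_used=alpha,
        converged=bool(current.converged),
        n_obs=len(data),
        steps=steps,
    )


def fto_model(
    fto_table: pd.DataFrame,
    alpha: float = 0.05,
) -> FtoModelResults:
    """Floor-transfer-offset models.

    ``group``: LRT for front/back loading group (treatment coded with
    back-loaded = 0, front-loaded = 1) over a base model with number
    of words and a dyad random intercept — a negative front-loaded
    estimate means back-loaded languages have longer FTOs.
    ``surprisal_halves``: LRT (2 df) for adding the mean surprisal of
    the preceding utterance's first and last halves, on the rows where
    those are available.
    """
    data = fto_table.dropna(subset=["fto_ms", "n_words"]).copy()
    _check_grouping(data)
    res0 = _fit_mixed("fto_ms ~ n_words", data, nested_speaker=False)
    res1 = _fit_mixed(
        "fto_ms ~ n_words + C(loading_group, Treatment('back'))", data, nested_speaker=False
    )
    chisq, p = _lrt(res0, res1, df=1)
    group = ModelComparisonResult(
        model_label="fto_loading_group",
        chisq=chisq,
        df=1,
        p_value=p,
        fixed_effects=_fixed_effects(res1),
        alpha_used=alpha,
        converged=bool(res0.converged and res1.converged),
        n_obs=len(data),
    )
    surp = data.dropna(subset=["mean_first", "mean_last"]).copy()
    _check_grouping(surp)
    res2 = _fit_mixed("fto_ms ~ n_words", surp, nested_speaker=False)
    res3 = _fit_mixed("fto_ms ~ n_words + mean_first + mean_last", surp, nested_speaker=False)
    chisq2, p2 = _lrt(res2, res3, df=2)
    halves = ModelComparisonResult(
        model_label="fto_surprisal_halves",
        chisq=chisq2,
        df=2,
        p_value=p2,
        fixed_effects=_fixed_effects(res3),
        alpha_used=alpha,
        converged=bool(res2.converged and res3.converged),
        n_obs=len(surp),
    )
    return FtoModelResults(group=group, surprisal_halves=halves)
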