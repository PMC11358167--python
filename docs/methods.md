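# Methods

`infodist` measures how information is distributed *within* spoken
utterances in dyadic conversation, and whether that distribution
relates to part-of-speech composition and turn-transition timing. This
note documents the model and procedure, the synthetic-data generator
that stands in for licensed conversational corpora, the numerical
choices, and the limits of what the package's tests demonstrate.

## The measurement model

**Surprisal.** Each language corpus gets its own unsmoothed
second-order Markov (trigram) word model, estimated by maximum
likelihood over the cleaned utterances of that corpus. Counts restart
at every utterance boundary; no padding symbols are introduced. The
surprisal of word *i* in an utterance is

    s(w_i) = −log₂ P(w_i | w_{i−2}, w_{i−1})        [bits]

with `P` the raw count ratio. The first word of an utterance has no
trigram context and is scored from unigram relative frequency, the
second from bigram frequency; both carry a reduced-context flag and
are excluded from all half averages. Because the model scores the same
corpus it was trained on, every scored event has count ≥ 1 and
surprisal is finite; held-out scoring is possible only through an
explicit unseen-event policy (raise, or an infinite-surprisal sentinel
that excludes the utterance from aggregation). Log base 2 is the
default; base *e* is available, and nats = bits × ln 2 exactly, so all
sign conclusions are base-invariant.

**Filtering and the half split.** Utterances with fewer than 8 lexical
tokens or shorter than 600 ms are excluded *after* training (training
uses everything; only the analysis set is subset). Both thresholds
keep their boundary values. The half split is a simple count split:
first half = tokens 1..⌊n/2⌋, last half = the rest, so 8 tokens split
4/4 and 9 tokens split 4/5. The 8-token floor guarantees at least two
full-context trigram values per half (windows 1–3 and 2–4 in the
first half; 5–7 and 6–8 in the last).

**The loading statistic.** Per utterance,

    Δ = mean s(last half) − mean s(first half, excluding tokens 1–2).

Δ > 0 is back-loading (information concentrated late), Δ < 0
front-loading.

**Grammatical units.** Universal-POS tags attach through a pluggable
tagger interface (any callable mapping tokens to an equal-length UPOS
sequence; synthetic corpora carry ground-truth tags). For each
utterance half and unit (NOUN, VERB): rate = unit count ÷ words in
that half (a per-utterance denominator is available as a config
switch; the per-half definition is the default because the field's
worked convention divides by the words of the half), and mean unit
surprisal averages the unit's tokens in that half, excluding the two
reduced-context tokens from the average while still counting their
tags toward the rate.

**Turn timing.** The floor transfer offset (FTO) of a speaker change
is `next.start − prev.end` in ms for adjacent utterances (start-time
order) with different speakers; negative values are overlaps.
Same-speaker adjacencies yield no transition, and each cross-speaker
adjacency is treated independently (no merging of multi-utterance
turns). The FTO table carries the *preceding* utterance's half-mean
surprisals — the turn being responded to. No trimming is used in
analysis; ±2 SD trimming exists for plots only.

## Inference

All model comparisons are likelihood-ratio tests between nested
models fit by maximum likelihood (never REML) on identical rows.
Random structure is intercept-only with speaker nested in dyad
(statsmodels `MixedLM`, `groups=dyad`, variance component for
speaker); random slopes are omitted by default because they produce
singular fits at these designs.

- **Per-language half effect:** response = per-half mean surprisal
  (two rows per utterance), fixed effect of word count, plus/minus
  utterance half; α = 0.05/6 = 0.008 when run across six languages
  (Bonferroni). The half estimate's sign classifies the language.
- **Cross-language model:** response = Δ per utterance, fixed effects
  centered word count and language; the language LRT has k−1 df.
  Pairwise language contrasts are built from the treatment-coded
  coefficients and their covariance; the family of all k(k−1)/2
  contrasts is Tukey-adjusted by referring |z|·√2 to the studentized
  range with residual degrees of freedom.
- **Unit surprisal (stepwise forward):** sum-coded unit, loading
  group, and half are added one at a time, then the two-way block,
  then the three-way term, with an LRT at each step; non-significant
  additions stay out.
- **Unit rate (beta family):** rates are squeezed into (0, 1) by
  (y·(n−1)+0.5)/n and fit with a logit-link beta regression
  (statsmodels `BetaModel`) on the full sum-coded factorial; the
  reported LRT compares the factorial against main effects (4 df).
  This is the one fixed-effects-only model in the package: no
  beta-family mixed estimator is available in this stack, so the
  dyad/speaker intercepts used elsewhere are omitted here. At the
  tested designs (hundreds of dyads contributing balanced rows) the
  interaction LRT is driven by the within-utterance contrast and this
  omission mainly costs some variance accounting; it is a known
  limitation.
- **Backwards selection (Δ model):** the full model contains rate,
  word surprisal, half, and unit with all 2-, 3- and 4-way
  interactions. "Lowest explained variance" is operationalized as the
  smallest log-likelihood drop per degree of freedom upon removal,
  among terms not contained in any retained higher-order interaction.
  Removal is kept when its LRT is non-significant; the first
  significant removal stops the search, and the final model is
  compared against the random-effects-only base. Note that with ~11
  null terms tested at α = 0.05, stopping early on a chance hit is
  expected in a sizeable fraction of null runs; this is inherent to
  stop-at-first-significant selection, not an implementation defect.
- **FTO model:** response FTO, fixed effect word count, dyad random
  intercept; the loading-group term is treatment coded with
  back-loaded = 0. A second comparison adds the preceding utterance's
  first- and last-half mean surprisals (2 df).

Degenerate inputs fail loudly: a single-dyad table raises rather than
silently dropping the random structure.

**Optimizer.** MixedLM fits use Powell search. With synthetic data the
dyad/speaker variance components are genuinely zero, so the ML optimum
sits on the boundary of the parameter space, where gradient-based
optimizers (L-BFGS, BFGS, CG) stop short of the optimum and report
failure; Powell reaches the boundary reliably and its likelihoods
dominate the gradient methods' in direct comparison. Fits are
deterministic, so all outputs are bit-reproducible.

## The synthetic-data generator

The generator produces dyadic conversations with strictly alternating
speakers, durations from a constant speech rate (default 3 words/s),
Gaussian inter-turn gaps with a per-condition mean (overlaps allowed),
utterance lengths `min + Binomial(max−min, p)` straddling the 8-token
threshold (defaults 4–22, mean ≈ 13, in the range of conversational
transcripts), and aligned ground-truth UPOS tags. Its purpose is to
give every pipeline stage a testable input with *known* per-token
information content.

**Why the emission process looks the way it does.** Information
loading is realized as an entropy contrast between two conditional
word families — sparse and dense — over disjoint sub-vocabularies, so
each token's true surprisal is a closed-form function of its realized
context. Within a family, emission cycles through phases
`content, linker, linker`: a content word is drawn as the
class-conditional *head* word with probability `a`, else from a fixed
Zipf tail over the family's other content words; linkers come from a
small 8-word set (head linker with probability `b`, else uniform).
The conditioning class is carried by the immediately preceding word,
so the true conditional distribution of every token is identified by
its visible one-word history, and a trigram model — which conditions
on two words — can recover it. Two properties of this construction
matter:

1. *Exact calibration.* Head masses are solved numerically (Brent)
   so content and linker conditional entropies sit exactly
   `delta_bits/2` above and below their baselines (defaults 3.3 and
   1.3 bits) in the dense and sparse families. The dense family
   governs the last half (back loading), the first half (front), or
   is absent (flat: a single family, hence an exact null). The
   expected Δ is therefore exactly ±`delta_bits` at every position,
   and a per-utterance random phase offset keeps the content/linker
   composition of the two halves exchangeable, so the calibration
   survives the count-based split. Infeasible contrasts (beyond the
   vocabulary's entropy budget) raise a config error naming the
   feasible maximum.
2. *Estimability.* High-entropy (content) draws always follow a
   frequent two-linker context, and rare tail words are followed only
   by low-entropy linker draws. This keeps the count tables of an
   unsmoothed ML trigram model dense where it matters: estimated and
   true surprisal correlate at r ≈ 0.92 on a 5,000-utterance corpus.
   A flat Zipf-conditional process of the same size is *not*
   recoverable at that fidelity (r ≈ 0.75 in our measurements) —
   ML trigram estimation needs repeated contexts, which real
   conversational language supplies through its function-word
   scaffolding and the generator supplies through linkers.

The only model misspecification is the single sparse/dense boundary
inside each utterance (the trigram model cannot know the switch
position), which costs roughly one boundary token's worth of
estimation error per utterance and attenuates the *estimated* Δ
slightly toward zero relative to the true Δ; signs and orderings are
unaffected.

POS labels are drawn position-dependently (content positions
open-class-heavy, linker positions closed-class), with a configurable
NOUN/VERB rate increment in the dense half and an optional
verb–surprisal coupling that tilts VERB labels toward high-surprisal
tokens. Optional filler injection ("uh") exercises the cleaning
stage; ground truth aligns with the filler-free token sequence, which
is exactly what cleaning restores.

**What the generator does not emulate:** morphology, syntax, word
order in any linguistic sense, backchannels, question structure, and
retroactive grammatical modification. Passing tests therefore show
that the *pipeline* measures, classifies and tests information
loading correctly when the signal is present as specified — they do
not validate claims about any natural language.

**Reference conditions.** The canonical six-language suite uses three
back-loaded and three front-loaded languages at δ = 0.5 bits — the
same order of magnitude as per-word half contrasts observed in
conversational corpora — with 50 dyads × 40 utterances per language,
a +100 ms FTO shift for the back-loaded group (inter-turn means
300 vs. 200 ms, SD 150 ms, matching typical turn-transition scales),
NOUN/VERB enrichment of 0.05 and verb–surprisal coupling 0.3 in the
dense half. The null suite is six flat languages of 40 dyads × 20
utterances with every effect zero.

## Problem sizes used in tests

The test suite regenerates data rather than shipping it. The heavier
checks run at: surprisal recovery, 5,000 utterances (one corpus);
sign recovery, 20 replicates of the six-language reference suite
(120 language-runs, ~2,000 utterances each); type-I calibration,
400 null corpora of 40 dyads × 20 utterances; FTO recovery, ~20,000
transitions. These sizes were chosen so each Monte-Carlo bound has
comfortable sampling margin while the whole suite completes in a few
minutes on one core.

## Known limitations

- ML trigram probabilities are biased for sparse contexts; the
  package deliberately matches the unsmoothed count-ratio definition
  rather than adding smoothing, so corpus-size effects on estimated Δ
  (attenuation) are inherited by design.
- The beta rate model omits random intercepts (see above).
- Tukey adjustment uses the normal-theory studentized range with
  residual df rather than Satterthwaite/Kenward-Roger df.
- The transcript dialect is deliberately minimal (TSV/JSONL);
  corpus-vendor markup must be converted upstream, and only the
  configurable annotation-pattern/filler lists are applied during
  cleaning.
- FTO analysis treats every cross-speaker adjacency independently;
  multi-unit turns are not merged.
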