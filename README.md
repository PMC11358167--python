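# infodist

Utterance-level information distribution analysis for conversational
corpora: trigram surprisal, front/back loading, grammatical-unit
rates, turn-transition timing, and mixed-model inference — with a
calibrated synthetic dialogue generator so the whole pipeline is
testable without licensed corpus data.

## The problem

In dialogue, words arrive one at a time and listeners process them
while already planning their own next turn. Where a speaker puts the
informative words inside an utterance — early (*front-loaded*) or
late (*back-loaded*) — may therefore shape both comprehension and
turn-taking, and languages appear to differ systematically in this
respect. `infodist` implements the full analysis chain for asking
such questions of time-aligned, speaker-attributed transcripts:

1. **Surprisal.** Per corpus, an unsmoothed trigram (second-order
   Markov) model is trained on the cleaned utterances, and each word
   is scored with s(wᵢ) = −log₂ P(wᵢ | wᵢ₋₂, wᵢ₋₁) bits. The first
   two words of an utterance have reduced context and are flagged.
2. **Loading.** Utterances with ≥ 8 lexical tokens and ≥ 600 ms are
   split in half by word count, and the statistic
   Δ = mean s(last half) − mean s(first half, excluding words 1–2)
   summarizes each utterance: Δ > 0 is back-loading.
3. **Grammatical units.** With universal-POS tags attached (pluggable
   tagger; synthetic corpora carry ground truth), per-half NOUN/VERB
   rates (count ÷ words in the half) and unit mean surprisals.
4. **Turn timing.** Floor transfer offsets (FTO = next start − prev
   end, negative for overlap) for every speaker change.
5. **Inference.** Mixed-effects model comparisons via likelihood-
   ratio tests: per-language half effects at Bonferroni α = 0.008,
   a cross-language Δ model with Tukey-adjusted pairwise contrasts,
   sum-coded unit surprisal/rate models (beta family for rates),
   backwards selection for the Δ interaction model, and the FTO
   group model.

The synthetic generator produces dyadic conversations whose per-token
true surprisal is known in closed form, with a configurable entropy
contrast `delta_bits` between utterance halves, POS enrichment, and
per-condition turn-gap distributions — the ground truth every
recovery and calibration test is scored against.

## A worked example

```python
from infodist import (GeneratorConfig, generate_corpus, train_trigram_model,
                      filter_utterances, corpus_loading_table, inference)

config = GeneratorConfig(language_label="demo_back", n_dyads=20,
                         utterances_per_conversation=50,
                         loading_mode="back", delta_bits=0.5, seed=11)
corpus, truth = generate_corpus(config)
model = train_trigram_model(corpus)
table = corpus_loading_table(filter_utterances(corpus), model)
print(table["diff"].mean())

long = inference.half_long_table(table)
result = inference.lrt_half_effect(long)
print(result.chisq, result.p_value, inference.half_effect_estimate(result))
```

This prints a mean Δ of `+0.326` bits for the estimated loading
(ground truth `+0.481`, configured contrast `+0.5`; maximum-likelihood
trigram estimates attenuate high-entropy halves slightly), then the
mixed-model comparison `χ²(1) = 117.7, p ≈ 2e-27, estimate = +0.326`:
the language is classified back-loaded, exactly as generated. The
`examples/` directory holds one short narrative script per
capability — surprisal basics, the loading statistic, per-language
inference, POS rates, turn timing, and the end-to-end pipeline — each
printing the numbers it computes and what they mean.

A thin CLI wraps the same pipeline:

```bash
infodist generate --fixture reference --outdir corpora
infodist analyze --generate reference --seed 1 --outdir run1
infodist report run1
infodist simulate-calibration --suite type1 --n 100
```

`analyze` writes `loading_table.csv`, `unit_stats.csv`,
`fto_table.csv`, `inference_report.csv` and a `manifest.json` with
the config hash, seed, versions, and per-stage utterance counts.

## Layout

```
src/infodist/
  corpus.py      transcript types, TSV/JSONL I/O, cleaning
  trigram.py     trigram models and surprisal
  loading.py     filtering, half split, Δ statistic
  pos.py         UPOS tagging interface, unit rates/surprisal
  timing.py      floor transfer offsets
  inference.py   mixed-model LRT workflows
  synthetic.py   calibrated dialogue generator with ground truth
  calibration.py Monte-Carlo recovery/calibration suites
  pipeline.py    end-to-end orchestration
  cli.py         thin command-line interface
docs/methods.md  model, assumptions, numerical choices, limitations
examples/        one narrative script per capability
```
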