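"""Measure front/back loading on a synthetic back-loaded language.

Generates a corpus whose last utterance halves carry 0.5 bits more
information per word than the first halves, runs the filter → split →
half-statistics pipeline, and prints the mean surprisal difference Δ
(last-half mean minus first-half mean). A positive Δ means the
language back-loads information. The ground-truth Δ sits at the
configured +0.5 bits; the trigram *estimate* of Δ is attenuated
somewhat at this modest corpus size because maximum-likelihood
probabilities shrink high-entropy contexts.
"""

import numpy as np

from infodist import (
    GeneratorConfig,
    corpus_loading_table,
    filter_utterances,
    generate_corpus,
    train_trigram_model,
)

config = GeneratorConfig(
    language_label="demo_back",
    n_dyads=20,
    utterances_per_conversation=50,
    loading_mode="back",
    delta_bits=0.5,
    seed=11,
)
corpus, truth = generate_corpus(config)
model = train_trigram_model(corpus)
filtered = filter_utterances(corpus)
table = corpus_loading_table(filtered, model)

print(f"utterances analyzed: {len(table)} (of {corpus.n_utterances} generated)")
print(f"mean first-half surprisal: {table['mean_first'].mean():.3f} bits")
print(f"mean last-half surprisal:  {table['mean_last'].mean():.3f} bits")
true_diffs = []
for utt in filtered.utterances():
    ts = truth.surprisal[utt.utterance_id]
    cut = len(ts) // 2
    true_diffs.append(np.mean(ts[cut:]) - np.mean(ts[2:cut]))

print(f"estimated Δ: {table['diff'].mean():+.3f} bits")
print(f"ground-truth Δ: {np.mean(true_diffs):+.3f} bits "
      f"(configured contrast: +{config.delta_bits})")
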