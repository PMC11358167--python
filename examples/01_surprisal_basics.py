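"""Train a trigram model on a toy corpus and read off word surprisal.

Builds a four-utterance corpus by hand, trains an unsmoothed trigram
model, and scores one utterance. The printed surprisal values are in
bits: after "a b", the continuations "c" and "d" each occur twice out
of four, so P = 0.5 and the surprisal is exactly 1 bit; the first two
words are scored from unigram/bigram frequency and flagged as
reduced-context.
"""

from infodist import Conversation, Corpus, Utterance, train_trigram_model, utterance_surprisal


def utt(i, tokens):
    return Utterance(
        conversation_id="c1", dyad_id="d1", speaker_id="ab"[i % 2],
        start=i * 2000, end=i * 2000 + 1500, tokens=tuple(tokens),
    )


token_lists = [["a", "b", "c"], ["a", "b", "c"], ["a", "b", "d"], ["a", "b", "d"]]
conv = Conversation(
    conversation_id="c1", dyad_id="d1",
    utterances=tuple(utt(i, t) for i, t in enumerate(token_lists)),
)
corpus = Corpus(language_label="toy", conversations=(conv,))

model = train_trigram_model(corpus)
seq = utterance_surprisal(model, conv.utterances[0])

print(f"context count (a, b): {model.context_counts[('a', 'b')]}")
print(f"continuation count (a, b, c): {model.continuation_counts[('a', 'b', 'c')]}")
for token, value, complete in zip(seq.utterance.tokens, seq.values, seq.context_complete):
    ctx = "full trigram" if complete else "reduced context"
    print(f"  s({token!r}) = {value:.3f} bits  [{ctx}]")
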