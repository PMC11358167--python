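"""Trigram (second-order Markov) word models and per-word surprisal.

A trigram model tabulates, per corpus, how often each word follows each
two-word context, with counts restarting at every utterance boundary
(no trigram spans two utterances and no padding symbols are used).
Probabilities are maximum-likelihood count ratios — the model is meant
to score the corpus it was trained on, where every event has count ≥ 1,
so no smoothing is applied. The surprisal of a word is the negative log
of its conditional probability,

    s(w_i) = -log P(w_i | w_{i-2}, w_{i-1}),

in bits for log base 2 (the default) or nats for base e. The first word
of an utterance has no preceding context and is scored from unigram
relative frequency; the second is scored from bigram frequency; both
carry a ``context_complete=False`` flag so downstream analyses can
exclude them.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from infodist.corpus import Corpus, Utterance

__all__ = [
    "TrigramModel",
    "SurprisalSequence",
    "UnseenNgramError",
    "train_trigram_model",
    "conditional_probability",
    "utterance_surprisal",
    "score_corpus",
]

_SERIAL_VERSION = 1


class UnseenNgramError(KeyError):
    """Raised when scoring an n-gram never observed in training."""


@dataclass
class TrigramModel:
    """Count tables and ML probabilities for a trained trigram model.

    ``context_counts[(w2, w1)]`` is the total number of continuations
    observed after the pair, and equals the sum of
    ``continuation_counts[(w2, w1, w)]`` over continuations ``w``.
    Lower-order tables serve the reduced-context scoring of utterance-
    initial words.
    """

    context_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    continuation_counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    bigram_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    bigram_context_counts: dict[str, int] = field(default_factory=dict)
    unigram_counts: dict[str, int] = field(default_factory=dict)
    total_tokens: int = 0
    log_base: float = 2.0

    def _log(self, p: float) -> float:
        if self.log_base == 2.0:
            return math.log2(p)
        return math.log(p) / math.log(self.log_base)

    def surprisal_of(self, p: float) -> float:
        """Convert a probability to surprisal in the model's log base."""
        value = -self._log(p)
        return 0.0 if value == 0.0 else value  # avoid -0.0 for p = 1

    # -- serialization ------------------------------------------------

    def to_json(self, path: str | Path) -> Path:
        """Serialize counts to a versioned JSON file with sorted keys."""
        path = Path(path)
        payload = {
            "format_version": _SERIAL_VERSION,
            "log_base": self.log_base,
            "total_tokens": self.total_tokens,
            "unigram_counts": {w: c for w, c in sorted(self.unigram_counts.items())},
            "bigram_counts": {
                " ".join(k): c for k, c in sorted(self.bigram_counts.items())
            },
            "bigram_context_counts": {
                w: c for w, c in sorted(self.bigram_context_counts.items())
            },
            "context_counts": {
                " ".join(k): c for k, c in sorted(self.context_counts.items())
            },
            "continuation_counts": {
                " ".join(k): c for k, c in sorted(self.continuation_counts.items())
            },
        }
        path.write_text(json.dumps(payload, ensure_ascii=False, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TrigramModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != _SERIAL_VERSION:
            raise ValueError(f"unsupported model format: {payload.get('format_version')}")
        return cls(
            context_counts={tuple(k.split(" ")): c for k, c in payload["context_counts"].items()},
            continuation_counts={
                tuple(k.split(" ")): c for k, c in payload["continuation_counts"].items()
            },
            bigram_counts={tuple(k.split(" ")): c for k, c in payload["bigram_counts"].items()},
            bigram_context_counts=dict(payload["bigram_context_counts"]),
            unigram_counts=dict(payload["unigram_counts"]),
            total_tokens=payload["total_tokens"],
            log_base=payload["log_base"],
        )


@dataclass(frozen=True)
class SurprisalSequence:
    """Per-token surprisal for one utterance.

    ``context_complete`` is False exactly for the first two tokens,
    which are scored with reduced context (unigram/bigram) rather than
    a full trigram.
    """

    utterance: Utterance
    values: tuple[float, ...]
    context_complete: tuple[bool, ...]
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if len(self.values) != len(self.utterance.tokens):
            raise ValueError("surprisal values misaligned with tokens")
        if len(self.context_complete) != len(self.values):
            raise ValueError("context flags misaligned with values")


def train_trigram_model(corpus: Corpus, log_base: float = 2.0) -> TrigramModel:
    """Tabulate trigram, bigram and unigram counts over a cleaned corpus.

    Training uses every cleaned utterance — including those a later
    length/duration filter will exclude from analysis — and each
    utterance restarts the context (no cross-utterance n-grams, no
    boundary padding).
    """
    if log_base not in (2.0, math.e, 2, math.e):
        raise ValueError("log_base must be 2 or e")
    uni: Counter = Counter()
    bi: Counter = Counter()
    bi_ctx: Counter = Counter()
    tri: Counter = Counter()
    tri_ctx: Counter = Counter()
    n_utts = 0
    for utt in corpus.utterances():
        n_utts += 1
        toks = utt.tokens
        uni.update(toks)
        for i in range(1, len(toks)):
            bi[(toks[i - 1], toks[i])] += 1
            bi_ctx[toks[i - 1]] += 1
        for i in range(2, len(toks)):
            tri[(toks[i - 2], toks[i - 1], toks[i])] += 1
            tri_ctx[(toks[i - 2], toks[i - 1])] += 1
    if n_utts == 0:
        raise ValueError("cannot train a trigram model on an empty corpus")
    return TrigramModel(
        context_counts=dict(tri_ctx),
        continuation_counts=dict(tri),
        bigram_counts=dict(bi),
        bigram_context_counts=dict(bi_ctx),
        unigram_counts=dict(uni),
        total_tokens=sum(uni.values()),
        log_base=float(log_base),
    )


def conditional_probability(
    model: TrigramModel, w2: str, w1: str, w: str, unseen: str = "raise"
) -> float:
    """ML probability P(w | w2, w1) = count(w2,w1,w) / count(w2,w1).

    ``unseen`` controls held-out behaviour: ``"raise"`` (default) raises
    :class:`UnseenNgramError` for triples never observed in training;
    ``"inf"`` returns 0.0 so the surprisal becomes the infinite-surprisal
    sentinel.
    """
    c = model.continuation_counts.get((w2, w1, w))
    if c is None:
        if unseen == "inf":
            return 0.0
        raise UnseenNgramError(f"trigram never observed in training: {(w2, w1, w)}")
    return c / model.context_counts[(w2, w1)]


def _reduced_probability(model: TrigramModel, position: int, toks: tuple[str, ...], unseen: str) -> float:
    if position == 0:
        c = model.unigram_counts.get(toks[0])
        if c is None:
            if unseen == "inf":
                return 0.0
            raise UnseenNgramError(f"word never observed in training: {toks[0]!r}")
        return c / model.total_tokens
    c = model.bigram_counts.get((toks[0], toks[1]))
    if c is None:
        if unseen == "inf":
            return 0.0
        raise UnseenNgramError(f"bigram never observed in training: {toks[:2]}")
    return c / model.bigram_context_counts[toks[0]]


def utterance_surprisal(
    model: TrigramModel, utt: Utterance, unseen: str = "raise"
) -> SurprisalSequence:
    """Score every token of an utterance under the model.

    Tokens 3..n are scored from full trigram context; tokens 1 and 2
    are scored from unigram and bigram relative frequency respectively
    and flagged ``context_complete=False``. A zero probability under the
    permissive unseen policy yields ``inf`` surprisal.
    """
    toks = utt.tokens
    values: list[float] = []
    flags: list[bool] = []
    for i in range(len(toks)):
        if i < 2:
            p = _reduced_probability(model, i, toks, unseen)
            flags.append(False)
        else:
            p = conditional_probability(model, toks[i - 2], toks[i - 1], toks[i], unseen)
            flags.append(True)
        values.append(math.inf if p == 0.0 else model.surprisal_of(p))
    return SurprisalSequence(
        utterance=utt,
        values=tuple(values),
        context_complete=tuple(flags),
        log_base=model.log_base,
    )


def score_corpus(
    model: TrigramModel, corpus: Corpus, unseen: str = "raise"
) -> list[SurprisalSequence]:
    """Score every utterance in a corpus; convenience wrapper."""
    return [utterance_surprisal(model, u, unseen) for u in corpus.utterances()]
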