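"""Utterance filtering, half splitting, and the front/back-loading statistic.

The loading statistic Δ of an utterance is the mean surprisal of its
last half minus the mean surprisal of its first half, where the first
two tokens are excluded from the first-half mean because they are not
scored from full trigram context. Utterances shorter than eight lexical
tokens or 600 ms are excluded before splitting; both thresholds keep
boundary values (exactly 8 tokens, exactly 600 ms) by the strict-
inequality reading of "fewer than" / "less than". The 8-token floor
guarantees at least two full-context surprisal values in each half.

Halves are a simple count split: the first half holds tokens
1..⌊n/2⌋ and the last half the remainder, so an 8-token utterance
splits 4/4 and a 9-token utterance splits 4/5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from infodist.corpus import Conversation, Corpus, Utterance
from infodist.trigram import SurprisalSequence, TrigramModel, utterance_surprisal

__all__ = [
    "MIN_TOKENS",
    "MIN_DURATION_MS",
    "HalfStats",
    "FilterReport",
    "filter_utterances",
    "split_halves",
    "compute_half_stats",
    "corpus_loading_table",
]

MIN_TOKENS = 8
MIN_DURATION_MS = 600


@dataclass(frozen=True)
class FilterReport:
    """Before/after utterance counts for one filtering pass."""

    n_before: int
    n_after: int
    n_too_short: int
    n_too_brief: int


@dataclass(frozen=True)
class HalfStats:
    """First/last-half mean surprisals and their difference for one utterance."""

    utterance: Utterance
    n_words: int
    first_half_indices: tuple[int, ...]
    last_half_indices: tuple[int, ...]
    mean_surprisal_first: float
    mean_surprisal_last: float

    @property
    def surprisal_diff(self) -> float:
        """Δ = last-half mean − first-half mean; > 0 means back-loaded."""
        return self.mean_surprisal_last - self.mean_surprisal_first


def filter_utterances(
    corpus: Corpus,
    min_tokens: int = MIN_TOKENS,
    min_duration_ms: int = MIN_DURATION_MS,
    return_report: bool = False,
) -> Corpus | tuple[Corpus, FilterReport]:
    """Keep utterances with ≥ ``min_tokens`` tokens AND ≥ ``min_duration_ms`` ms.

    Conversations left empty are dropped. With ``return_report=True``
    also returns before/after counts.
    """
    n_before = n_short = n_brief = 0
    convs: list[Conversation] = []
    for conv in corpus.conversations:
        kept = []
        for u in conv.utterances:
            n_before += 1
            if u.n_tokens < min_tokens:
                n_short += 1
                continue
            if u.duration_ms < min_duration_ms:
                n_brief += 1
                continue
            kept.append(u)
        if kept:
            convs.append(
                Conversation(
                    conversation_id=conv.conversation_id,
                    dyad_id=conv.dyad_id,
                    utterances=tuple(kept),
                )
            )
    out = Corpus(language_label=corpus.language_label, conversations=tuple(convs))
    if return_report:
        return out, FilterReport(
            n_before=n_before,
            n_after=out.n_utterances,
            n_too_short=n_short,
            n_too_brief=n_brief,
        )
    return out


def split_halves(utt: Utterance) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Split an utterance's token positions (0-based) into first/last halves.

    First half = positions 0..⌊n/2⌋−1; last half = the rest. Requires
    n ≥ 8 so that each half contains at least two full-context trigram
    values after the first two tokens are excluded.
    """
    n = utt.n_tokens
    if n < MIN_TOKENS:
        raise ValueError(
            f"cannot split an utterance of {n} tokens; at least {MIN_TOKENS} required"
        )
    cut = n // 2
    return tuple(range(cut)), tuple(range(cut, n))


def compute_half_stats(
    seq: SurprisalSequence,
    split: tuple[tuple[int, ...], tuple[int, ...]] | None = None,
) -> HalfStats | None:
    """Mean surprisal per half, excluding the two reduced-context tokens.

    The first-half mean is taken over first-half positions 3..⌊n/2⌋
    (the reduced-context first two tokens are dropped); the last-half
    mean is over all last-half positions. Returns ``None`` when any
    in-scope surprisal is non-finite (held-out scoring under the
    permissive unseen policy), flagging the utterance for exclusion
    rather than poisoning aggregates.
    """
    utt = seq.utterance
    if split is None:
        split = split_halves(utt)
    first_idx, last_idx = split
    first_vals = [seq.values[i] for i in first_idx if seq.context_complete[i]]
    last_vals = [seq.values[i] for i in last_idx]
    # the 8-token floor guarantees ≥ 2 full-context values per half
    if len(first_vals) < 2 or len(last_vals) < 2:
        raise ValueError("each half must contribute at least two surprisal values")
    if not all(math.isfinite(v) for v in first_vals + last_vals):
        return None
    return HalfStats(
        utterance=utt,
        n_words=utt.n_tokens,
        first_half_indices=tuple(first_idx),
        last_half_indices=tuple(last_idx),
        mean_surprisal_first=float(np.mean(first_vals)),
        mean_surprisal_last=float(np.mean(last_vals)),
    )


def corpus_loading_table(
    corpus: Corpus,
    model: TrigramModel,
    unseen: str = "raise",
) -> pd.DataFrame:
    """One row of half statistics per surviving utterance of a filtered corpus.

    Columns: language, dyad, speaker, conversation_id, utterance_id,
    n_words, mean_first, mean_last, diff. Row order follows the corpus
    ordering (conversations by id, utterances by start time), so reruns
    are deterministic. Utterances with non-finite surprisal in scope
    are skipped.
    """
    rows = []
    for conv in corpus.conversations:
        for k, utt in enumerate(conv.utterances):
            seq = utterance_surprisal(model, utt, unseen=unseen)
            hs = compute_half_stats(seq)
            if hs is None:
                continue
            uid = utt.utterance_id or f"{conv.conversation_id}:{k}"
            rows.append(
                {
                    "language": corpus.language_label,
                    "dyad": utt.dyad_id,
                    "speaker": utt.speaker_id,
                    "conversation_id": conv.conversation_id,
                    "utterance_id": uid,
                    "n_words": hs.n_words,
                    "mean_first": hs.mean_surprisal_first,
                    "mean_last": hs.mean_surprisal_last,
                    "diff": hs.surprisal_diff,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "language",
            "dyad",
            "speaker",
            "conversation_id",
            "utterance_id",
            "n_words",
            "mean_first",
            "mean_last",
            "diff",
        ],
    )
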