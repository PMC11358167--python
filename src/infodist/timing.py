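"""Floor transfer offsets (FTOs) between adjacent turns of different speakers.

The FTO of a turn transition is the signed time between the end of
speaker A's utterance and the beginning of speaker B's next utterance;
negative values indicate overlap. Transitions are paired in start-time
order; consecutive utterances by the same speaker yield no transition
(each cross-speaker adjacency is treated independently — no merging of
multi-utterance turns).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from infodist.corpus import Conversation, Corpus, Utterance
from infodist.loading import MIN_TOKENS, compute_half_stats
from infodist.trigram import TrigramModel, utterance_surprisal

__all__ = ["TurnTransition", "compute_ftos", "fto_table", "trim_outliers"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TurnTransition:
    """One cross-speaker adjacency with its signed floor transfer offset."""

    conversation_id: str
    prev_utterance: Utterance
    next_utterance: Utterance
    fto: int

    def __post_init__(self) -> None:
        if self.prev_speaker == self.next_speaker:
            raise ValueError("turn transition requires a speaker change")

    @property
    def prev_speaker(self) -> str:
        return self.prev_utterance.speaker_id

    @property
    def next_speaker(self) -> str:
        return self.next_utterance.speaker_id

    @property
    def n_words_next(self) -> int:
        return self.next_utterance.n_tokens


def compute_ftos(conv: Conversation) -> list[TurnTransition]:
    """One transition per adjacent start-time-ordered pair with a speaker change.

    FTO = next.start − prev.end, so overlapping starts give negative
    offsets. Input arriving unordered is sorted internally with a
    logged notice (Conversation normally maintains order).
    """
    utts = list(conv.utterances)
    if any(utts[i].start > utts[i + 1].start for i in range(len(utts) - 1)):
        logger.info("conversation %s not start-ordered; sorting", conv.conversation_id)
        utts.sort(key=lambda u: (u.start, u.end))
    out = []
    for prev, nxt in zip(utts, utts[1:]):
        if prev.speaker_id == nxt.speaker_id:
            continue
        out.append(
            TurnTransition(
                conversation_id=conv.conversation_id,
                prev_utterance=prev,
                next_utterance=nxt,
                fto=nxt.start - prev.end,
            )
        )
    return out


def fto_table(
    corpus: Corpus,
    model: TrigramModel | None = None,
    loading_group: str | None = None,
) -> pd.DataFrame:
    """All turn transitions of a corpus as a table.

    When a trigram model is supplied, each transition is joined with
    the half-mean surprisals of both flanking utterances where they
    are long enough to split (NaN otherwise): ``mean_first``/
    ``mean_last`` belong to the utterance *preceding* the transition —
    the turn being responded to, which is what the inference stage
    uses — and ``next_mean_first``/``next_mean_last`` to the
    following one. Columns: language, loading_group, conversation_id,
    dyad, prev_speaker, next_speaker, fto_ms, n_words, mean_first,
    mean_last, next_mean_first, next_mean_last.
    """
    def half_means(utt):
        if model is not None and utt.n_tokens >= MIN_TOKENS:
            seq = utterance_surprisal(model, utt, unseen="inf")
            hs = compute_half_stats(seq)
            if hs is not None:
                return hs.mean_surprisal_first, hs.mean_surprisal_last
        return math.nan, math.nan

    rows = []
    for conv in corpus.conversations:
        for tr in compute_ftos(conv):
            prev = tr.prev_utterance
            mean_first, mean_last = half_means(prev)
            next_mean_first, next_mean_last = half_means(tr.next_utterance)
            rows.append(
                {
                    "language": corpus.language_label,
                    "loading_group": loading_group,
                    "conversation_id": tr.conversation_id,
                    "dyad": prev.dyad_id,
                    "prev_speaker": tr.prev_speaker,
                    "next_speaker": tr.next_speaker,
                    "fto_ms": tr.fto,
                    "n_words": prev.n_tokens,
                    "mean_first": mean_first,
                    "mean_last": mean_last,
                    "next_mean_first": next_mean_first,
                    "next_mean_last": next_mean_last,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "language",
            "loading_group",
            "conversation_id",
            "dyad",
            "prev_speaker",
            "next_speaker",
            "fto_ms",
            "n_words",
            "mean_first",
            "mean_last",
            "next_mean_first",
            "next_mean_last",
        ],
    )


def trim_outliers(values: pd.Series, n_sd: float = 2.0) -> pd.Series:
    """Drop values beyond ``n_sd`` standard deviations from the mean.

    For visualization only; analyses use untrimmed FTOs.
    """
    mu, sd = values.mean(), values.std()
    return values[(values - mu).abs() <= n_sd * sd]
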