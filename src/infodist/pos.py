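"""Per-half rates and mean surprisals of grammatical units (nouns, verbs).

The rate of a grammatical unit in an utterance half is its occurrence
count divided by the number of words in that half (e.g. three verbs
among seven words → 3/7 ≈ 0.429); a per-utterance denominator variant
is available. The unit's mean surprisal in a half averages over the
unit's tokens there, excluding the two reduced-context utterance-
initial tokens from the average (their tags still count toward rates).

Tagging is a pluggable interface: any callable mapping a token sequence
to an equal-length universal-POS label sequence can be bound (e.g. a
stanza pipeline for real corpora); synthetic corpora carry ground-truth
tags and pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from infodist.corpus import Conversation, Corpus, Utterance
from infodist.loading import split_halves
from infodist.trigram import SurprisalSequence, TrigramModel, utterance_surprisal

__all__ = [
    "Tagger",
    "UnitHalfStats",
    "tag_corpus",
    "unit_half_stats",
    "unit_stats_table",
]

#: A tagger maps tokens to an aligned sequence of UPOS labels.
Tagger = Callable[[Sequence[str]], Sequence[str]]

DEFAULT_UNITS = ("NOUN", "VERB")


@dataclass(frozen=True)
class UnitHalfStats:
    """Rate and mean surprisal of one grammatical unit in one utterance half."""

    utterance: Utterance
    half: str  # "first" | "last"
    unit: str
    n_unit: int
    n_words_half: int
    rate: float
    mean_unit_surprisal: float | None

    def __post_init__(self) -> None:
        # mean_unit_surprisal is None iff the half has no scoreable unit
        # token (none at all, or only reduced-context ones).
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"rate out of [0, 1]: {self.rate}")
        if self.n_unit == 0 and self.mean_unit_surprisal is not None:
            raise ValueError("mean surprisal present for an absent unit")


def tag_corpus(corpus: Corpus, tagger: Tagger | None = None) -> Corpus:
    """Attach aligned UPOS tags to every utterance.

    Utterances that already carry tags (synthetic ground truth) pass
    through unchanged. Without a tagger, untagged utterances raise.
    A tagger returning a label sequence of the wrong length raises an
    alignment error.
    """
    convs = []
    for conv in corpus.conversations:
        utts = []
        for u in conv.utterances:
            if u.tags is not None:
                utts.append(u)
                continue
            if tagger is None:
                raise ValueError(
                    f"utterance in {conv.conversation_id!r} has no tags and no "
                    "tagger was supplied"
                )
            tags = tuple(tagger(u.tokens))
            if len(tags) != len(u.tokens):
                raise ValueError(
                    f"tagger returned {len(tags)} labels for {len(u.tokens)} tokens"
                )
            utts.append(replace(u, tags=tags))
        convs.append(
            Conversation(
                conversation_id=conv.conversation_id,
                dyad_id=conv.dyad_id,
                utterances=tuple(utts),
            )
        )
    return Corpus(language_label=corpus.language_label, conversations=tuple(convs))


def unit_half_stats(
    seq: SurprisalSequence,
    unit: str,
    split: tuple[tuple[int, ...], tuple[int, ...]] | None = None,
    rate_denominator: str = "half",
) -> tuple[UnitHalfStats, UnitHalfStats]:
    """Rate and mean unit surprisal for both halves of one tagged utterance.

    ``rate_denominator="half"`` divides the unit count by the words in
    that half (the default); ``"utterance"`` divides by the utterance's
    total word count.
    """
    utt = seq.utterance
    if utt.tags is None:
        raise ValueError("utterance is untagged; run tag_corpus first")
    if rate_denominator not in ("half", "utterance"):
        raise ValueError(f"unknown rate_denominator {rate_denominator!r}")
    if split is None:
        split = split_halves(utt)
    out = []
    for half_name, idx in zip(("first", "last"), split):
        unit_idx = [i for i in idx if utt.tags[i] == unit]
        # Reduced-context tokens count toward rate but not the surprisal mean.
        scoreable = [seq.values[i] for i in unit_idx if seq.context_complete[i]]
        denom = len(idx) if rate_denominator == "half" else utt.n_tokens
        out.append(
            UnitHalfStats(
                utterance=utt,
                half=half_name,
                unit=unit,
                n_unit=len(unit_idx),
                n_words_half=len(idx),
                rate=len(unit_idx) / denom,
                mean_unit_surprisal=float(np.mean(scoreable)) if scoreable else None,
            )
        )
    return tuple(out)


def unit_stats_table(
    corpus: Corpus,
    model: TrigramModel,
    tagger: Tagger | None = None,
    units: Sequence[str] = DEFAULT_UNITS,
    rate_denominator: str = "half",
    loading_group: str | None = None,
) -> pd.DataFrame:
    """Per-utterance, per-half, per-unit rates and surprisals as a table.

    ``loading_group`` labels each row front/back; when None it is
    derived from the sign of the corpus-level mean surprisal difference
    (non-negative → "back", negative → "front"). Columns: language,
    dyad, speaker, conversation_id, utterance_id, half, unit, n_unit,
    n_words_half, rate, mean_unit_surprisal, loading_group.
    """
    tagged = tag_corpus(corpus, tagger)
    rows = []
    diffs = []
    for conv in tagged.conversations:
        for k, utt in enumerate(conv.utterances):
            seq = utterance_surprisal(model, utt)
            split = split_halves(utt)
            uid = utt.utterance_id or f"{conv.conversation_id}:{k}"
            first_idx, last_idx = split
            fv = [seq.values[i] for i in first_idx if seq.context_complete[i]]
            lv = [seq.values[i] for i in last_idx]
            diffs.append(float(np.mean(lv)) - float(np.mean(fv)))
            for unit in units:
                for st in unit_half_stats(seq, unit, split, rate_denominator):
                    rows.append(
                        {
                            "language": tagged.language_label,
                            "dyad": utt.dyad_id,
                            "speaker": utt.speaker_id,
                            "conversation_id": conv.conversation_id,
                            "utterance_id": uid,
                            "half": st.half,
                            "unit": st.unit,
                            "n_unit": st.n_unit,
                            "n_words_half": st.n_words_half,
                            "rate": st.rate,
                            "mean_unit_surprisal": st.mean_unit_surprisal,
                        }
                    )
    if loading_group is None:
        loading_group = "back" if (diffs and float(np.mean(diffs)) >= 0) else "front"
    df = pd.DataFrame(
        rows,
        columns=[
            "language",
            "dyad",
            "speaker",
            "conversation_id",
            "utterance_id",
            "half",
            "unit",
            "n_unit",
            "n_words_half",
            "rate",
            "mean_unit_surprisal",
        ],
    )
    df["loading_group"] = loading_group
    return df
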