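"""Domain types for speaker-attributed, time-aligned transcripts plus I/O and cleaning.

A corpus is a set of dyadic conversations; each conversation is an
ordered sequence of utterances, where an utterance carries a token
sequence, start/end times in milliseconds, speaker and dyad identifiers,
and (optionally) universal part-of-speech tags aligned to the tokens.

Transcripts are read and written in a minimal TSV or JSONL dialect
documented in :func:`read_corpus`; parsing of corpus-vendor-specific
markup (e.g. CHAT/CLAN) is out of scope.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Utterance",
    "Conversation",
    "Corpus",
    "CorpusParseError",
    "DEFAULT_FILLERS",
    "read_corpus",
    "write_corpus",
    "clean_utterance",
    "clean_corpus",
]

#: Filled-pause inventories per language label. Filled pauses are
#: non-lexical vocalizations removed during cleaning; inventories are
#: language-specific, so these are defaults meant to be overridden from
#: config for real corpora.
DEFAULT_FILLERS: dict[str, frozenset[str]] = {
    "english": frozenset({"uh", "um", "hm", "hmm", "ah", "mhm", "eh", "er"}),
    "german": frozenset({"äh", "ähm", "hm", "mhm", "ah", "eh"}),
    "spanish": frozenset({"eh", "em", "este", "mm", "ah", "hm"}),
    "arabic": frozenset({"اه", "يعني", "ah", "eh", "hm"}),
    "japanese": frozenset({"あの", "えと", "えーと", "うん", "ah", "eh"}),
    "mandarin": frozenset({"呃", "嗯", "那个", "ah", "eh", "hm"}),
}

#: Generic fallback when no per-language lexicon is configured.
GENERIC_FILLERS: frozenset[str] = frozenset({"uh", "hm", "ah"})

_TSV_COLUMNS = ("conversation_id", "dyad_id", "speaker", "start_ms", "end_ms", "tokens", "tags")


class CorpusParseError(ValueError):
    """Raised for malformed transcript records; names the offending line."""


@dataclass(frozen=True)
class Utterance:
    """One speaker turn-constructional unit: tokens plus timing and attribution.

    Times are integer milliseconds from conversation start. ``tags``,
    when present, are universal POS labels aligned one-to-one with
    ``tokens``.
    """

    conversation_id: str
    speaker_id: str
    dyad_id: str
    start: int
    end: int
    tokens: tuple[str, ...]
    tags: tuple[str, ...] | None = None
    utterance_id: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"utterance end ({self.end}) precedes start ({self.start})"
            )
        if not self.tokens:
            raise ValueError("utterance must contain at least one token")
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if self.tags is not None:
            object.__setattr__(self, "tags", tuple(self.tags))
            if len(self.tags) != len(self.tokens):
                raise ValueError(
                    f"tag/token misalignment: {len(self.tags)} tags for "
                    f"{len(self.tokens)} tokens"
                )

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    @property
    def duration_ms(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Conversation:
    """A dyadic conversation: utterances ordered by start time."""

    conversation_id: str
    dyad_id: str
    utterances: tuple[Utterance, ...]

    def __post_init__(self) -> None:
        utts = tuple(sorted(self.utterances, key=lambda u: (u.start, u.end)))
        object.__setattr__(self, "utterances", utts)
        for u in utts:
            if u.conversation_id != self.conversation_id:
                raise ValueError(
                    f"utterance conversation_id {u.conversation_id!r} does not "
                    f"match conversation {self.conversation_id!r}"
                )
        speakers = {u.speaker_id for u in utts}
        if len(speakers) > 2:
            raise ValueError(
                f"conversation {self.conversation_id!r} has {len(speakers)} "
                "speakers; conversations are dyadic"
            )

    @property
    def speakers(self) -> frozenset[str]:
        return frozenset(u.speaker_id for u in self.utterances)


@dataclass(frozen=True)
class Corpus:
    """A language-labelled collection of conversations."""

    language_label: str
    conversations: tuple[Conversation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "conversations", tuple(self.conversations))
        ids = [c.conversation_id for c in self.conversations]
        if len(ids) != len(set(ids)):
            raise ValueError("conversation_ids must be unique within a corpus")

    def utterances(self) -> Iterator[Utterance]:
        for conv in self.conversations:
            yield from conv.utterances

    @property
    def n_utterances(self) -> int:
        return sum(len(c.utterances) for c in self.conversations)

    def __len__(self) -> int:
        return len(self.conversations)


def _utterance_to_record(u: Utterance) -> dict:
    rec = {
        "conversation_id": u.conversation_id,
        "dyad_id": u.dyad_id,
        "speaker": u.speaker_id,
        "start_ms": u.start,
        "end_ms": u.end,
        "tokens": " ".join(u.tokens),
    }
    if u.tags is not None:
        rec["tags"] = " ".join(u.tags)
    if u.utterance_id is not None:
        rec["utterance_id"] = u.utterance_id
    return rec


def _record_to_utterance(rec: dict, where: str) -> Utterance:
    try:
        tokens = tuple(str(rec["tokens"]).split())
        tags_raw = rec.get("tags")
        tags = tuple(str(tags_raw).split()) if tags_raw not in (None, "") else None
        return Utterance(
            conversation_id=str(rec["conversation_id"]),
            dyad_id=str(rec["dyad_id"]),
            speaker_id=str(rec["speaker"]),
            start=int(rec["start_ms"]),
            end=int(rec["end_ms"]),
            tokens=tokens,
            tags=tags,
            utterance_id=str(rec["utterance_id"]) if rec.get("utterance_id") else None,
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise CorpusParseError(f"malformed record at {where}: {exc}") from exc


def _group_conversations(utterances: Sequence[Utterance], language_label: str) -> Corpus:
    by_conv: dict[str, list[Utterance]] = {}
    order: list[str] = []
    for u in utterances:
        if u.conversation_id not in by_conv:
            by_conv[u.conversation_id] = []
            order.append(u.conversation_id)
        by_conv[u.conversation_id].append(u)
    convs = []
    for cid in sorted(order):
        utts = by_conv[cid]
        dyads = {u.dyad_id for u in utts}
        if len(dyads) != 1:
            raise CorpusParseError(
                f"conversation {cid!r} spans multiple dyads: {sorted(dyads)}"
            )
        convs.append(Conversation(conversation_id=cid, dyad_id=utts[0].dyad_id, utterances=tuple(utts)))
    return Corpus(language_label=language_label, conversations=tuple(convs))


def read_corpus(path: str | Path, dialect: str = "tsv", language_label: str | None = None) -> Corpus:
    """Read a transcript file into a :class:`Corpus`.

    TSV dialect: UTF-8, header row with columns ``conversation_id``,
    ``dyad_id``, ``speaker``, ``start_ms``, ``end_ms``, ``tokens``
    (single-space-separated) and optionally ``tags`` (space-separated
    UPOS) and ``utterance_id``. JSONL: one utterance object per line,
    same field names.

    The language label defaults to the file stem.
    """
    path = Path(path)
    if dialect not in ("tsv", "jsonl"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'jsonl'")
    label = language_label if language_label is not None else path.stem
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or all(not ln.strip() for ln in lines):
        raise CorpusParseError(f"empty transcript file: {path}")

    utterances: list[Utterance] = []
    if dialect == "tsv":
        header = lines[0].rstrip("\n").split("\t")
        unknown = set(header) - set(_TSV_COLUMNS) - {"utterance_id"}
        if "conversation_id" not in header or unknown:
            raise CorpusParseError(f"unrecognized TSV header in {path}: {header}")
        for i, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise CorpusParseError(
                    f"malformed record at {path}:{i}: expected {len(header)} "
                    f"columns, found {len(cells)}"
                )
            rec = dict(zip(header, cells))
            utterances.append(_record_to_utterance(rec, f"{path}:{i}"))
    else:
        for i, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(f"malformed JSON at {path}:{i}: {exc}") from exc
            utterances.append(_record_to_utterance(rec, f"{path}:{i}"))

    if not utterances:
        raise CorpusParseError(f"transcript file contains no records: {path}")
    return _group_conversations(utterances, label)


def write_corpus(corpus: Corpus, path: str | Path, dialect: str = "tsv") -> Path:
    """Write a corpus so that it round-trips bit-identically through
    :func:`read_corpus` at the token level.

    Records are emitted grouped by conversation (sorted by id) and
    ordered by start time within each conversation, so output is
    deterministic for a given corpus.
    """
    path = Path(path)
    if dialect not in ("tsv", "jsonl"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'jsonl'")
    records = [
        _utterance_to_record(u)
        for conv in sorted(corpus.conversations, key=lambda c: c.conversation_id)
        for u in conv.utterances
    ]
    with path.open("w", encoding="utf-8") as fh:
        if dialect == "tsv":
            has_tags = any("tags" in r for r in records)
            has_ids = any("utterance_id" in r for r in records)
            cols = [c for c in _TSV_COLUMNS if c != "tags" or has_tags]
            if has_ids:
                cols.append("utterance_id")
            fh.write("\t".join(cols) + "\n")
            for rec in records:
                fh.write("\t".join(str(rec.get(c, "")) for c in cols) + "\n")
        else:
            for rec in records:
                fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")
    return path


def _is_punctuation_only(token: str) -> bool:
    # A token is punctuation-only if it has no letter/digit under Unicode
    # categories; intra-word apostrophes and hyphens therefore survive.
    return not any(unicodedata.category(ch)[0] in ("L", "N") for ch in token)


def clean_utterance(
    utt: Utterance,
    filler_lexicon: Iterable[str] | None = None,
    annotation_patterns: Iterable[str] = (r"^\[.*\]$", r"^<.*>$", r"^&.*", r"^\{.*\}$"),
    lowercase: bool = True,
) -> Utterance | None:
    """Remove punctuation-only tokens, non-lexeme annotations, and filled pauses.

    Filled pauses ("uh", "hm", "ah", ...) are matched against
    ``filler_lexicon`` case-insensitively; annotation markup (bracketed
    or ampersand-prefixed non-lexeme events such as laughter) is matched
    against the configurable regex ``annotation_patterns``. Surviving
    tokens keep their relative order; aligned tags are removed with
    their tokens. Tokens are lowercased unless ``lowercase=False``.

    Returns ``None`` when every token is removed: the utterance is
    flagged empty rather than raising, and is excluded downstream.
    """
    if filler_lexicon is None:
        filler_lexicon = DEFAULT_FILLERS.get(
            utt.conversation_id.split("_")[0].lower(), GENERIC_FILLERS
        )
    fillers = {f.lower() for f in filler_lexicon}
    patterns = [re.compile(p) for p in annotation_patterns]

    kept_tokens: list[str] = []
    kept_tags: list[str] = []
    for i, tok in enumerate(utt.tokens):
        if _is_punctuation_only(tok):
            continue
        if any(p.match(tok) for p in patterns):
            continue
        if tok.lower() in fillers:
            continue
        kept_tokens.append(tok.lower() if lowercase else tok)
        if utt.tags is not None:
            kept_tags.append(utt.tags[i])
    if not kept_tokens:
        return None
    return replace(
        utt,
        tokens=tuple(kept_tokens),
        tags=tuple(kept_tags) if utt.tags is not None else None,
    )


def clean_corpus(
    corpus: Corpus,
    filler_lexicon: Iterable[str] | None = None,
    annotation_patterns: Iterable[str] = (r"^\[.*\]$", r"^<.*>$", r"^&.*", r"^\{.*\}$"),
    lowercase: bool = True,
) -> Corpus:
    """Apply :func:`clean_utterance` corpus-wide, dropping emptied utterances.

    Conversations whose utterances are all removed are dropped entirely.
    """
    if filler_lexicon is None:
        filler_lexicon = DEFAULT_FILLERS.get(corpus.language_label.lower(), GENERIC_FILLERS)
    convs = []
    for conv in corpus.conversations:
        cleaned = [
            cu
            for u in conv.utterances
            if (cu := clean_utterance(u, filler_lexicon, annotation_patterns, lowercase))
            is not None
        ]
        if cleaned:
            convs.append(
                Conversation(
                    conversation_id=conv.conversation_id,
                    dyad_id=conv.dyad_id,
                    utterances=tuple(cleaned),
                )
            )
    return Corpus(language_label=corpus.language_label, conversations=tuple(convs))
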