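"""Synthetic dialogue corpora with closed-form ground-truth surprisal.

The generator emulates the statistical structure the pipeline assumes
in real conversational data: dyadic conversations with alternating
speakers, Zipf-shaped word frequencies with Markov (trigram-
recoverable) dependencies, utterance lengths straddling the 8-token
analysis threshold, position-dependent part-of-speech composition, and
inter-turn gaps with a controllable mean per condition.

Information loading is realized as an *entropy contrast* between two
conditional word families rather than a positional frequency bias, so
every token's true surprisal is available in closed form. Each family
(sparse vs. dense) owns a disjoint sub-vocabulary split into *content*
words and a small set of *linker* words, and emission cycles through
phases ``content, linker, linker, content, ...``:

* a content word is drawn conditioned on a latent class carried by the
  preceding linker: the class's head word with probability ``a``,
  otherwise a fixed Zipf tail over the family's other content words;
* each linker is drawn conditioned on the class of the preceding
  token: the class's head linker with probability ``b``, otherwise
  uniform over the family's other linkers.

Head masses ``a`` and ``b`` are solved numerically so content and
linker conditional entropies sit exactly ``delta_bits/2`` above and
below their configured baselines in the dense and sparse families, so
the expected true-surprisal gap between dense and sparse halves equals
``delta_bits`` at every position. The cycle guarantees that every
high-entropy (content) draw follows a frequent two-linker context,
while rare tail words are followed only by low-entropy linker draws —
which is what lets an unsmoothed maximum-likelihood trigram model
trained on the corpus recover per-token surprisal with high fidelity.
The conditioning class is always a function of the immediately
preceding word, so the true conditional distribution of every token is
identified by its visible context; the only model misspecification is
at the single dense/sparse boundary inside each utterance.

The high-entropy family governs the dense half: the last half when
``loading_mode="back"``, the first half when ``"front"``, and neither
when ``"flat"`` (two equal-entropy families).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from infodist.corpus import Conversation, Corpus, Utterance

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "CalibrationError",
    "generate_corpus",
    "true_surprisal",
    "make_fixture",
    "expected_surprisal_diff",
    "max_feasible_delta",
    "write_ground_truth",
    "read_ground_truth",
]

_ENTROPY_MARGIN = 0.05  # bits kept clear of each layer's feasible range
_N_LINKERS = 8  # linker words per family

#: UPOS composition by position type in the sparse (baseline) half.
#: Content positions carry open-class tags, linker positions closed-
#: class tags, echoing the function-word scaffolding of real speech.
_CONTENT_TAG_PROBS = {"NOUN": 0.45, "VERB": 0.35, "ADJ": 0.10, "ADV": 0.10}
_LINKER_TAG_PROBS = {"PRON": 0.30, "ADP": 0.30, "DET": 0.20, "ADV": 0.20}


class CalibrationError(ValueError):
    """Raised when the requested entropy contrast is infeasible."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions for one synthetic language corpus.

    ``delta_bits`` is the target expected per-word true-surprisal
    difference between the dense and sparse utterance halves;
    ``pos_enrichment`` is the NOUN and VERB rate increment in the
    dense half; ``fto_mean_ms``/``fto_sd_ms`` parameterize the
    Gaussian inter-turn gap of the corpus' loading mode (negative
    draws, i.e. overlaps, are permitted). Durations follow a constant
    speech rate of ``words_per_second``. Utterance lengths are
    ``min_len + Binomial(max_len − min_len, len_shape)``, straddling
    the 8-token analysis threshold at the defaults.
    """

    language_label: str = "synthlang"
    n_dyads: int = 20
    conversations_per_dyad: int = 1
    utterances_per_conversation: int = 50
    min_len: int = 4
    max_len: int = 22
    len_shape: float = 0.5
    vocab_size: int = 96
    n_classes: int = 4
    zipf_exponent: float = 1.2  # shape of the content-word tail
    loading_mode: str = "back"  # {"front", "back", "flat"}
    delta_bits: float = 0.5
    content_entropy_bits: float = 3.3
    linker_entropy_bits: float = 1.3
    pos_enrichment: float = 0.0
    verb_surprisal_coupling: float = 0.0
    fto_mean_ms: float = 250.0
    fto_sd_ms: float = 150.0
    words_per_second: float = 3.0
    filler_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loading_mode not in ("front", "back", "flat"):
            raise ValueError(f"unknown loading_mode {self.loading_mode!r}")
        if self.delta_bits < 0:
            raise ValueError("delta_bits must be ≥ 0")
        if self.vocab_size < 50:
            raise ValueError("vocab_size must be ≥ 50")
        if self.n_classes < 2 or self.n_classes > _N_LINKERS:
            raise ValueError(f"n_classes must be in [2, {_N_LINKERS}]")
        for name in ("n_dyads", "conversations_per_dyad", "utterances_per_conversation"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("need 0 < min_len ≤ max_len")

    @property
    def content_vocab_size(self) -> int:
        """Content words per family (the rest are 2 × 8 linkers)."""
        return (self.vocab_size - 2 * _N_LINKERS) // 2


@dataclass
class GroundTruth:
    """Generator-side truth aligned to the emitted corpus.

    ``surprisal[uid]`` holds the true per-token surprisal (bits) of the
    utterance's *lexical* tokens — injected fillers, which cleaning
    removes, carry no entry, so the arrays align with the cleaned token
    sequence. ``tags[uid]`` are the filler-free ground-truth UPOS
    labels; ``loading_mode[uid]`` labels each utterance's condition;
    ``fto_mean_ms``/``fto_sd_ms`` are the transition-gap parameters
    used.
    """

    surprisal: dict[str, tuple[float, ...]] = field(default_factory=dict)
    loading_mode: dict[str, str] = field(default_factory=dict)
    tags: dict[str, tuple[str, ...]] = field(default_factory=dict)
    fto_mean_ms: float = 0.0
    fto_sd_ms: float = 0.0
    config: GeneratorConfig | None = None


# --------------------------------------------------------------------
# entropy calibration


def _zipf_probs(m: int, s: float) -> np.ndarray:
    ranks = np.arange(1, m + 1, dtype=float)
    w = ranks ** (-s)
    return w / w.sum()


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _head_tail_entropy(a: float, tail_entropy: float) -> float:
    # entropy of {head: a} ∪ (1 − a)·tail, head outside the tail support
    if a <= 0.0:
        return tail_entropy
    if a >= 1.0:
        return 0.0
    return -a * math.log2(a) - (1 - a) * math.log2(1 - a) + (1 - a) * tail_entropy


def _entropy_cap(tail_entropy: float) -> float:
    a_star = 1.0 / (1.0 + 2.0**tail_entropy)
    return _head_tail_entropy(a_star, tail_entropy)


def _solve_head_mass(tail_entropy: float, target_bits: float) -> float:
    """Head mass whose head+tail mixture has the target entropy.

    H(a) rises from the tail entropy to its maximum at
    a* = 1/(1 + 2^H_tail) and then falls to 0; the solver works on the
    decreasing branch, so larger targets mean smaller heads.
    """
    a_star = 1.0 / (1.0 + 2.0**tail_entropy)
    h_max = _head_tail_entropy(a_star, tail_entropy)
    if not (0.0 < target_bits < h_max):
        raise CalibrationError(
            f"entropy target {target_bits:.3f} bits outside feasible range "
            f"(0, {h_max:.3f})"
        )
    return float(
        brentq(
            lambda a: _head_tail_entropy(a, tail_entropy) - target_bits,
            a_star,
            1.0 - 1e-12,
            xtol=1e-12,
        )
    )


def _layer_tails(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    m = config.content_vocab_size
    if m < 2 * config.n_classes:
        raise CalibrationError(
            f"vocab_size {config.vocab_size} leaves only {m} content words per family"
        )
    content_tail = _zipf_probs(m - 1, config.zipf_exponent)
    linker_tail = np.full(_N_LINKERS - 1, 1.0 / (_N_LINKERS - 1))
    return content_tail, linker_tail


def max_feasible_delta(config: GeneratorConfig) -> float:
    """Largest realizable ``delta_bits`` for the config's vocabulary/baselines."""
    content_tail, linker_tail = _layer_tails(config)
    c_cap = _entropy_cap(_entropy_bits(content_tail)) - _ENTROPY_MARGIN
    l_cap = _entropy_cap(_entropy_bits(linker_tail)) - _ENTROPY_MARGIN
    head_room = min(
        c_cap - config.content_entropy_bits,
        l_cap - config.linker_entropy_bits,
        config.content_entropy_bits - _ENTROPY_MARGIN,
        config.linker_entropy_bits - _ENTROPY_MARGIN,
    )
    return max(0.0, 2.0 * head_room)


def _layer_entropies(config: GeneratorConfig) -> tuple[tuple[float, float], tuple[float, float]]:
    """((content_sparse, content_dense), (linker_sparse, linker_dense)) targets."""
    half = config.delta_bits / 2
    if config.delta_bits > max_feasible_delta(config):
        raise CalibrationError(
            f"delta_bits={config.delta_bits} infeasible at vocab_size="
            f"{config.vocab_size} with content/linker baselines "
            f"{config.content_entropy_bits}/{config.linker_entropy_bits} bits; "
            f"feasible maximum is {max_feasible_delta(config):.3f} bits"
        )
    return (
        (config.content_entropy_bits - half, config.content_entropy_bits + half),
        (config.linker_entropy_bits - half, config.linker_entropy_bits + half),
    )


def expected_surprisal_diff(config: GeneratorConfig) -> float:
    """Analytic expectation of Δ (last-half − first-half true surprisal).

    The entropy gap between the dense and sparse families is δ at
    every position (content and linker alike), so the expected
    half-mean difference is exactly ±δ (0 when flat).
    """
    if config.loading_mode == "flat":
        return 0.0
    _layer_entropies(config)  # feasibility check
    return config.delta_bits if config.loading_mode == "back" else -config.delta_bits


# --------------------------------------------------------------------
# emission tables


class _ProcessTables:
    """Conditional distributions for both families, with exact entropies.

    Family 0 is sparse, family 1 dense (for flat corpora both sit at
    the baselines). Global word indexing: content words of family f
    occupy ``f·m .. f·m+m−1``; linkers follow after ``2m``, eight per
    family. Class of a content word = local index mod k; class of a
    linker = local index mod k.
    """

    def __init__(self, config: GeneratorConfig):
        self.k = config.n_classes
        self.m = config.content_vocab_size
        content_tail, linker_tail = _layer_tails(config)
        if config.loading_mode == "flat":
            _layer_entropies(dc_replace(config, delta_bits=0.0))  # budget check
            c_targets = (config.content_entropy_bits,) * 2
            l_targets = (config.linker_entropy_bits,) * 2
        else:
            (c_lo, c_hi), (l_lo, l_hi) = _layer_entropies(config)
            c_targets, l_targets = (c_lo, c_hi), (l_lo, l_hi)
        self.content_entropy = c_targets
        self.linker_entropy = l_targets
        h_c_tail = _entropy_bits(content_tail)
        h_l_tail = _entropy_bits(linker_tail)
        self.a = tuple(_solve_head_mass(h_c_tail, h) for h in c_targets)
        self.b = tuple(_solve_head_mass(h_l_tail, h) for h in l_targets)
        self.content_tail_cum = np.cumsum(content_tail)
        self.linker_tail_cum = np.cumsum(linker_tail)
        # surprisal lookups per family
        self.content_head_surp = tuple(-math.log2(a) for a in self.a)
        self.content_tail_surp = tuple(-np.log2((1 - a) * content_tail) for a in self.a)
        self.linker_head_surp = tuple(-math.log2(b) for b in self.b)
        self.linker_tail_surp = tuple(-np.log2((1 - b) * linker_tail) for b in self.b)
        # tail word lists per class (local indices with the head removed)
        self.content_tail_words = [
            np.array([w for w in range(self.m) if w != cls], dtype=np.int64)
            for cls in range(self.k)
        ]
        self.linker_tail_words = [
            np.array([w for w in range(_N_LINKERS) if w != cls], dtype=np.int64)
            for cls in range(self.k)
        ]

    def draw_content(self, family: int, cls: int, u: float, v: float) -> tuple[int, float]:
        """→ (local content index, true surprisal in bits)."""
        if u < self.a[family]:
            return cls, self.content_head_surp[family]
        r = min(
            int(np.searchsorted(self.content_tail_cum, v, side="right")), self.m - 2
        )
        return int(self.content_tail_words[cls][r]), float(self.content_tail_surp[family][r])

    def draw_linker(self, family: int, cls: int, u: float, v: float) -> tuple[int, float]:
        """→ (local linker index, true surprisal in bits)."""
        if u < self.b[family]:
            return cls, self.linker_head_surp[family]
        r = min(
            int(np.searchsorted(self.linker_tail_cum, v, side="right")), _N_LINKERS - 2
        )
        return int(self.linker_tail_words[cls][r]), float(self.linker_tail_surp[family][r])


def _tag_table(probs: dict[str, float], enrichment: float) -> tuple[list[str], np.ndarray]:
    probs = dict(probs)
    if enrichment > 0:
        for unit in ("NOUN", "VERB"):
            probs[unit] = probs.get(unit, 0.0) + enrichment
        others = [t for t in probs if t not in ("NOUN", "VERB")]
        total_other = sum(probs[t] for t in others)
        for t in others:
            probs[t] -= 2 * enrichment * probs[t] / total_other
    labels = sorted(probs)
    w = np.array([probs[t] for t in labels])
    return labels, w / w.sum()


# --------------------------------------------------------------------
# generation


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate one language corpus and its aligned ground truth.

    Speakers alternate strictly within each conversation; durations are
    ``n_words / words_per_second``; inter-turn gaps are Gaussian with
    the configured mean and SD, clamped only as far as necessary to
    preserve start-time order. Identical configs (including ``seed``)
    reproduce the corpus bit-exactly.
    """
    rng = np.random.default_rng(config.seed)
    tables = _ProcessTables(config)
    m, k = tables.m, tables.k
    content_names = [
        [f"{'ab'[f]}c{w:03d}" for w in range(m)] for f in range(2)
    ]
    linker_names = [[f"{'ab'[f]}l{w}" for w in range(_N_LINKERS)] for f in range(2)]

    sparse_content_tags = _tag_table(_CONTENT_TAG_PROBS, 0.0)
    dense_content_tags = _tag_table(_CONTENT_TAG_PROBS, config.pos_enrichment)
    sparse_linker_tags = _tag_table(_LINKER_TAG_PROBS, 0.0)
    dense_linker_tags = _tag_table(_LINKER_TAG_PROBS, config.pos_enrichment)

    gt = GroundTruth(
        fto_mean_ms=config.fto_mean_ms,
        fto_sd_ms=config.fto_sd_ms,
        config=config,
    )

    def pick_tag(table: tuple[list[str], np.ndarray], surp: float, h_ref: float) -> str:
        labels, w = table
        c = config.verb_surprisal_coupling
        if c > 0 and "VERB" in labels and "NOUN" in labels:
            w = w.copy()
            tilt = math.exp(max(-4.0, min(4.0, c * (surp - h_ref))))
            w[labels.index("VERB")] *= tilt
            w[labels.index("NOUN")] /= math.sqrt(tilt)
            w = w / w.sum()
        return labels[int(np.searchsorted(np.cumsum(w), rng.random(), side="right"))]

    conversations = []
    uid_counter = 0
    for d in range(config.n_dyads):
        dyad_id = f"{config.language_label}_d{d:03d}"
        speakers = (f"{dyad_id}_A", f"{dyad_id}_B")
        for c in range(config.conversations_per_dyad):
            conv_id = f"{dyad_id}_c{c:02d}"
            utts: list[Utterance] = []
            for j in range(config.utterances_per_conversation):
                n = config.min_len + int(
                    rng.binomial(config.max_len - config.min_len, config.len_shape)
                )
                cut = n // 2
                tokens: list[str] = []
                surps: list[float] = []
                tags: list[str] = []
                cls = int(rng.integers(k))
                # random phase offset keeps the expected content/linker
                # composition identical across positions, so half means
                # are exactly calibrated regardless of the split point
                phase_offset = int(rng.integers(3))
                for t in range(n):
                    if config.loading_mode == "back":
                        family = 1 if t >= cut else 0
                    elif config.loading_mode == "front":
                        family = 1 if t < cut else 0
                    else:
                        family = 0  # flat: one family, no boundary
                    dense = family == 1 and config.loading_mode != "flat"
                    u, v = rng.random(), rng.random()
                    if (t + phase_offset) % 3 == 0:
                        widx, s_bits = tables.draw_content(family, cls, u, v)
                        tokens.append(content_names[family][widx])
                        h_ref = tables.content_entropy[family]
                        tag_tbl = dense_content_tags if dense else sparse_content_tags
                    else:
                        widx, s_bits = tables.draw_linker(family, cls, u, v)
                        tokens.append(linker_names[family][widx])
                        h_ref = tables.linker_entropy[family]
                        tag_tbl = dense_linker_tags if dense else sparse_linker_tags
                    cls = widx % k
                    surps.append(s_bits)
                    tags.append(pick_tag(tag_tbl, s_bits, h_ref))

                if config.filler_rate > 0:
                    emit_tokens, emit_tags = [], []
                    for tok, tag in zip(tokens, tags):
                        if rng.random() < config.filler_rate:
                            emit_tokens.append("uh")
                            emit_tags.append("INTJ")
                        emit_tokens.append(tok)
                        emit_tags.append(tag)
                else:
                    emit_tokens, emit_tags = tokens, tags

                duration = max(1, round(1000 * len(emit_tokens) / config.words_per_second))
                if j == 0:
                    start = 0
                else:
                    gap = rng.normal(config.fto_mean_ms, config.fto_sd_ms)
                    prev = utts[-1]
                    # keep start-time order
                    start = max(prev.start + 1, prev.end + int(round(gap)))
                end = start + duration
                uid = f"{conv_id}_u{uid_counter:05d}"
                uid_counter += 1
                utts.append(
                    Utterance(
                        conversation_id=conv_id,
                        dyad_id=dyad_id,
                        speaker_id=speakers[j % 2],
                        start=start,
                        end=end,
                        tokens=tuple(emit_tokens),
                        tags=tuple(emit_tags),
                        utterance_id=uid,
                    )
                )
                gt.surprisal[uid] = tuple(surps)
                gt.loading_mode[uid] = config.loading_mode
                gt.tags[uid] = tuple(tags)
            conversations.append(
                Conversation(conversation_id=conv_id, dyad_id=dyad_id, utterances=tuple(utts))
            )
    corpus = Corpus(language_label=config.language_label, conversations=tuple(conversations))
    return corpus, gt


def true_surprisal(gt: GroundTruth, utt: Utterance) -> tuple[float, ...]:
    """Ground-truth per-token surprisal (bits) for a generated utterance.

    Values align with the utterance's lexical tokens (injected fillers
    excluded). Foreign utterances raise ``LookupError``.
    """
    if utt.utterance_id is None or utt.utterance_id not in gt.surprisal:
        raise LookupError(
            f"utterance {utt.utterance_id!r} is not part of this generated corpus"
        )
    return gt.surprisal[utt.utterance_id]


def write_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    """Write a JSONL ground-truth sidecar aligned by utterance_id.

    One record per utterance: utterance_id, per-token true surprisal
    (bits), ground-truth tags, and loading mode; a header line carries
    the generator config and FTO parameters.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        header = {
            "record": "header",
            "fto_mean_ms": gt.fto_mean_ms,
            "fto_sd_ms": gt.fto_sd_ms,
            "config": asdict(gt.config) if gt.config is not None else None,
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for uid in sorted(gt.surprisal):
            rec = {
                "record": "utterance",
                "utterance_id": uid,
                "surprisal_bits": list(gt.surprisal[uid]),
                "tags": list(gt.tags.get(uid, ())),
                "loading_mode": gt.loading_mode[uid],
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Read a ground-truth sidecar written by :func:`write_ground_truth`."""
    gt = GroundTruth()
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            rec = json.loads(line)
            if rec["record"] == "header":
                gt.fto_mean_ms = rec["fto_mean_ms"]
                gt.fto_sd_ms = rec["fto_sd_ms"]
                if rec.get("config"):
                    gt.config = GeneratorConfig(**rec["config"])
            else:
                uid = rec["utterance_id"]
                gt.surprisal[uid] = tuple(rec["surprisal_bits"])
                gt.tags[uid] = tuple(rec["tags"])
                gt.loading_mode[uid] = rec["loading_mode"]
    return gt


#: Reference six-language suite: three back-loaded and three
#: front-loaded languages at a 0.5-bit contrast, with a +100 ms FTO
#: shift for the back-loaded group.
_REFERENCE_LANGS = [
    ("back_a", "back", 0.5, 300.0),
    ("back_b", "back", 0.5, 300.0),
    ("back_c", "back", 0.5, 300.0),
    ("front_a", "front", 0.5, 200.0),
    ("front_b", "front", 0.5, 200.0),
    ("front_c", "front", 0.5, 200.0),
]


def make_fixture(
    name: str,
    seed: int = 0,
    utterances_per_conversation: int = 40,
    n_dyads: int = 50,
) -> list[tuple[Corpus, GroundTruth]]:
    """Canonical fixtures: one ``(Corpus, GroundTruth)`` pair per language.

    ``tiny``: one 20-utterance flat language (two dyads) for exact
    oracle tests. ``reference``: the calibrated six-language suite — three
    back-loaded and three front-loaded languages at δ = 0.5 bits,
    2,000 utterances each at the defaults (50 dyads × 40 utterances),
    a +100 ms FTO shift for the back-loaded group, mild NOUN/VERB
    enrichment and verb–surprisal coupling in the dense half.
    ``null``: six identically configured flat languages with every
    effect at zero (40 dyads × 20 utterances).
    """
    ss = np.random.SeedSequence(seed)
    if name == "tiny":
        cfg = GeneratorConfig(
            language_label="tinylang",
            n_dyads=2,
            conversations_per_dyad=1,
            utterances_per_conversation=10,
            min_len=8,
            max_len=12,
            loading_mode="flat",
            delta_bits=0.0,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        return [generate_corpus(cfg)]
    if name == "reference":
        children = ss.spawn(len(_REFERENCE_LANGS))
        out = []
        for (label, mode, delta, fto), child in zip(_REFERENCE_LANGS, children):
            cfg = GeneratorConfig(
                language_label=label,
                n_dyads=n_dyads,
                conversations_per_dyad=1,
                utterances_per_conversation=utterances_per_conversation,
                loading_mode=mode,
                delta_bits=delta,
                pos_enrichment=0.05,
                verb_surprisal_coupling=0.3,
                fto_mean_ms=fto,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            out.append(generate_corpus(cfg))
        return out
    if name == "null":
        children = ss.spawn(6)
        out = []
        for i, child in enumerate(children):
            cfg = GeneratorConfig(
                language_label=f"null_{chr(ord('a') + i)}",
                n_dyads=40,
                conversations_per_dyad=1,
                utterances_per_conversation=20,
                loading_mode="flat",
                delta_bits=0.0,
                fto_mean_ms=250.0,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            out.append(generate_corpus(cfg))
        return out
    raise ValueError(f"unknown fixture {name!r}; expected tiny, reference, or null")
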