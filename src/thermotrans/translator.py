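"""Conditional sequence models and decoding.

The central contract: a conditional sequence model maps a source protein
and a target prefix to a probability vector over the 21-token alphabet
(20 residues + end token) for the next target position.  Scoring
(teacher-forcing likelihoods) and generation (beam search) are defined
against this contract only, so any causal translator — a toy profile, the
bundled trainable model, or an external adapter — plugs in unchanged.

The bundled :class:`TinyTranslator` is a compact numpy encoder–decoder:
the encoder context for target position *i* is a one-hot window of source
residues around the aligned position, the decoder state is the previous
target token, and a linear-softmax layer predicts the next token.  It is
trained teacher-forced with per-token categorical cross entropy, an Adam
optimizer under a linear ramp-up/ramp-down learning-rate schedule, and
early stopping on validation loss (patience 4, improvement threshold 0.1
by default).  It is deliberately small: enough capacity to learn
position-wise meso→thermo substitution rules, trainable in seconds on one
CPU, and seed-deterministic.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .alphabet import (
    AA20,
    AA_INDEX,
    END_INDEX,
    END_TOKEN,
    N_RESIDUES,
    N_TOKENS,
    SequenceAlphabetError,
    TOKEN_INDEX,
)

__all__ = [
    "ConditionalSequenceModel",
    "UniformModel",
    "ProfileModel",
    "ScriptedModel",
    "TinyTranslator",
    "TrainingConfig",
    "BeamResult",
    "predict_stepwise",
    "train_tiny_translator",
    "beam_search",
]

_PROB_ATOL = 1e-6


class ConditionalSequenceModel(ABC):
    """Contract: (source, target_prefix) → next-token probability vector.

    Returned vectors have length 21 (residues in :data:`~thermotrans.alphabet.AA20`
    order, end token last), are non-negative, and sum to 1 within 1e-6.
    Implementations must be deterministic for fixed inputs and model state.
    """

    @abstractmethod
    def next_distribution(self, source: str, target_prefix: str) -> np.ndarray:
        """Probability vector over the token alphabet for the next position."""


def _check_tokens(seq: str, name: str) -> None:
    for pos, ch in enumerate(seq):
        if ch not in TOKEN_INDEX:
            raise SequenceAlphabetError(
                f"{name}: token {ch!r} at position {pos} outside the model alphabet"
            )


def predict_stepwise(
    model: ConditionalSequenceModel,
    source: str,
    target: str,
    include_end: bool = False,
) -> np.ndarray:
    """Teacher-forced stepwise prediction matrix.

    Row ``i`` is the model's next-token distribution given ``source`` and
    the true target prefix ``target[:i]``.  With ``include_end`` an extra
    final row conditioned on the full target is appended (used to score the
    end-of-sequence decision).
    """
    if not target:
        raise ValueError("target must be non-empty")
    _check_tokens(source, "source")
    _check_tokens(target, "target")
    n = len(target) + (1 if include_end else 0)
    rows = np.empty((n, N_TOKENS), dtype=float)
    for i in range(n):
        vec = np.asarray(model.next_distribution(source, target[:i]), dtype=float)
        if vec.shape != (N_TOKENS,):
            raise ValueError(
                f"model returned vector of shape {vec.shape}, expected ({N_TOKENS},)"
            )
        if vec.min() < -_PROB_ATOL or abs(vec.sum() - 1.0) > _PROB_ATOL:
            raise ValueError(
                f"model distribution at position {i} is not a probability vector"
            )
        rows[i] = vec
    return rows


class UniformModel(ConditionalSequenceModel):
    """Uninformed baseline: probability 1/20 on each residue, 0 on the end token."""

    def next_distribution(self, source: str, target_prefix: str) -> np.ndarray:
        vec = np.full(N_TOKENS, 1.0 / N_RESIDUES)
        vec[END_INDEX] = 0.0
        return vec


class ProfileModel(ConditionalSequenceModel):
    """Position-independent (or per-position) residue-frequency model.

    ``frequencies`` is either one mapping residue → weight applied at every
    position, or a sequence of such mappings indexed by target position.
    Weights are normalized over the 20 residues; the end token receives
    probability 0 while a per-position profile exists and probability 1
    beyond the last profile (per-position mode only).
    """

    def __init__(
        self,
        frequencies: Mapping[str, float] | Sequence[Mapping[str, float]],
    ) -> None:
        if isinstance(frequencies, Mapping):
            self._global = self._normalize(frequencies)
            self._per_position = None
        else:
            self._global = None
            self._per_position = [self._normalize(f) for f in frequencies]

    @staticmethod
    def _normalize(freqs: Mapping[str, float]) -> np.ndarray:
        vec = np.zeros(N_TOKENS)
        for aa, w in freqs.items():
            if aa not in AA_INDEX:
                raise SequenceAlphabetError(f"profile key {aa!r} is not a canonical residue")
            if w < 0:
                raise ValueError(f"negative frequency for {aa!r}")
            vec[AA_INDEX[aa]] = w
        total = vec.sum()
        if total <= 0:
            raise ValueError("profile has no positive frequencies")
        return vec / total

    def next_distribution(self, source: str, target_prefix: str) -> np.ndarray:
        if self._global is not None:
            return self._global.copy()
        assert self._per_position is not None
        i = len(target_prefix)
        if i < len(self._per_position):
            return self._per_position[i].copy()
        vec = np.zeros(N_TOKENS)
        vec[END_INDEX] = 1.0
        return vec


class ScriptedModel(ConditionalSequenceModel):
    """Model defined by an explicit list of per-position distributions.

    Depends on the target position only (not on the prefix content); after
    the last scripted row all mass moves to the end token.  Used as a
    hand-settable oracle for decoding and scoring tests.
    """

    def __init__(self, rows: Sequence[Sequence[float]]) -> None:
        self.rows = [np.asarray(r, dtype=float) for r in rows]
        for k, r in enumerate(self.rows):
            if r.shape != (N_TOKENS,):
                raise ValueError(f"row {k} has shape {r.shape}, expected ({N_TOKENS},)")
            if r.min() < 0 or abs(r.sum() - 1.0) > _PROB_ATOL:
                raise ValueError(f"row {k} is not a probability vector")

    def next_distribution(self, source: str, target_prefix: str) -> np.ndarray:
        i = len(target_prefix)
        if i < len(self.rows):
            return self.rows[i].copy()
        vec = np.zeros(N_TOKENS)
        vec[END_INDEX] = 1.0
        return vec


# ---------------------------------------------------------------------------
# Tiny trainable translator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer and early-stopping settings for the tiny translator.

    ``max_learning_rate`` is the peak of a linear ramp-up/ramp-down
    schedule; early stopping halts when validation loss fails to improve on
    the best value by ``improvement_threshold`` nats for ``patience``
    consecutive evaluations (one per epoch).
    """

    max_learning_rate: float = 1e-4
    warmup_fraction: float = 0.1
    patience: int = 4
    improvement_threshold: float = 0.1
    batch_size: int = 128
    max_epochs: int = 50
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be ≥ 1")
        for name in ("warmup_fraction", "validation_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0,1)")
        if self.max_learning_rate <= 0:
            raise ValueError("max_learning_rate must be positive")


# feature vocabulary: 20 residues, END, START, PAD
_F_START = N_TOKENS          # 21
_F_PAD = N_TOKENS + 1        # 22
_F_VOCAB = N_TOKENS + 2      # 23
_WINDOW = (-1, 0, 1)         # source positions relative to the target index
_N_FEATURES = _F_VOCAB * (len(_WINDOW) + 1)


def _source_symbol(source_idx: list[int], pos: int) -> int:
    if 0 <= pos < len(source_idx):
        return source_idx[pos]
    return _F_PAD


def _feature_indices(source_idx: list[int], prev_token: int, i: int) -> list[int]:
    """Active one-hot feature slots for target position ``i``."""
    slots = []
    for k, off in enumerate(_WINDOW):
        slots.append(k * _F_VOCAB + _source_symbol(source_idx, i + off))
    slots.append(len(_WINDOW) * _F_VOCAB + prev_token)
    return slots


def _encode_residues(seq: str) -> list[int]:
    out = []
    for pos, ch in enumerate(seq):
        if ch not in TOKEN_INDEX or ch == END_TOKEN:
            raise SequenceAlphabetError(
                f"residue {ch!r} at position {pos} outside the model alphabet"
            )
        out.append(TOKEN_INDEX[ch])
    return out


class TinyTranslator(ConditionalSequenceModel):
    """Compact trainable meso→thermo translator (linear-softmax decoder)."""

    def __init__(self, weights: np.ndarray, bias: np.ndarray) -> None:
        if weights.shape != (_N_FEATURES, N_TOKENS) or bias.shape != (N_TOKENS,):
            raise ValueError("weight shapes do not match the feature layout")
        self.weights = weights
        self.bias = bias
        self.history: list[float] = []
        self.best_val_loss: float | None = None

    @classmethod
    def zeros(cls) -> "TinyTranslator":
        return cls(np.zeros((_N_FEATURES, N_TOKENS)), np.zeros(N_TOKENS))

    def next_distribution(self, source: str, target_prefix: str) -> np.ndarray:
        src = _encode_residues(source)
        i = len(target_prefix)
        prev = _F_START if i == 0 else _encode_residues(target_prefix[-1])[0]
        logits = self.bias + self.weights[_feature_indices(src, prev, i)].sum(axis=0)
        logits -= logits.max()
        exp = np.exp(logits)
        return exp / exp.sum()

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        np.savez(path, weights=self.weights, bias=self.bias)

    @classmethod
    def load(cls, path) -> "TinyTranslator":
        data = np.load(path)
        return cls(data["weights"], data["bias"])


def _build_examples(pairs) -> tuple[np.ndarray, np.ndarray]:
    """Teacher-forcing token examples: feature slot matrix + target labels.

    One example per thermo position plus one end-of-sequence example per pair.
    """
    feats, labels = [], []
    for rec in pairs:
        src = _encode_residues(rec.meso_seq.replace("X", "A"))
        tgt = _encode_residues(rec.thermo_seq.replace("X", "A"))
        for i in range(len(tgt) + 1):
            prev = _F_START if i == 0 else tgt[i - 1]
            feats.append(_feature_indices(src, prev, i))
            labels.append(tgt[i] if i < len(tgt) else END_INDEX)
    return np.asarray(feats, dtype=np.int64), np.asarray(labels, dtype=np.int64)


def _cross_entropy(model: TinyTranslator, feats: np.ndarray, labels: np.ndarray) -> float:
    logits = model.bias + model.weights[feats].sum(axis=1)
    logits -= logits.max(axis=1, keepdims=True)
    logz = np.log(np.exp(logits).sum(axis=1))
    return float(np.mean(logz - logits[np.arange(len(labels)), labels]))


def train_tiny_translator(pairs, cfg: TrainingConfig | None = None) -> TinyTranslator:
    """Train the tiny translator on homolog pairs with teacher forcing.

    An internal validation subset (``validation_fraction`` of the pairs) is
    held out; training minimizes per-token categorical cross entropy with
    Adam under a linear warmup/decay schedule and stops early on validation
    loss.  Returns the model state with the best validation loss seen.
    """
    cfg = cfg or TrainingConfig()
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to train (one must be held out)")

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(pairs))
    n_val = max(1, int(round(cfg.validation_fraction * len(pairs))))
    val_pairs = [pairs[i] for i in order[:n_val]]
    train_pairs = [pairs[i] for i in order[n_val:]]
    if not train_pairs:
        raise ValueError("validation split consumed all pairs")

    Xtr, ytr = _build_examples(train_pairs)
    Xva, yva = _build_examples(val_pairs)

    model = TinyTranslator.zeros()
    mW = np.zeros_like(model.weights); vW = np.zeros_like(model.weights)
    mb = np.zeros_like(model.bias); vb = np.zeros_like(model.bias)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n_train = len(ytr)
    steps_per_epoch = max(1, -(-n_train // cfg.batch_size))
    total_steps = steps_per_epoch * cfg.max_epochs
    warmup_steps = max(1, int(cfg.warmup_fraction * total_steps))

    best = np.inf
    best_state = (model.weights.copy(), model.bias.copy())
    wait = 0
    history: list[float] = []

    for _epoch in range(cfg.max_epochs):
        perm = rng.permutation(n_train)
        for start in range(0, n_train, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            fb, yb = Xtr[idx], ytr[idx]
            logits = model.bias + model.weights[fb].sum(axis=1)
            logits -= logits.max(axis=1, keepdims=True)
            exp = np.exp(logits)
            probs = exp / exp.sum(axis=1, keepdims=True)
            probs[np.arange(len(yb)), yb] -= 1.0
            probs /= len(yb)
            gW = np.zeros_like(model.weights)
            for col in range(fb.shape[1]):
                np.add.at(gW, fb[:, col], probs)
            gb = probs.sum(axis=0)

            step += 1
            if step <= warmup_steps:
                lr = cfg.max_learning_rate * step / warmup_steps
            else:
                frac = (step - warmup_steps) / max(1, total_steps - warmup_steps)
                lr = cfg.max_learning_rate * max(0.0, 1.0 - frac)
            for g, m, v, param in ((gW, mW, vW, model.weights), (gb, mb, vb, model.bias)):
                m *= beta1; m += (1 - beta1) * g
                v *= beta2; v += (1 - beta2) * g * g
                mhat = m / (1 - beta1 ** step)
                vhat = v / (1 - beta2 ** step)
                param -= lr * mhat / (np.sqrt(vhat) + eps)

        val = _cross_entropy(model, Xva, yva)
        history.append(val)
        if val < best - 1e-12:
            best_state = (model.weights.copy(), model.bias.copy())
        if val < best - cfg.improvement_threshold:
            best = val
            wait = 0
        else:
            best = min(best, val)
            wait += 1
            if wait >= cfg.patience:
                break

    model.weights, model.bias = best_state
    model.history = history
    model.best_val_loss = float(min(history)) if history else None
    return model


# ---------------------------------------------------------------------------
# Beam search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeamResult:
    """Decoded sequence with its cumulative log probability.

    ``collapsed`` flags a decode in which no beam reached the end token
    within ``max_len`` positions; the returned sequence is then the best
    incomplete beam and should not be trusted as a full translation.
    """

    sequence: str
    log_prob: float
    collapsed: bool


def beam_search(
    model: ConditionalSequenceModel,
    source: str,
    beam_width: int = 10,
    max_len: int = 512,
) -> BeamResult:
    """Breadth-limited best-first decoding.

    Keeps the ``beam_width`` highest cumulative-log-probability partial
    sequences at each depth; a sequence completes when the end token is
    emitted, and its score includes the end-token term.  Ties are broken
    lexicographically.  ``beam_width=1`` reduces to greedy argmax rollout.
    """
    if beam_width < 1:
        raise ValueError("beam_width must be ≥ 1")
    if max_len <= 0:
        raise ValueError("max_len must be positive")

    beams: list[tuple[str, float]] = [("", 0.0)]
    completed: list[tuple[float, str]] = []
    with np.errstate(divide="ignore"):
        for _depth in range(max_len):
            candidates: list[tuple[float, str, bool]] = []
            for seq, lp in beams:
                dist = np.asarray(model.next_distribution(source, seq), dtype=float)
                logd = np.log(np.clip(dist, 0.0, None))
                for t in range(N_TOKENS):
                    if not np.isfinite(logd[t]):
                        continue
                    if t == END_INDEX:
                        candidates.append((lp + logd[t], seq, True))
                    else:
                        candidates.append((lp + logd[t], seq + AA20[t], False))
            if not candidates:
                break
            candidates.sort(key=lambda c: (-c[0], c[1]))
            new_beams: list[tuple[str, float]] = []
            for score, seq, done in candidates:
                if done:
                    # completed hypotheses do not consume beam slots
                    completed.append((score, seq))
                elif len(new_beams) < beam_width:
                    new_beams.append((seq, score))
            beams = new_beams
            if not beams:
                break
        # beams that used the full length budget may still terminate cleanly
        for seq, lp in beams:
            dist = np.asarray(model.next_distribution(source, seq), dtype=float)
            p_end = dist[END_INDEX]
            if p_end > 0.0:
                completed.append((lp + float(np.log(p_end)), seq))

    if completed:
        best_score = max(s for s, _ in completed)
        best_seq = min(seq for s, seq in completed if s == best_score)
        return BeamResult(sequence=best_seq, log_prob=best_score, collapsed=False)
    # collapse: no complete sequence within max_len
    if beams:
        best = max(beams, key=lambda b: (b[1], b[0]))
        return BeamResult(sequence=best[0], log_prob=best[1], collapsed=True)
    return BeamResult(sequence="", log_prob=float("-inf"), collapsed=True)
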