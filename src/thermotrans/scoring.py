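"""Causal log-likelihood scoring of protein variants.

Given a conditional sequence model P_i(·|x_0..x_{i-1}) conditioned on a
(mesophilic) source protein, the thermophilicity score of a sequence or a
set of mutations M is the mean natural-log probability

    L(x) = (1/|M|) Σ_{i∈M} ln P_i(x_i)

and a variant is compared to the wild type by ΔL = L(variant) − L(WT):
positive ΔL means the variant looks more like a thermophilic homolog of
the source than the wild type does.  For substitution-only variants
(equal lengths) only the mutated positions are scored; when lengths
differ (indels) whole-sequence means are compared instead.

The per-token categorical cross entropy CCE = −L(all positions) is the
model's loss statistic; the MSA column-profile baseline gives the same
quantity under a position-independent model of natural variation over
thermophilic homologs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alphabet import AA_INDEX, AA20, GAP_CHARS
from .translator import ConditionalSequenceModel, predict_stepwise

__all__ = [
    "LikelihoodScore",
    "DeltaScore",
    "MSAColumnProfiles",
    "log_likelihood",
    "delta_log_likelihood",
    "categorical_cross_entropy",
    "msa_column_profiles",
    "natural_cross_entropy",
]


@dataclass(frozen=True)
class LikelihoodScore:
    """Mean natural-log probability over a set of scored positions (nats)."""

    value: float
    positions: frozenset[int]
    mode: str  # "mutation-set" | "full-sequence"


@dataclass(frozen=True)
class DeltaScore:
    """Wild-type-relative likelihood ΔL = L(variant) − L(WT), in nats."""

    value: float
    variant_id: str
    wt_id: str
    mode: str
    positions: frozenset[int]


def _ln_prob(probs: np.ndarray, i: int, residue: str) -> float:
    j = AA_INDEX.get(residue)
    if j is None:
        raise ValueError(f"cannot score non-canonical residue {residue!r} at position {i}")
    p = probs[i, j]
    if p <= 0.0:
        warnings.warn(
            f"zero probability for residue {residue!r} at position {i}; "
            "log-likelihood is -inf",
            stacklevel=3,
        )
        return float("-inf")
    return float(np.log(p))


def log_likelihood(
    probs: np.ndarray,
    target: str,
    positions: Iterable[int] | None = None,
) -> LikelihoodScore:
    """Mean ln P_i(target_i) over ``positions`` (default: all positions).

    ``probs`` is a stepwise (teacher-forcing) probability matrix whose row i
    is the model's distribution for position i.  A zero-probability target
    residue yields −inf with a warning rather than an exception.
    """
    if not target:
        raise ValueError("target must be non-empty")
    if probs.shape[0] < len(target):
        raise ValueError(
            f"probability matrix has {probs.shape[0]} rows for target of length {len(target)}"
        )
    if positions is None:
        pos = frozenset(range(len(target)))
        mode = "full-sequence"
    else:
        pos = frozenset(int(i) for i in positions)
        bad = [i for i in pos if not (0 <= i < len(target))]
        if bad:
            raise ValueError(f"positions outside target: {sorted(bad)}")
        mode = "mutation-set"
    if not pos:
        return LikelihoodScore(value=0.0, positions=pos, mode=mode)
    value = float(np.mean([_ln_prob(probs, i, target[i]) for i in sorted(pos)]))
    return LikelihoodScore(value=value, positions=pos, mode=mode)


def categorical_cross_entropy(probs: np.ndarray, target: str) -> float:
    """Mean per-residue categorical cross entropy, −L over all positions (nats)."""
    return -log_likelihood(probs, target).value


def delta_log_likelihood(
    model: ConditionalSequenceModel,
    source: str,
    wt: str,
    variant: str,
    *,
    wt_id: str = "WT",
    variant_id: str = "variant",
    prefix_mode: str = "own",
) -> DeltaScore:
    """Score a variant against the wild type under a causal model.

    Equal-length pairs are scored in mutation-set mode: M is the set of
    differing positions and each sequence is teacher-forced on its own
    prefix (``prefix_mode="own"``, default) or both on the wild-type prefix
    (``prefix_mode="wt"``).  Length-changing variants switch to
    full-sequence mode, comparing length-normalized whole-sequence means.
    """
    if not wt or not variant:
        raise ValueError("wt and variant must be non-empty")
    if prefix_mode not in ("own", "wt"):
        raise ValueError("prefix_mode must be 'own' or 'wt'")

    if len(variant) == len(wt):
        diff = frozenset(i for i, (a, b) in enumerate(zip(wt, variant)) if a != b)
        if not diff:
            return DeltaScore(0.0, variant_id, wt_id, "mutation-set", frozenset())
        probs_wt = predict_stepwise(model, source, wt)
        if prefix_mode == "own":
            probs_var = predict_stepwise(model, source, variant)
        else:
            probs_var = probs_wt  # same conditioning rows, different scored residues
        l_var = log_likelihood(probs_var, variant, diff).value
        l_wt = log_likelihood(probs_wt, wt, diff).value
        return DeltaScore(l_var - l_wt, variant_id, wt_id, "mutation-set", diff)

    probs_var = predict_stepwise(model, source, variant)
    probs_wt = predict_stepwise(model, source, wt)
    l_var = log_likelihood(probs_var, variant).value
    l_wt = log_likelihood(probs_wt, wt).value
    return DeltaScore(
        l_var - l_wt,
        variant_id,
        wt_id,
        "full-sequence",
        frozenset(range(len(variant))),
    )


# ---------------------------------------------------------------------------
# MSA natural-variation baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MSAColumnProfiles:
    """Residue distributions over natural diversity, one per reference column.

    ``profiles[k]`` is the probability vector (AA20 order) for the k-th
    non-gap column of the reference sequence in the alignment.
    """

    profiles: np.ndarray  # (n_reference_positions, 20)
    reference_id: str

    def __len__(self) -> int:
        return self.profiles.shape[0]


def msa_column_profiles(
    msa: Sequence[tuple[str, str]],
    reference_id: str,
    pseudocount: float = 1e-3,
) -> MSAColumnProfiles:
    """Column residue profiles of an MSA at the reference's non-gap columns.

    ``msa`` is a list of (id, aligned sequence) with equal aligned lengths.
    Counts run over non-gap canonical residues in each column; a
    ``pseudocount`` is added per residue before normalization so unobserved
    residues keep small positive probability.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    by_id = dict(msa)
    if len(by_id) != len(msa):
        raise ValueError("duplicate ids in MSA")
    if reference_id not in by_id:
        raise ValueError(f"reference id {reference_id!r} not present in MSA")
    ref = by_id[reference_id].upper()
    lengths = {len(s) for _, s in msa}
    if len(lengths) != 1:
        raise ValueError(f"aligned lengths differ: {sorted(lengths)}")

    cols = [k for k, ch in enumerate(ref) if ch not in GAP_CHARS]
    profiles = np.zeros((len(cols), len(AA20)))
    for out_i, k in enumerate(cols):
        counts = np.full(len(AA20), pseudocount, dtype=float)
        for _sid, seq in msa:
            ch = seq[k].upper()
            j = AA_INDEX.get(ch)
            if j is not None:
                counts[j] += 1.0
        total = counts.sum()
        if total <= 0:
            raise ValueError(
                f"column {k} has no observed residues and zero pseudocount"
            )
        profiles[out_i] = counts / total
    return MSAColumnProfiles(profiles=profiles, reference_id=reference_id)


def natural_cross_entropy(profiles: MSAColumnProfiles, target: str) -> float:
    """Mean −ln P_i(target_i) under the MSA natural-variation profiles (nats)."""
    if len(target) != len(profiles):
        raise ValueError(
            f"target length {len(target)} does not match {len(profiles)} profiles"
        )
    values = []
    for i, ch in enumerate(target.upper()):
        j = AA_INDEX.get(ch)
        if j is None:
            raise ValueError(f"cannot score non-canonical residue {ch!r} at position {i}")
        p = profiles.profiles[i, j]
        if p <= 0.0:
            warnings.warn(
                f"zero natural probability at position {i}; cross entropy is +inf",
                stacklevel=2,
            )
            values.append(float("inf"))
        else:
            values.append(-float(np.log(p)))
    return float(np.mean(values))
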