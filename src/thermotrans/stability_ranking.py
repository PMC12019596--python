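"""Length-normalized ensemble stability scoring and variant comparison.

A variant's thermal stability is proxied by the mean of an ensemble of
free-energy-like scores (e.g. Rosetta energies over predicted structure
ensembles, default ensemble size 25), normalized by the number of residues
so variants with insertions or deletions remain comparable.  Lower
(more negative) per-residue energy means more stable.  Two variants are
compared with a seeded bootstrap interval on the difference of per-residue
means; "confidently stabilizing" means the 95% interval excludes zero on
the stabilizing (negative) side.  The structure predictor and energy
scorer themselves are external oracles: this module only consumes their
per-structure score lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StabilityEstimate",
    "StabilityComparison",
    "normalized_stability",
    "compare_stability",
    "rank_correlation",
]

DEFAULT_ENSEMBLE_SIZE = 25


@dataclass(frozen=True)
class StabilityEstimate:
    """Ensemble-mean energy per residue (score units / residue)."""

    mean_energy_per_residue: float
    ensemble_values: tuple[float, ...]
    n_residues: int

    @property
    def ensemble_size(self) -> int:
        return len(self.ensemble_values)


@dataclass(frozen=True)
class StabilityComparison:
    """Bootstrap comparison of two per-residue stability estimates (a − b)."""

    delta: float
    ci95: tuple[float, float]
    confident_stabilizing: bool


def normalized_stability(
    energies: Sequence[float], n_residues: int
) -> StabilityEstimate:
    """Ensemble-mean energy divided by residue count; lower is more stable."""
    if n_residues < 1:
        raise ValueError("n_residues must be ≥ 1")
    values = tuple(float(e) for e in energies)
    if not values:
        raise ValueError("energies must be non-empty")
    return StabilityEstimate(
        mean_energy_per_residue=float(np.mean(values)) / n_residues,
        ensemble_values=values,
        n_residues=n_residues,
    )


def compare_stability(
    a: StabilityEstimate,
    b: StabilityEstimate,
    n_boot: int = 2000,
    seed: int = 0,
) -> StabilityComparison:
    """Bootstrap 95% interval on the difference of per-residue means (a − b).

    Each ensemble is resampled with replacement ``n_boot`` times; the
    interval is the 2.5/97.5 percentile of the resampled differences.
    ``confident_stabilizing`` is true when the interval lies entirely below
    zero, i.e. a is confidently more stable than b.
    """
    if a.ensemble_size < 2 or b.ensemble_size < 2:
        raise ValueError("both ensembles need at least 2 values")
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} is small for a 95% interval", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    va = np.asarray(a.ensemble_values) / a.n_residues
    vb = np.asarray(b.ensemble_values) / b.n_residues
    idx_a = rng.integers(0, va.size, size=(n_boot, va.size))
    idx_b = rng.integers(0, vb.size, size=(n_boot, vb.size))
    deltas = va[idx_a].mean(axis=1) - vb[idx_b].mean(axis=1)
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    delta = a.mean_energy_per_residue - b.mean_energy_per_residue
    return StabilityComparison(
        delta=float(delta),
        ci95=(float(lo), float(hi)),
        confident_stabilizing=bool(hi < 0.0),
    )


def rank_correlation(
    scores: Sequence[float], truths: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) with its p-value.

    Constant input makes the correlation undefined; it is reported as NaN
    with a warning rather than raising.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truths, dtype=float)
    if s.size != t.size:
        raise ValueError("scores and truths must have equal length")
    if s.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(s == s[0]) or np.all(t == t[0]):
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(s, t)
    return float(rho), float(p)
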