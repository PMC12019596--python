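"""Disulfide-bond labeling from Cα geometry and the cysteine-bias test.

Disulfide bonds are posited with a Cα-distance heuristic: two cysteines
whose alpha carbons sit strictly closer than 7.5 Å are taken to form a
bond.  Because a causal model only sees residues to the left, the *second*
cysteine of a bonded pair is the one whose placement "completes" the bond
at inference time; it alone is labeled bond-forming.  The bias test asks
whether a model assigns higher cysteine log-likelihood at bond-completing
positions than at non-bonding ones (one-sided Welch t-test).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StructureModel",
    "DisulfideLabel",
    "label_disulfides",
    "cysteine_bias_test",
]

DEFAULT_DISULFIDE_THRESHOLD = 7.5  # Å, strict upper bound on Cα–Cα distance


@dataclass(frozen=True)
class StructureModel:
    """Per-residue Cα coordinates (Å), index-aligned to a sequence.

    ``residue_numbers`` carries the author numbering (1-based by default);
    internal indexing is 0-based.
    """

    coords: np.ndarray  # (n, 3)
    residue_numbers: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords contain non-finite values")
        object.__setattr__(self, "coords", coords)
        if not self.residue_numbers:
            object.__setattr__(
                self, "residue_numbers", tuple(range(1, coords.shape[0] + 1))
            )
        elif len(self.residue_numbers) != coords.shape[0]:
            raise ValueError("residue_numbers length does not match coords")

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class DisulfideLabel:
    """Bond assignment for one cysteine (0-based sequence positions)."""

    position: int
    partner: int | None
    bond_forming_causal: bool


def label_disulfides(
    structure: StructureModel,
    sequence: str,
    threshold: float = DEFAULT_DISULFIDE_THRESHOLD,
) -> list[DisulfideLabel]:
    """Label each cysteine by the Cα-distance disulfide heuristic.

    Candidate pairs are cysteine pairs with Cα distance strictly below
    ``threshold``; they are accepted greedily by ascending distance with
    each cysteine in at most one pair.  In each accepted pair the
    later-indexed cysteine gets ``bond_forming_causal=True`` (it completes
    the bond from a left-to-right generator's perspective); every other
    cysteine is labeled non-bonding.
    """
    if len(structure) != len(sequence):
        raise ValueError(
            f"structure has {len(structure)} residues but sequence has {len(sequence)}"
        )
    cys = [i for i, ch in enumerate(sequence.upper()) if ch == "C"]
    candidates = []
    for a_idx, i in enumerate(cys):
        for j in cys[a_idx + 1 :]:
            d = float(np.linalg.norm(structure.coords[i] - structure.coords[j]))
            if d < threshold:
                candidates.append((d, i, j))
    candidates.sort()
    used: set[int] = set()
    partner: dict[int, int] = {}
    for _d, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        partner[i] = j
        partner[j] = i
    labels = []
    for i in cys:
        p = partner.get(i)
        labels.append(
            DisulfideLabel(
                position=i,
                partner=p,
                bond_forming_causal=(p is not None and i > p),
            )
        )
    return labels


def cysteine_bias_test(
    loglik_bonded: Sequence[float],
    loglik_nonbonded: Sequence[float],
) -> tuple[float, float]:
    """One-sided Welch t-test: bonded cysteine log-likelihoods exceed non-bonded.

    Returns (t_statistic, one_sided_p) for H1: mean(bonded) > mean(non-bonded).
    Degenerate (zero-variance) inputs produce an infinite statistic with the
    appropriate limiting p-value rather than an error.
    """
    bonded = np.asarray(loglik_bonded, dtype=float)
    nonbonded = np.asarray(loglik_nonbonded, dtype=float)
    if bonded.size < 2 or nonbonded.size < 2:
        raise ValueError("need at least 2 observations per group")
    if bonded.var(ddof=1) == 0.0 and nonbonded.var(ddof=1) == 0.0:
        diff = bonded.mean() - nonbonded.mean()
        if diff == 0.0:
            return 0.0, 0.5
        return (float("inf"), 0.0) if diff > 0 else (float("-inf"), 1.0)
    res = stats.ttest_ind(bonded, nonbonded, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.pvalue)
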