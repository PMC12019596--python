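"""Translation-evaluation metric battery.

Implements the sequence-level metrics used to judge how well a generated
(thermophile-like) sequence recapitulates its ground-truth thermophilic
homolog: pairwise alignment identity and BLOSUM62 bits-per-residue,
residue-level transcription error rate, relative length difference,
secondary-structure composition Jensen–Shannon divergence, and the pooled
amino-acid frequency shift between two sequence sets.

Alignments use a global alignment with free end gaps (match +1,
mismatch −1, gap open −4, gap extend −1); the substitution-matrix score is
computed on the resulting alignment with BLOSUM62 half-bit entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial.distance import jensenshannon

from .alphabet import AA20

__all__ = [
    "AlignmentResult",
    "SSComposition",
    "align_pair",
    "alignment_identity",
    "transcription_error_rate",
    "js_divergence",
    "length_difference",
    "aa_frequency_shift",
    "ss_composition",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

SS_STATES = ("H", "E", "L")
# 8-state DSSP collapsed to three states: helices (H,G,I), strands (E,B), rest loop.
_SS8_TO_3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "L", "S": "L", "C": "L", "-": "L", "L": "L", " ": "L", "P": "L",
}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aligner.open_end_gap_score = 0
    aligner.extend_end_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class AlignmentResult:
    """A scored pairwise alignment.

    ``matrix_score`` is the BLOSUM62 total over aligned (non-gap) columns in
    half-bits; ``bits_per_residue`` converts it to bits and divides by the
    number of aligned residue pairs.  ``identity`` is exact matches divided
    by alignment columns excluding terminal gap overhangs.
    """

    aligned_a: str
    aligned_b: str
    identity: float
    matrix_score: float
    bits_per_residue: float
    n_columns: int
    n_aligned_pairs: int


@dataclass(frozen=True)
class SSComposition:
    """Probability vector over (Helix, Strand, Loop)."""

    probs: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.probs, dtype=float)
        if arr.min() < 0:
            raise ValueError("secondary-structure composition must be non-negative")
        if not np.isclose(arr.sum(), 1.0, atol=1e-6):
            raise ValueError("secondary-structure composition must sum to 1")


def _blosum_lookup(a: str, b: str) -> float:
    try:
        return float(_BLOSUM62[a, b])
    except KeyError:
        warnings.warn(
            f"residue pair ({a},{b}) not in BLOSUM62; scoring via X", stacklevel=3
        )
        a2 = a if a in _BLOSUM62.alphabet else "X"
        b2 = b if b in _BLOSUM62.alphabet else "X"
        return float(_BLOSUM62[a2, b2])


def align_pair(a: str, b: str) -> AlignmentResult:
    """Globally align two protein sequences (free end gaps) and score them.

    Identity counts exact matches over columns between the first and last
    column where both sequences are present (terminal overhangs excluded).
    The matrix score sums BLOSUM62 entries over columns where both rows are
    residues; bits_per_residue = matrix_score / 2 / n_aligned_pairs.
    """
    if not a or not b:
        raise ValueError("align_pair requires two non-empty sequences")
    aln = _ALIGNER.align(a.upper(), b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])

    both = [i for i, (x, y) in enumerate(zip(row_a, row_b)) if x != "-" and y != "-"]
    if not both:
        # degenerate: nothing aligned at all
        return AlignmentResult(row_a, row_b, 0.0, 0.0, 0.0, len(row_a), 0)
    lo, hi = both[0], both[-1]

    matches = sum(
        1 for x, y in zip(row_a[lo : hi + 1], row_b[lo : hi + 1]) if x == y and x != "-"
    )
    identity = matches / (hi - lo + 1)

    matrix_score = sum(
        _blosum_lookup(row_a[i], row_b[i]) for i in both
    )
    bits_per_residue = matrix_score / 2.0 / len(both)
    return AlignmentResult(
        aligned_a=row_a,
        aligned_b=row_b,
        identity=identity,
        matrix_score=matrix_score,
        bits_per_residue=bits_per_residue,
        n_columns=len(row_a),
        n_aligned_pairs=len(both),
    )


def alignment_identity(a: str, b: str) -> float:
    """Pairwise identity under the package-wide alignment definition."""
    return align_pair(a, b).identity


def transcription_error_rate(pairs: Sequence[tuple[str, str]]) -> float:
    """Residue-level error rate of generated sequences against ground truths.

    Errors are positional mismatches over the overlapping prefix plus the
    absolute length difference (missing or extra residues each count as one
    error); the total is normalized by the summed ground-truth lengths, so
    the statistic is a per-residue rate over the whole set rather than a
    per-sequence average.
    """
    if not pairs:
        raise ValueError("transcription_error_rate requires at least one pair")
    errors = 0
    total = 0
    for generated, truth in pairs:
        if not truth:
            warnings.warn("skipping pair with empty ground-truth sequence", stacklevel=2)
            continue
        overlap = min(len(generated), len(truth))
        errors += sum(1 for g, t in zip(generated[:overlap], truth[:overlap]) if g != t)
        errors += abs(len(generated) - len(truth))
        total += len(truth)
    if total == 0:
        raise ValueError("all ground-truth sequences were empty")
    return errors / total


def _as_composition(p: "SSComposition | Sequence[float]") -> np.ndarray:
    arr = np.asarray(p.probs if isinstance(p, SSComposition) else p, dtype=float)
    s = arr.sum()
    if not np.isclose(s, 1.0, atol=1e-9):
        warnings.warn("composition not normalized; renormalizing", stacklevel=3)
        arr = arr / s
    return arr


def js_divergence(p, q) -> float:
    """Base-2 Jensen–Shannon divergence between two compositions.

    Symmetric, bounded in [0, 1]; 0 iff the compositions are equal and 1 for
    disjoint supports.
    """
    parr, qarr = _as_composition(p), _as_composition(q)
    val = float(jensenshannon(parr, qarr, base=2) ** 2)
    if np.isnan(val):  # identical distributions can yield 0/0 inside the sqrt
        return 0.0
    return min(max(val, 0.0), 1.0)


def length_difference(generated: str, truth: str) -> float:
    """Relative length difference |len(generated) − len(truth)| / len(truth)."""
    if not truth:
        raise ValueError("ground-truth sequence must be non-empty")
    return abs(len(generated) - len(truth)) / len(truth)


def _pooled_frequencies(seqs: Iterable[str]) -> np.ndarray:
    counts = np.zeros(len(AA20), dtype=float)
    index = {aa: i for i, aa in enumerate(AA20)}
    for seq in seqs:
        for ch in seq.upper():
            i = index.get(ch)
            if i is not None:  # X and other non-canonical residues excluded
                counts[i] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence set contains no canonical residues")
    return counts / total


def aa_frequency_shift(
    set_a: Iterable[str], set_b: Iterable[str]
) -> Mapping[str, float]:
    """Per-residue pooled frequency delta (set_b − set_a); deltas sum to 0."""
    fa = _pooled_frequencies(set_a)
    fb = _pooled_frequencies(set_b)
    return {aa: float(fb[i] - fa[i]) for i, aa in enumerate(AA20)}


def ss_composition(ss_string: str) -> SSComposition:
    """Collapse a DSSP-style secondary-structure string to an H/E/L composition."""
    if not ss_string:
        raise ValueError("empty secondary-structure string")
    counts = {s: 0 for s in SS_STATES}
    for ch in ss_string.upper():
        counts[_SS8_TO_3.get(ch, "L")] += 1
    n = len(ss_string)
    return SSComposition((counts["H"] / n, counts["E"] / n, counts["L"] / n))
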