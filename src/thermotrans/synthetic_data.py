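"""Synthetic fixtures: pair tables, rule-based translations, toy structures.

Everything the rest of the package consumes can be generated here at desk
scale, with no downloads: OGT-labeled homolog-pair tables with
controllable identity/indel/coverage structure, meso→thermo pairs related
by an explicit substitution rule (learnable by the tiny translator and
analytically checkable by the frequency-shift metrics), and toy Cα-only
structures with a cysteine pair placed at a requested distance.

Generated statistics are true by construction: coverage and length
difference stored on each pair follow from the exact edit operations
applied, so brute-force re-derivation from the stored sequences agrees
with them.  Every generator is bit-deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alphabet import AA20, AA_INDEX
from .pair_curation import PairRecord
from .structure_analysis import StructureModel

__all__ = [
    "PairTableSpec",
    "TranslationRule",
    "generate_pair_table",
    "generate_rule_pairs",
    "generate_toy_structure",
    "generate_family_sequences",
]

CA_SPACING = 3.8  # Å between consecutive Cα atoms
MIN_NONBOND_DISTANCE = 3.5  # Å floor for all non-designated inter-Cα distances


def _check_range(name: str, rng: tuple[float, float], lo=None, hi=None) -> None:
    a, b = rng
    if a > b:
        raise ValueError(f"{name}: range ({a}, {b}) is not ordered lo ≤ hi")
    if lo is not None and a < lo:
        raise ValueError(f"{name}: lower bound {a} below {lo}")
    if hi is not None and b > hi:
        raise ValueError(f"{name}: upper bound {b} above {hi}")


@dataclass(frozen=True)
class PairTableSpec:
    """Parameters of a synthetic homolog-pair table.

    OGT ranges are in Kelvin; identity/coverage ranges are fractions.
    ``residue_frequencies`` optionally biases the residue draw (default
    uniform over the 20 canonical residues), which makes frequency-shift
    analytics exactly predictable.
    """

    n_pairs: int
    seed: int = 0
    ogt_meso_range: tuple[float, float] = (280.0, 312.0)
    ogt_thermo_range: tuple[float, float] = (333.0, 363.0)
    identity_range: tuple[float, float] = (0.60, 0.90)
    indel_rate: float = 0.10
    coverage_range: tuple[float, float] = (0.96, 1.0)
    length_range: tuple[int, int] = (60, 120)
    residue_frequencies: Mapping[str, float] | None = None
    alphabet: str = AA20

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be non-negative")
        _check_range("ogt_meso_range", self.ogt_meso_range, lo=0.0)
        _check_range("ogt_thermo_range", self.ogt_thermo_range, lo=0.0)
        _check_range("identity_range", self.identity_range, lo=0.0, hi=1.0)
        _check_range("coverage_range", self.coverage_range, lo=0.0, hi=1.0)
        _check_range("length_range", self.length_range, lo=1)
        if not (0.0 <= self.indel_rate <= 1.0):
            raise ValueError("indel_rate must lie in [0,1]")
        if set(self.alphabet) - set(AA20):
            raise ValueError("alphabet must be a subset of the 20 canonical residues")


def _frequency_vector(spec: PairTableSpec) -> np.ndarray:
    letters = list(spec.alphabet)
    if spec.residue_frequencies is None:
        return np.full(len(letters), 1.0 / len(letters))
    vec = np.array([spec.residue_frequencies.get(a, 0.0) for a in letters], dtype=float)
    if vec.min() < 0 or vec.sum() <= 0:
        raise ValueError("residue_frequencies must be non-negative with positive sum")
    return vec / vec.sum()


def _draw_sequence(rng: np.random.Generator, n: int, letters: str, freqs: np.ndarray) -> str:
    idx = rng.choice(len(letters), size=n, p=freqs)
    return "".join(letters[i] for i in idx)


def generate_pair_table(spec: PairTableSpec) -> list[PairRecord]:
    """Generate homolog pairs with known identity, indel and coverage structure.

    Each thermophilic member starts as a substituted copy of its mesophilic
    partner (substitution count set by the drawn target identity), may
    receive one contiguous indel of length 1–3 (probability ``indel_rate``),
    and terminal overhang residues are appended to steer alignment coverage
    into ``coverage_range``.  Stored coverages are computed from the exact
    edits applied, not re-estimated.
    """
    rng = np.random.default_rng(spec.seed)
    letters = spec.alphabet
    freqs = _frequency_vector(spec)
    pairs: list[PairRecord] = []
    for k in range(spec.n_pairs):
        L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        meso_core = _draw_sequence(rng, L, letters, freqs)

        identity = float(rng.uniform(*spec.identity_range))
        n_sub = int(round((1.0 - identity) * L))
        sub_pos = rng.choice(L, size=min(n_sub, L), replace=False)
        thermo = list(meso_core)
        for p in sub_pos:
            current = thermo[p]
            choices = [a for a in letters if a != current] or [current]
            thermo[p] = choices[int(rng.integers(len(choices)))]

        aligned_m, aligned_t = L, L
        if len(letters) > 1 and rng.random() < spec.indel_rate and L > 6:
            k_ev = int(rng.integers(1, 4))
            at = int(rng.integers(1, L - k_ev))
            if rng.random() < 0.5:  # deletion from the thermophile
                del thermo[at : at + k_ev]
                aligned_m = L - k_ev
                aligned_t = L - k_ev
            else:  # insertion into the thermophile
                ins = _draw_sequence(rng, k_ev, letters, freqs)
                thermo[at:at] = list(ins)
                aligned_t = L  # inserted residues are unaligned
        thermo_core = "".join(thermo)

        # terminal overhangs lower coverage toward the drawn targets
        meso_seq, thermo_seq = meso_core, thermo_core
        cov_m_target = float(rng.uniform(*spec.coverage_range))
        cov_t_target = float(rng.uniform(*spec.coverage_range))
        ov_m = max(0, int(round(aligned_m / max(cov_m_target, 1e-9))) - len(meso_seq))
        ov_t = max(0, int(round(aligned_t / max(cov_t_target, 1e-9))) - len(thermo_seq))
        if ov_m:
            meso_seq += _draw_sequence(rng, ov_m, letters, freqs)
        if ov_t:
            thermo_seq += _draw_sequence(rng, ov_t, letters, freqs)

        pairs.append(
            PairRecord(
                pair_id=f"p{k:05d}",
                meso_id=f"m{k:05d}",
                thermo_id=f"t{k:05d}",
                meso_seq=meso_seq,
                thermo_seq=thermo_seq,
                meso_ogt=float(rng.uniform(*spec.ogt_meso_range)),
                thermo_ogt=float(rng.uniform(*spec.ogt_thermo_range)),
                cov_meso=aligned_m / len(meso_seq),
                cov_thermo=aligned_t / len(thermo_seq),
            )
        )
    return pairs


@dataclass(frozen=True)
class TranslationRule:
    """Deterministic meso→thermo transformation for learnability fixtures.

    ``substitution_map`` sends selected residues to replacements at every
    occurrence; ``insertion_motif`` (optional) is appended at the C-terminus
    (``insertion_position="end"``), prepended (``"start"``), or spliced in at
    a fixed 0-based position.
    """

    substitution_map: Mapping[str, str] = field(default_factory=dict)
    insertion_motif: str | None = None
    insertion_position: int | str = "end"
    name: str = "rule"

    def __post_init__(self) -> None:
        for k, v in self.substitution_map.items():
            if k not in AA_INDEX or v not in AA_INDEX:
                raise ValueError(
                    f"substitution_map entry {k!r}→{v!r} uses non-canonical residues"
                )
        if self.insertion_motif is not None:
            for ch in self.insertion_motif:
                if ch not in AA_INDEX:
                    raise ValueError(f"insertion motif residue {ch!r} is non-canonical")
            if isinstance(self.insertion_position, str) and self.insertion_position not in (
                "start",
                "end",
            ):
                raise ValueError("insertion_position must be 'start', 'end', or an int")

    def apply(self, seq: str) -> str:
        out = "".join(self.substitution_map.get(ch, ch) for ch in seq)
        if self.insertion_motif:
            if self.insertion_position == "start":
                out = self.insertion_motif + out
            elif self.insertion_position == "end":
                out = out + self.insertion_motif
            else:
                at = int(self.insertion_position)
                out = out[:at] + self.insertion_motif + out[at:]
        return out


def generate_rule_pairs(
    n: int,
    seed: int,
    rule: TranslationRule,
    length_range: tuple[int, int] = (30, 60),
    ogt_meso_range: tuple[float, float] = (285.0, 310.0),
    ogt_thermo_range: tuple[float, float] = (335.0, 360.0),
) -> list[PairRecord]:
    """Pairs whose thermophilic member is exactly the rule applied to the mesophile."""
    if n < 0:
        raise ValueError("n must be non-negative")
    _check_range("length_range", length_range, lo=1)
    rng = np.random.default_rng(seed)
    freqs = np.full(len(AA20), 1.0 / len(AA20))
    pairs = []
    for k in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        meso = _draw_sequence(rng, L, AA20, freqs)
        thermo = rule.apply(meso)
        aligned = min(len(meso), len(thermo))
        pairs.append(
            PairRecord(
                pair_id=f"r{k:05d}",
                meso_id=f"rm{k:05d}",
                thermo_id=f"rt{k:05d}",
                meso_seq=meso,
                thermo_seq=thermo,
                meso_ogt=float(rng.uniform(*ogt_meso_range)),
                thermo_ogt=float(rng.uniform(*ogt_thermo_range)),
                cov_meso=aligned / len(meso),
                cov_thermo=aligned / len(thermo),
            )
        )
    return pairs


def generate_toy_structure(
    sequence: str,
    cys_pair_distance: float | None = None,
    seed: int = 0,
) -> StructureModel:
    """Cα-only toy structure with an optional constrained cysteine pair.

    Residues lie on straight backbone segments with the canonical 3.8 Å
    consecutive Cα spacing.  When ``cys_pair_distance`` is given, the chain
    is built as two parallel offset segments so the first two cysteines sit
    exactly at the requested distance while every other inter-Cα distance
    stays ≥ 3.5 Å.  Non-designated residues carry a
    tiny seeded z-jitter (≤ 0.05 Å) so no fixture is accidentally degenerate.
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("sequence must be non-empty")
    rng = np.random.default_rng(seed)
    coords = np.zeros((n, 3))
    coords[:, 0] = CA_SPACING * np.arange(n)

    designated: tuple[int, int] | None = None
    if cys_pair_distance is not None:
        d = float(cys_pair_distance)
        cys = [i for i, ch in enumerate(sequence.upper()) if ch == "C"]
        if len(cys) < 2:
            raise ValueError(
                "cys_pair_distance given but sequence has fewer than 2 cysteines"
            )
        if d < CA_SPACING:
            raise ValueError(
                f"cys_pair_distance must be ≥ {CA_SPACING} Å for a valid chain geometry"
            )
        c1, c2 = cys[0], cys[1]
        designated = (c1, c2)
        # offset along a 3-4-5 direction keeps the parallel segments separated
        # by ≥ 3.5 Å while the designated pair sits at the requested distance
        dy = 0.8 * d if 0.8 * d >= MIN_NONBOND_DISTANCE else MIN_NONBOND_DISTANCE
        dx = float(np.sqrt(max(d * d - dy * dy, 0.0)))
        # nudge dx up by ulps so the measured distance never rounds below d:
        # boundary fixtures must not drift under a strict < threshold
        for _ in range(64):
            start = coords[c1] + np.array([dx, dy, 0.0])
            if float(np.linalg.norm(start - coords[c1])) >= d:
                break
            dx = float(np.nextafter(dx, np.inf))
        start = coords[c1] + np.array([dx, dy, 0.0])
        for i in range(c2, n):
            coords[i] = start + np.array([CA_SPACING * (i - c2), 0.0, 0.0])

    jitter = rng.uniform(-0.05, 0.05, size=n)
    if designated is not None:
        jitter[list(designated)] = 0.0
    coords[:, 2] += jitter
    return StructureModel(coords=coords)


def generate_family_sequences(
    n_families: int,
    members_per_family: int,
    length: int = 50,
    seed: int = 0,
    mutation_rate: float = 0.08,
) -> list[tuple[str, str]]:
    """Identity-structured sequence set for clustering/split fixtures.

    Each family descends from an independent random founder; members carry
    point substitutions at ``mutation_rate``, so intra-family identities stay
    high while inter-family identities sit near chance.  Returns
    (id, sequence) pairs with ids ``f{family}_s{member}``.
    """
    if n_families < 1 or members_per_family < 1:
        raise ValueError("need at least one family and one member")
    rng = np.random.default_rng(seed)
    freqs = np.full(len(AA20), 1.0 / len(AA20))
    out = []
    for f in range(n_families):
        founder = _draw_sequence(rng, length, AA20, freqs)
        for m in range(members_per_family):
            seq = list(founder)
            n_mut = rng.binomial(length, mutation_rate)
            for p in rng.choice(length, size=n_mut, replace=False):
                choices = [a for a in AA20 if a != seq[p]]
                seq[p] = choices[int(rng.integers(len(choices)))]
            out.append((f"f{f}_s{m}", "".join(seq)))
    return out
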