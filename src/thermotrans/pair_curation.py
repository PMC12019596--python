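"""Curation of mesophile–thermophile homolog pair tables.

A homolog pair couples a protein from a mesophilic organism (optimal growth
temperature, OGT, below ~313 K) with a homolog from a thermophile
(OGT ≥ ~333 K).  Curation keeps only strongly supported pairs, clusters the
mesophilic sequences by identity so that no near-duplicates straddle data
folds, and splits clusters 80/10/10 into train/validation/test sets.

Filter semantics (defaults, each boundary read strictly as stated):

* OGT difference strictly greater than 20 K,
* thermophile OGT at least 333 K,
* mesophile OGT strictly below 313 K,
* alignment coverage of both members strictly above 0.95,
* relative length difference at most 10% (of the mesophilic length).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alphabet import validate_sequence
from .evaluation_metrics import align_pair

__all__ = [
    "PairRecord",
    "CurationConfig",
    "ClusterAssignment",
    "SplitAssignment",
    "FILTER_ORDER",
    "clustering_identity",
    "filter_pairs",
    "cluster_sequences",
    "split_clusters",
    "subsample_test",
]

SPLITS = ("train", "valid", "test")

#: first-failing-filter attribution order for rejection reports
FILTER_ORDER = ("delta_ogt", "thermo_floor", "meso_ceiling", "coverage", "length")


@dataclass(frozen=True)
class PairRecord:
    """One meso–thermo homolog pair with OGT labels and alignment statistics."""

    pair_id: str
    meso_seq: str
    thermo_seq: str
    meso_ogt: float
    thermo_ogt: float
    cov_meso: float
    cov_thermo: float
    meso_id: str = ""
    thermo_id: str = ""

    def __post_init__(self) -> None:
        for name in ("meso_seq", "thermo_seq"):
            seq = getattr(self, name)
            if not seq:
                raise ValueError(f"pair {self.pair_id}: {name} is empty")
            validate_sequence(seq, allow_x=True, name=f"pair {self.pair_id} {name}")
        if self.meso_ogt <= 0 or self.thermo_ogt <= 0:
            raise ValueError(f"pair {self.pair_id}: OGTs must be positive Kelvin")
        for name in ("cov_meso", "cov_thermo"):
            cov = getattr(self, name)
            if not (0.0 <= cov <= 1.0):
                raise ValueError(f"pair {self.pair_id}: {name}={cov} outside [0,1]")


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds and split parameters for pair curation."""

    min_delta_ogt: float = 20.0     # K, strict >
    min_thermo_ogt: float = 333.0   # K, inclusive floor
    max_meso_ogt: float = 313.0     # K, strict <
    min_coverage: float = 0.95      # fraction, strict >
    max_len_diff: float = 0.10      # fraction of mesophile length, inclusive
    cluster_identity: float = 0.50
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        for name in (
            "min_delta_ogt", "min_thermo_ogt", "max_meso_ogt",
            "min_coverage", "max_len_diff", "cluster_identity",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class ClusterAssignment:
    """Mapping sequence-id → cluster-id plus the representative of each cluster."""

    membership: dict[str, str]
    representatives: dict[str, str]  # cluster-id -> representative sequence id

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, cid in self.membership.items():
            out.setdefault(cid, []).append(sid)
        return out


@dataclass
class SplitAssignment:
    """Mapping cluster-id → split name; every cluster appears exactly once."""

    assignment: dict[str, str]

    def clusters_in(self, split: str) -> list[str]:
        return [cid for cid, s in self.assignment.items() if s == split]


def clustering_identity(a: str, b: str) -> float:
    """Global-alignment identity normalized by the shorter sequence length.

    Exact matches in the optimal (free-end-gap) alignment divided by
    min(len(a), len(b)).  Unlike the alignment-span identity used for
    translation metrics, this cannot be inflated by a short chance
    match island between otherwise unrelated sequences, so it is the
    similarity notion used for clustering and split-leakage audits
    (clustering tools apply a coverage requirement for the same reason).
    """
    aln = align_pair(a, b)
    matches = sum(
        1
        for x, y in zip(aln.aligned_a, aln.aligned_b)
        if x == y and x != "-"
    )
    return matches / min(len(a), len(b))


def _first_failing_filter(rec: PairRecord, cfg: CurationConfig) -> str | None:
    if not (rec.thermo_ogt - rec.meso_ogt > cfg.min_delta_ogt):
        return "delta_ogt"
    if not (rec.thermo_ogt >= cfg.min_thermo_ogt):
        return "thermo_floor"
    if not (rec.meso_ogt < cfg.max_meso_ogt):
        return "meso_ceiling"
    if not (min(rec.cov_meso, rec.cov_thermo) > cfg.min_coverage):
        return "coverage"
    if not (
        abs(len(rec.thermo_seq) - len(rec.meso_seq)) / len(rec.meso_seq)
        <= cfg.max_len_diff
    ):
        return "length"
    return None


def filter_pairs(
    pairs: list[PairRecord], cfg: CurationConfig | None = None
) -> tuple[list[PairRecord], dict[str, int]]:
    """Apply the OGT/coverage/length filters, returning kept pairs and a report.

    The report attributes each rejected pair to the first failing filter in
    :data:`FILTER_ORDER`, so per-filter counts plus the kept count always sum
    to the input count.
    """
    cfg = cfg or CurationConfig()
    report = {name: 0 for name in FILTER_ORDER}
    kept: list[PairRecord] = []
    for rec in pairs:
        fail = _first_failing_filter(rec, cfg)
        if fail is None:
            kept.append(rec)
        else:
            report[fail] += 1
    return kept, report


def cluster_sequences(
    seqs: list[tuple[str, str]], identity_threshold: float = 0.50
) -> ClusterAssignment:
    """Greedy incremental identity clustering.

    Sequences are visited in order of descending length (ties broken by id);
    each joins the first existing cluster whose *representative* aligns at
    identity ≥ ``identity_threshold``, otherwise it founds a new cluster.
    Deterministic; an order-of-magnitude stand-in for MMSeqs2-style
    clustering at desk scale.
    """
    ids = [sid for sid, _ in seqs]
    if len(set(ids)) != len(ids):
        dupes = sorted({sid for sid in ids if ids.count(sid) > 1})
        raise ValueError(f"duplicate sequence ids: {', '.join(dupes)}")

    ordered = sorted(seqs, key=lambda item: (-len(item[1]), item[0]))
    membership: dict[str, str] = {}
    reps: list[tuple[str, str]] = []  # (representative id, sequence)
    for sid, seq in ordered:
        placed = False
        for rep_id, rep_seq in reps:
            if clustering_identity(seq, rep_seq) >= identity_threshold:
                membership[sid] = rep_id
                placed = True
                break
        if not placed:
            membership[sid] = sid
            reps.append((sid, seq))
    return ClusterAssignment(
        membership=membership,
        representatives={rep_id: rep_id for rep_id, _ in reps},
    )


def split_clusters(
    clusters: ClusterAssignment,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Assign whole clusters to train/valid/test by sequence-count quota.

    Clusters are shuffled by ``seed`` then fill the train split until its
    sequence quota is met, then valid, with the remainder going to test.
    Because assignment is per cluster, no two sequences sharing a cluster
    ever land in different splits.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    cluster_map = clusters.clusters()
    if len(cluster_map) < 3:
        raise ValueError(
            f"need at least 3 clusters to split, got {len(cluster_map)}"
        )
    total = sum(len(m) for m in cluster_map.values())
    rng = np.random.default_rng(seed)
    order = sorted(cluster_map)
    rng.shuffle(order)

    quotas = [fractions[0] * total, fractions[1] * total]
    assignment: dict[str, str] = {}
    counts = [0, 0, 0]
    idx = 0  # current split being filled
    for cid in order:
        size = len(cluster_map[cid])
        while idx < 2 and counts[idx] >= quotas[idx] - 1e-9:
            idx += 1
        assignment[cid] = SPLITS[idx]
        counts[idx] += size
    return SplitAssignment(assignment=assignment)


def subsample_test(
    split: SplitAssignment,
    clusters: ClusterAssignment,
    n_clusters: int,
    seed: int = 0,
) -> list[str]:
    """Pick one random sequence from each of ``n_clusters`` random test clusters.

    Reduces the weight of large clusters in evaluation.  If the test split
    holds fewer clusters than requested, all are used with a warning.
    """
    if n_clusters <= 0:
        raise ValueError("n_clusters must be positive")
    test_clusters = sorted(split.clusters_in("test"))
    cluster_map = clusters.clusters()
    rng = np.random.default_rng(seed)
    if n_clusters > len(test_clusters):
        warnings.warn(
            f"requested {n_clusters} clusters but test split has "
            f"{len(test_clusters)}; using all",
            stacklevel=2,
        )
        chosen = test_clusters
    else:
        chosen = list(rng.choice(test_clusters, size=n_clusters, replace=False))
    picked = []
    for cid in sorted(chosen):
        members = sorted(cluster_map[cid])
        picked.append(members[int(rng.integers(len(members)))])
    return picked
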