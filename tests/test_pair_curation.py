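"""Filtering, clustering and split hygiene for homolog-pair curation."""

import numpy as np
import pytest

from thermotrans import (
    CurationConfig,
    PairRecord,
    PairTableSpec,
    cluster_sequences,
    clustering_identity,
    filter_pairs,
    generate_family_sequences,
    generate_pair_table,
    split_clusters,
    subsample_test,
)
from thermotrans.pair_curation import FILTER_ORDER


def make_pair(
    pair_id="p0", meso_ogt=300.0, thermo_ogt=340.0,
    cov=0.99, meso_len=50, thermo_len=50,
):
    return PairRecord(
        pair_id=pair_id,
        meso_seq="A" * meso_len,
        thermo_seq="L" * thermo_len,
        meso_ogt=meso_ogt,
        thermo_ogt=thermo_ogt,
        cov_meso=cov,
        cov_thermo=cov,
    )


def brute_force_keep(rec, cfg):
    """Independent re-statement of the filter rules."""
    return (
        rec.thermo_ogt - rec.meso_ogt > cfg.min_delta_ogt
        and rec.thermo_ogt >= cfg.min_thermo_ogt
        and rec.meso_ogt < cfg.max_meso_ogt
        and min(rec.cov_meso, rec.cov_thermo) > cfg.min_coverage
        and abs(len(rec.thermo_seq) - len(rec.meso_seq)) / len(rec.meso_seq)
        <= cfg.max_len_diff
    )


class TestFilterPairs:
    def test_delta_ogt_boundary_is_strict(self):
        # exactly 20 K apart: rejected by the strict > rule
        rec = make_pair(meso_ogt=313.0 - 0.5, thermo_ogt=332.5)
        kept, report = filter_pairs([rec])
        assert kept == []
        # 20.0 exactly, with other filters passing
        rec2 = make_pair(meso_ogt=313.0 + -1.0, thermo_ogt=332.0)
        kept2, _ = filter_pairs([rec2])
        assert kept2 == []

    def test_ogt_floor_and_ceiling_boundaries(self):
        # thermo exactly at the 333 K floor is kept (>=); meso 312 < 313 kept
        rec = make_pair(meso_ogt=312.0, thermo_ogt=333.0)
        kept, _ = filter_pairs([rec])
        assert kept == [rec]
        # meso exactly at the 313 K ceiling is rejected (strict <)
        rec2 = make_pair(meso_ogt=313.0, thermo_ogt=340.0)
        kept2, report = filter_pairs([rec2])
        assert kept2 == [] and report["meso_ceiling"] == 1

    def test_coverage_boundary_is_strict(self):
        rec = make_pair(cov=0.95)
        kept, report = filter_pairs([rec])
        assert kept == [] and report["coverage"] == 1

    def test_length_boundary_is_inclusive(self):
        rec = make_pair(meso_len=100, thermo_len=110)  # exactly 10%
        kept, _ = filter_pairs([rec])
        assert kept == [rec]
        rec2 = make_pair(meso_len=100, thermo_len=111)
        kept2, report = filter_pairs([rec2])
        assert kept2 == [] and report["length"] == 1

    def test_first_failing_filter_attribution(self):
        # fails both delta and coverage; attributed to delta (first in order)
        rec = make_pair(meso_ogt=330.0, thermo_ogt=340.0, cov=0.5)
        _, report = filter_pairs([rec])
        assert report["delta_ogt"] == 1 and report["coverage"] == 0

    def test_report_counts_sum_to_input(self):
        pairs = generate_pair_table(PairTableSpec(n_pairs=100, seed=21,
                                                  ogt_meso_range=(280, 330),
                                                  ogt_thermo_range=(320, 363)))
        kept, report = filter_pairs(pairs)
        assert len(kept) + sum(report.values()) == len(pairs)
        assert set(report) == set(FILTER_ORDER)

    def test_matches_brute_force_on_synthetic_table(self):
        pairs = generate_pair_table(
            PairTableSpec(n_pairs=200, seed=8, ogt_meso_range=(280, 320),
                          ogt_thermo_range=(325, 363), coverage_range=(0.9, 1.0),
                          indel_rate=0.3)
        )
        cfg = CurationConfig()
        kept, _ = filter_pairs(pairs, cfg)
        expected = [p for p in pairs if brute_force_keep(p, cfg)]
        assert kept == expected

    def test_idempotence(self):
        pairs = generate_pair_table(PairTableSpec(n_pairs=100, seed=9))
        kept, _ = filter_pairs(pairs)
        kept2, report2 = filter_pairs(kept)
        assert kept2 == kept
        assert sum(report2.values()) == 0


class TestClusterSequences:
    def test_identical_sequences_one_cluster(self):
        ca = cluster_sequences([("a", "ACDEFGHIKL"), ("b", "ACDEFGHIKL")])
        assert len(set(ca.membership.values())) == 1

    def test_dissimilar_sequences_singletons(self):
        seqs = [(f"s{i}", s) for i, s in enumerate(
            ["AAAAAAAAAA", "WWWWWWWWWW", "HHHHHHHHHH"])]
        ca = cluster_sequences(seqs, 0.5)
        assert len(set(ca.membership.values())) == 3

    def test_family_fixture_recovers_families(self):
        seqs = generate_family_sequences(3, 10, length=50, seed=17)
        ca = cluster_sequences(seqs, 0.5)
        # brute-force pairwise identity matrix confirms the 3-family structure
        by_cluster = {}
        for sid, cid in ca.membership.items():
            by_cluster.setdefault(cid, []).append(sid)
        assert len(by_cluster) == 3
        for members in by_cluster.values():
            families = {m.split("_")[0] for m in members}
            assert len(families) == 1

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cluster_sequences([("a", "AAAA"), ("a", "LLLL")])

    def test_empty_input(self):
        ca = cluster_sequences([])
        assert ca.membership == {}

    def test_permutation_stability(self):
        seqs = generate_family_sequences(4, 5, length=40, seed=3)
        ca1 = cluster_sequences(seqs, 0.5)
        ca2 = cluster_sequences(list(reversed(seqs)), 0.5)
        assert ca1.membership == ca2.membership


class TestSplitClusters:
    def test_ten_singletons_split_8_1_1(self):
        seqs = generate_family_sequences(10, 1, length=30, seed=1)
        ca = cluster_sequences(seqs, 0.5)
        assert len(set(ca.membership.values())) == 10
        split = split_clusters(ca, (0.8, 0.1, 0.1), seed=42)
        sizes = {s: len(split.clusters_in(s)) for s in ("train", "valid", "test")}
        assert sizes == {"train": 8, "valid": 1, "test": 1}

    def test_determinism(self):
        seqs = generate_family_sequences(12, 2, length=30, seed=5)
        ca = cluster_sequences(seqs, 0.5)
        s1 = split_clusters(ca, seed=7)
        s2 = split_clusters(ca, seed=7)
        assert s1.assignment == s2.assignment

    def test_cluster_integrity(self):
        seqs = generate_family_sequences(10, 4, length=40, seed=6)
        ca = cluster_sequences(seqs, 0.5)
        split = split_clusters(ca, seed=0)
        for sid, cid in ca.membership.items():
            assert split.assignment[cid] in ("train", "valid", "test")
        # all members of a cluster share a split by construction of the mapping
        assert set(split.assignment) == set(ca.membership.values())

    def test_too_few_clusters_rejected(self):
        ca = cluster_sequences([("a", "AAAAAAA"), ("b", "WWWWWWW")], 0.5)
        with pytest.raises(ValueError, match="at least 3"):
            split_clusters(ca)

    def test_no_cross_split_leakage(self):
        """Exhaustive audit: no cross-split pair above the identity threshold."""
        seqs = generate_family_sequences(12, 4, length=40, seed=23)
        seq_map = dict(seqs)
        ca = cluster_sequences(seqs, 0.5)
        split = split_clusters(ca, seed=3)
        assign = {sid: split.assignment[cid] for sid, cid in ca.membership.items()}
        ids = sorted(seq_map)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if assign[a] != assign[b]:
                    ident = clustering_identity(seq_map[a], seq_map[b])
                    assert ident <= 0.5, (a, b, ident)


class TestSubsampleTest:
    @pytest.fixture()
    def split_fixture(self):
        seqs = generate_family_sequences(20, 3, length=30, seed=31)
        ca = cluster_sequences(seqs, 0.5)
        split = split_clusters(ca, (0.4, 0.2, 0.4), seed=1)
        return ca, split

    def test_one_id_per_cluster(self, split_fixture):
        ca, split = split_fixture
        ids = subsample_test(split, ca, n_clusters=5, seed=2)
        assert len(ids) == 5
        clusters = {ca.membership[i] for i in ids}
        assert len(clusters) == 5
        test_clusters = set(split.clusters_in("test"))
        assert clusters <= test_clusters

    def test_determinism(self, split_fixture):
        ca, split = split_fixture
        assert subsample_test(split, ca, 4, seed=5) == subsample_test(split, ca, 4, seed=5)

    def test_overflow_takes_all_with_warning(self, split_fixture):
        ca, split = split_fixture
        n_test = len(split.clusters_in("test"))
        with pytest.warns(UserWarning):
            ids = subsample_test(split, ca, n_clusters=n_test + 50, seed=0)
        assert len(ids) == n_test

    def test_invalid_count_rejected(self, split_fixture):
        ca, split = split_fixture
        with pytest.raises(ValueError):
            subsample_test(split, ca, 0, seed=0)
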