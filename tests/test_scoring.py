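"""Likelihood mathematics: mean log probability, ΔL, cross entropy, MSA baseline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermotrans import (
    ProfileModel,
    UniformModel,
    categorical_cross_entropy,
    delta_log_likelihood,
    log_likelihood,
    msa_column_profiles,
    natural_cross_entropy,
    predict_stepwise,
)
from thermotrans.alphabet import AA20, N_TOKENS, TOKEN_INDEX

LN20 = math.log(20.0)


def brute_force_L(probs, target, positions):
    """Independent per-position ln-sum / |M| computation."""
    total = 0.0
    for i in positions:
        total += math.log(probs[i][TOKEN_INDEX[target[i]]])
    return total / len(positions)


def one_hot_matrix(target):
    rows = np.zeros((len(target), N_TOKENS))
    for i, ch in enumerate(target):
        rows[i, TOKEN_INDEX[ch]] = 1.0
    return rows


class TestLogLikelihood:
    def test_uniform_model_gives_ln_one_twentieth(self):
        probs = predict_stepwise(UniformModel(), "MKV", "ACDEF")
        assert log_likelihood(probs, "ACDEF").value == pytest.approx(-LN20, abs=1e-12)

    def test_one_hot_match_gives_zero(self):
        assert log_likelihood(one_hot_matrix("ACD"), "ACD").value == 0.0

    def test_position_subset_mean(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet(np.ones(N_TOKENS), size=3)
        target = "WAD"
        score = log_likelihood(probs, target, positions={0, 2})
        expected = brute_force_L(probs, target, [0, 2])
        assert score.value == pytest.approx(expected, abs=1e-12)
        assert score.positions == frozenset({0, 2})
        assert score.mode == "mutation-set"

    def test_zero_probability_yields_neg_inf_with_warning(self):
        probs = one_hot_matrix("AAA")
        with pytest.warns(UserWarning, match="zero probability"):
            score = log_likelihood(probs, "AAC")
        assert score.value == -np.inf

    def test_positions_outside_target_rejected(self):
        probs = one_hot_matrix("AAA")
        with pytest.raises(ValueError):
            log_likelihood(probs, "AAA", positions={5})

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        target=st.text(alphabet=AA20, min_size=1, max_size=4),
        seed=st.integers(0, 10_000),
    )
    def test_oracle_equivalence_short_sequences(self, target, seed):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(N_TOKENS), size=len(target))
        got = log_likelihood(probs, target).value
        expected = brute_force_L(probs, target, range(len(target)))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_target_probability(self):
        base = np.full((1, N_TOKENS), 1.0 / N_TOKENS)
        bumped = base.copy()
        bumped[0, TOKEN_INDEX["A"]] += 0.2
        bumped /= bumped.sum()
        assert (
            log_likelihood(bumped, "A").value > log_likelihood(base, "A").value
        )


class TestCrossEntropy:
    def test_equals_negated_full_likelihood(self):
        rng = np.random.default_rng(7)
        probs = rng.dirichlet(np.ones(N_TOKENS), size=6)
        target = "MKVACD"
        assert categorical_cross_entropy(probs, target) == pytest.approx(
            -log_likelihood(probs, target).value, abs=1e-12
        )

    def test_uniform_is_ln20_and_one_hot_is_zero(self):
        probs = predict_stepwise(UniformModel(), "M", "ACD")
        assert categorical_cross_entropy(probs, "ACD") == pytest.approx(LN20, abs=1e-12)
        assert categorical_cross_entropy(one_hot_matrix("ACD"), "ACD") == 0.0

    def test_matches_brute_force_indicator_sum(self):
        rng = np.random.default_rng(11)
        probs = rng.dirichlet(np.ones(N_TOKENS), size=3)
        target = "CWY"
        # CCE_i = Σ_j −1(j = y_i) ln P_i(j), averaged over i
        expected = np.mean(
            [
                sum(
                    -math.log(probs[i][j]) if j == TOKEN_INDEX[target[i]] else 0.0
                    for j in range(N_TOKENS)
                )
                for i in range(3)
            ]
        )
        assert categorical_cross_entropy(probs, target) == pytest.approx(
            expected, abs=1e-12
        )


class TestDeltaLogLikelihood:
    def test_identical_variant_scores_zero(self):
        d = delta_log_likelihood(UniformModel(), "MKV", "ACD", "ACD")
        assert d.value == 0.0
        assert d.positions == frozenset()

    def test_profile_substitution_analytic(self):
        model = ProfileModel({"I": 0.2, "V": 0.05, "A": 0.75})
        d = delta_log_likelihood(model, "AAAA", "AVAA", "AIAA")
        assert d.value == pytest.approx(math.log(4.0), abs=1e-12)
        assert d.mode == "mutation-set"
        assert d.positions == frozenset({1})

    def test_indel_variant_under_uniform_cancels(self):
        d = delta_log_likelihood(UniformModel(), "MKV", "ACDE", "ACDEF")
        assert d.mode == "full-sequence"
        assert d.value == pytest.approx(0.0, abs=1e-12)

    def test_full_sequence_antisymmetry(self):
        rng = np.random.default_rng(5)
        freqs = {aa: float(f) for aa, f in zip(AA20, rng.dirichlet(np.ones(20)))}
        model = ProfileModel(freqs)
        d_ab = delta_log_likelihood(model, "MKV", "ACDE", "ACD")
        d_ba = delta_log_likelihood(model, "MKV", "ACD", "ACDE")
        assert d_ab.value == pytest.approx(-d_ba.value, abs=1e-12)

    def test_wt_prefix_conditioning_mode(self):
        model = ProfileModel({"I": 0.2, "V": 0.05, "A": 0.75})
        d = delta_log_likelihood(
            model, "AAAA", "AVAA", "AIAA", prefix_mode="wt"
        )
        # profile is prefix-independent, so both conditioning modes agree
        assert d.value == pytest.approx(math.log(4.0), abs=1e-12)


class TestMSAProfiles:
    def test_identical_sequences_one_hot(self):
        msa = [("a", "ACD"), ("b", "ACD"), ("c", "ACD")]
        profiles = msa_column_profiles(msa, "a", pseudocount=0.0)
        assert len(profiles) == 3
        assert profiles.profiles[0][TOKEN_INDEX["A"]] == 1.0
        assert natural_cross_entropy(profiles, "ACD") == 0.0

    def test_column_counting(self):
        msa = [("a", "A"), ("b", "A"), ("c", "V")]
        profiles = msa_column_profiles(msa, "a", pseudocount=0.0)
        assert profiles.profiles[0][TOKEN_INDEX["A"]] == pytest.approx(2 / 3)
        assert profiles.profiles[0][TOKEN_INDEX["V"]] == pytest.approx(1 / 3)

    def test_all_gap_column_near_uniform_with_pseudocount(self):
        msa = [("ref", "AC"), ("b", "A-"), ("c", "A-")]
        profiles = msa_column_profiles(msa, "ref", pseudocount=1e-3)
        col = profiles.profiles[1]  # only the reference has a residue (C)
        assert col.sum() == pytest.approx(1.0, abs=1e-12)
        # C observed once, everything else pseudocount only
        assert col[TOKEN_INDEX["C"]] > col[TOKEN_INDEX["A"]]
        near_uniform = (1e-3) / (1.0 + 20 * 1e-3)
        assert col[TOKEN_INDEX["A"]] == pytest.approx(near_uniform, rel=1e-9)

    def test_gap_columns_of_reference_skipped(self):
        msa = [("ref", "A-C"), ("b", "AGC")]
        profiles = msa_column_profiles(msa, "ref", pseudocount=0.0)
        assert len(profiles) == 2

    def test_reference_absent_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            msa_column_profiles([("a", "ACD")], "zzz")

    def test_hand_computed_cross_entropy(self):
        msa = [("ref", "AV"), ("b", "AV"), ("c", "VV")]
        profiles = msa_column_profiles(msa, "ref", pseudocount=0.0)
        expected = np.mean([-math.log(2 / 3), -math.log(1.0)])
        assert natural_cross_entropy(profiles, "AV") == pytest.approx(
            expected, abs=1e-12
        )

    def test_uniform_profiles_give_ln20(self):
        msa = [("ref", "AAAA")]
        profiles = msa_column_profiles(msa, "ref", pseudocount=0.0)
        uniform = np.full_like(profiles.profiles, 1.0 / 20)
        from thermotrans.scoring import MSAColumnProfiles

        assert natural_cross_entropy(
            MSAColumnProfiles(uniform, "ref"), "WYWC"
        ) == pytest.approx(LN20, abs=1e-12)

    def test_length_mismatch_rejected(self):
        msa = [("ref", "ACD")]
        profiles = msa_column_profiles(msa, "ref")
        with pytest.raises(ValueError, match="length"):
            natural_cross_entropy(profiles, "AC")
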