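"""Discriminative measures against brute-force enumeration oracles,
hand-computed values and their documented bounds/symmetries."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy import stats as sps

from oracles import brute_entropy_family, brute_relieff, mutual_information
from rbmprune.measures import (LARGE_SCORE, MEASURES, ClassStats,
                               DiscreteJoint, UndefinedScoreError, anova_f,
                               conditional_entropy, discretize, entropy,
                               fisher_score, gain_ratio, information_gain,
                               one_r, pcc_measure, relieff, score_all,
                               symmetric_uncertainty)

DETERMINISTIC = tuple(m for m in MEASURES if m != "relieff")

@st.composite
def count_tables(draw):
    nx = draw(st.integers(2, 6))
    ny = draw(st.integers(2, 6))
    vals = draw(st.lists(st.integers(0, 12), min_size=nx * ny,
                         max_size=nx * ny))
    table = np.array(vals, float).reshape(nx, ny)
    assume(table.sum() > 0)
    return table


class TestDiscretize:
    @pytest.mark.parametrize("x,expected", [(0.0, 0), (1.0, 9), (0.55, 5),
                                            (-2.0, 0), (3.0, 9)])
    def test_bin_codes_over_unit_interval(self, x, expected):
        assert discretize(np.array([x]), 10, 0.0, 1.0)[0] == expected

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.array([0.5]), 1, 0.0, 1.0)
        with pytest.raises(ValueError):
            discretize(np.array([0.5]), 10, 1.0, 0.0)


class TestEntropy:
    @pytest.mark.parametrize("p,expected", [
        ((0.5, 0.5), 1.0),
        ((1.0, 0.0), 0.0),
        ((0.25, 0.75), 0.8112781244591328),
    ])
    def test_known_values_in_bits(self, p, expected):
        assert entropy(np.array(p)) == pytest.approx(expected, abs=1e-12)

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            entropy(np.array([1.2, -0.2]))

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            entropy(np.array([0.5, 0.4]))


class TestConditionalEntropyAndGain:
    def test_perfect_prediction_gives_zero(self):
        j = DiscreteJoint(np.diag([5.0, 3.0, 2.0]))
        assert conditional_entropy(j) == pytest.approx(0.0, abs=1e-12)

    def test_independence_gives_marginal_entropy(self):
        j = DiscreteJoint(np.outer([4.0, 6.0], [3.0, 7.0]))
        assert conditional_entropy(j) == pytest.approx(entropy(j.px), abs=1e-12)

    def test_matches_brute_force_cell(self):
        j = DiscreteJoint(np.array([[2.0, 1.0], [1.0, 2.0]]))
        assert conditional_entropy(j) == pytest.approx(
            brute_entropy_family(j.counts)["hx_given_y"], abs=1e-12)

    def test_identical_uniform_binary_gives_one_bit(self):
        assert information_gain(DiscreteJoint(np.diag([5.0, 5.0]))) == \
            pytest.approx(1.0, abs=1e-12)

    def test_gain_matches_mutual_information_identity(self):
        counts = np.array([[4.0, 0.0], [1.0, 3.0]])
        assert information_gain(DiscreteJoint(counts)) == pytest.approx(
            mutual_information(counts), abs=1e-12)


class TestNormalizedMeasures:
    def test_gain_ratio_of_feature_with_itself_is_one(self):
        assert gain_ratio(DiscreteJoint(np.diag([25.0] * 4))) == \
            pytest.approx(1.0, abs=1e-12)

    def test_gain_ratio_of_independent_table_is_zero(self):
        assert gain_ratio(DiscreteJoint(np.full((2, 2), 25.0))) == \
            pytest.approx(0.0, abs=1e-12)

    def test_gain_ratio_undefined_for_constant_feature(self):
        with pytest.raises(UndefinedScoreError):
            gain_ratio(DiscreteJoint(np.array([[3.0, 4.0], [0.0, 0.0]])))

    def test_gain_ratio_matches_oracle(self):
        counts = np.array([[3.0, 1.0], [1.0, 3.0]])
        assert gain_ratio(DiscreteJoint(counts)) == pytest.approx(
            brute_entropy_family(counts)["gr"], abs=1e-12)

    def test_su_endpoints(self):
        assert symmetric_uncertainty(DiscreteJoint(np.diag([5.0, 5.0]))) == 1.0
        assert symmetric_uncertainty(
            DiscreteJoint(np.full((2, 2), 25.0))) == pytest.approx(0.0, abs=1e-12)

    def test_su_invariant_under_transpose(self, rng):
        counts = rng.integers(0, 9, (3, 2)).astype(float) + 1
        assert symmetric_uncertainty(DiscreteJoint(counts)) == \
            symmetric_uncertainty(DiscreteJoint(counts.T))


class TestEntropyFamilyProperties:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(count_tables())
    def test_oracle_equivalence(self, counts):
        """Entropy family agrees with full-table enumeration to 1e-12."""
        ref = brute_entropy_family(counts)
        j = DiscreteJoint(counts)
        assert conditional_entropy(j) == pytest.approx(ref["hx_given_y"],
                                                       abs=1e-12)
        assert information_gain(j) == pytest.approx(max(ref["ig"], 0.0),
                                                    abs=1e-12)
        if ref["hx"] > 0:
            assert gain_ratio(j) == pytest.approx(
                min(max(ref["gr"], 0.0), 1.0), abs=1e-12)
        if ref["hx"] + ref["hy"] > 0:
            assert symmetric_uncertainty(j) == pytest.approx(
                min(max(ref["su"], 0.0), 1.0), abs=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(count_tables())
    def test_information_gain_symmetry(self, counts):
        """H(X) - H(X|Y) == H(Y) - H(Y|X)."""
        ref = brute_entropy_family(counts)
        assert information_gain(DiscreteJoint(counts)) == pytest.approx(
            max(ref["hy"] - ref["hy_given_x"], 0.0), abs=1e-12)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(count_tables())
    def test_bounds(self, counts):
        j = DiscreteJoint(counts)
        assert information_gain(j) >= 0
        if entropy(j.px) > 0:
            assert 0 <= gain_ratio(j) <= 1
        if entropy(j.px) + entropy(j.py) > 0:
            assert 0 <= symmetric_uncertainty(j) <= 1


class TestFisher:
    def test_equal_class_means_score_zero(self):
        x = np.array([1.0, 1.0, 2.0, 2.0])
        y = np.array([0, 1, 0, 1])
        assert fisher_score(ClassStats.from_column(x, y)) == 0.0

    def test_hand_evaluated_ratio(self):
        stats = ClassStats(class_counts=np.array([10.0, 10.0]),
                           class_means=np.array([0.0, 1.0]),
                           class_vars=np.array([0.25, 0.25]),
                           grand_mean=0.5)
        assert fisher_score(stats) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        x = rng.normal(size=60)
        y = rng.integers(0, 2, 60)
        a = fisher_score(ClassStats.from_column(x, y))
        b = fisher_score(ClassStats.from_column(10 * x, y))
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_within_variance_undefined(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([0, 0, 1, 1])
        with pytest.raises(UndefinedScoreError):
            fisher_score(ClassStats.from_column(x, y))


class TestPcc:
    def test_indicator_column_scores_one(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        assert pcc_measure(y.astype(float), y) == pytest.approx(1.0)

    def test_sign_symmetric(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        assert pcc_measure(-y.astype(float), y) == pytest.approx(1.0)

    def test_hand_evaluated_correlation(self):
        assert pcc_measure(np.array([1.0, 2.0, 3.0, 4.0]),
                           np.array([0, 0, 1, 1])) == \
            pytest.approx(0.8944271909999159, abs=1e-12)

    def test_constant_column_undefined(self):
        with pytest.raises(UndefinedScoreError):
            pcc_measure(np.ones(4), np.array([0, 0, 1, 1]))


class TestAnova:
    def test_equal_group_means_give_zero(self):
        x = np.array([1.0, 2.0, 1.0, 2.0])
        assert anova_f(x, np.array([0, 0, 1, 1])) == 0.0

    def test_zero_within_variance_undefined(self):
        with pytest.raises(UndefinedScoreError):
            anova_f(np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0]),
                    np.array([0, 0, 0, 1, 1, 1]))

    def test_hand_evaluated_f(self):
        assert anova_f(np.array([1.0, 2.0, 3.0, 4.0]),
                       np.array([0, 0, 1, 1])) == pytest.approx(8.0)

    def test_matches_scipy_f_oneway(self, rng):
        x = rng.normal(size=90)
        y = rng.integers(0, 3, 90)
        expected = sps.f_oneway(*(x[y == c] for c in range(3))).statistic
        assert anova_f(x, y) == pytest.approx(expected, rel=1e-10)


class TestRelieff:
    def test_constant_feature_weighs_zero(self, rng):
        X = np.column_stack([np.ones(20), rng.random(20)])
        y = rng.integers(0, 2, 20)
        sv = relieff(X, y, k=3, seed=0)
        assert sv.scores[0] == 0.0

    def test_indicator_feature_is_maximal_and_positive(self, rng):
        y = np.repeat([0, 1], 15)
        X = np.column_stack([y.astype(float), rng.random(30), rng.random(30)])
        sv = relieff(X, y, k=5, seed=1)
        assert sv.scores[0] > 0
        assert sv.scores[0] == sv.scores.max()

    def test_matches_hand_simulated_pass(self):
        """Six-instance toy problem, k=1, all instances sampled."""
        X = np.array([[0.0, 0.1], [0.1, 0.9], [0.2, 0.5],
                      [1.0, 0.4], [0.9, 0.8], [0.8, 0.1]])
        y = np.array([0, 0, 0, 1, 1, 1])
        sv = relieff(X, y, k=1, seed=0)
        np.testing.assert_allclose(sv.scores, brute_relieff(X, y, k=1),
                                   atol=1e-12)

    def test_matches_hand_simulation_on_random_problems(self, rng):
        for _ in range(3):
            X = rng.random((25, 4))
            y = rng.integers(0, 3, 25)
            sv = relieff(X, y, k=3, seed=0)
            np.testing.assert_allclose(sv.scores, brute_relieff(X, y, k=3),
                                       atol=1e-12)

    def test_weights_bounded(self, rng):
        X = rng.random((50, 6))
        y = rng.integers(0, 4, 50)
        sv = relieff(X, y, k=5, seed=2)
        assert (np.abs(sv.scores) <= 1.0).all()

    def test_singleton_class_contributes_misses_only(self):
        X = np.array([[0.0], [0.1], [0.9]])
        y = np.array([0, 0, 1])
        with pytest.warns(UserWarning, match="single member"):
            relieff(X, y, k=1, seed=0)


class TestOneR:
    def test_perfect_predictor_has_zero_error(self):
        y = np.array([0, 1, 0, 1, 1])
        rule, err = one_r(y, y)
        assert err == 0.0
        assert rule == {0: 0, 1: 1}

    def test_constant_column_on_balanced_labels(self):
        _, err = one_r(np.zeros(10, int), np.repeat([0, 1], 5))
        assert err == 0.5

    def test_enumerated_frequency_table(self):
        rule, err = one_r(np.array([0, 0, 1, 1]), np.array([0, 1, 1, 1]))
        assert err == 0.25
        assert rule == {0: 0, 1: 1}          # bin-0 tie broken to class 0

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError):
            one_r(np.array([], int), np.array([], int))


class TestScoreAll:
    def test_unknown_measure_rejected(self, rng):
        with pytest.raises(ValueError):
            score_all(rng.random((10, 2)), rng.integers(0, 2, 10), "chi2")

    def test_single_column_matrix(self, rng):
        y = rng.integers(0, 2, 40)
        sv = score_all(rng.random((40, 1)), y, "ig")
        assert len(sv) == 1

    @pytest.mark.parametrize("measure", DETERMINISTIC)
    def test_identical_columns_score_identically(self, measure, rng):
        col = rng.random(60)
        y = rng.integers(0, 2, 60)
        sv = score_all(np.column_stack([col, rng.random(60), col]), y, measure)
        assert sv.scores[0] == sv.scores[2]

    @pytest.mark.parametrize("measure", MEASURES)
    def test_permutation_equivariance(self, measure, rng):
        M = rng.random((50, 5))
        y = rng.integers(0, 2, 50)
        perm = rng.permutation(5)
        sv = score_all(M, y, measure, seed=4)
        sv_perm = score_all(M[:, perm], y, measure, seed=4)
        np.testing.assert_allclose(sv_perm.scores, sv.scores[perm], atol=1e-12)

    def test_constant_column_falls_back_to_null_with_warning(self, rng):
        M = np.column_stack([np.full(20, 0.5), rng.random(20)])
        y = rng.integers(0, 2, 20)
        for measure in ("fisher", "pcc", "gain_ratio"):
            with pytest.warns(UserWarning, match="undefined"):
                sv = score_all(M, y, measure)
            assert sv.scores[0] == 0.0
        # IG and SU are already zero (not undefined) on a zero-entropy column
        for measure in ("ig", "su"):
            assert score_all(M, y, measure).scores[0] == 0.0

    def test_perfect_separation_maps_to_large_sentinel(self):
        y = np.repeat([0, 1], 5)
        M = np.column_stack([y.astype(float), np.linspace(0, 1, 10)])
        for measure in ("fisher", "anova"):
            with pytest.warns(UserWarning, match="undefined"):
                sv = score_all(M, y, measure)
            assert sv.scores[0] == LARGE_SCORE

    @pytest.mark.parametrize("measure",
                             ("ig", "gain_ratio", "su", "fisher", "relieff"))
    def test_label_permutation_drives_scores_to_null(self, measure):
        """Random relabelling destroys the signal: mean noise-column score
        across seeds approaches the measure's null value 0."""
        means = []
        for seed in range(10):
            g = np.random.default_rng(seed)
            M = g.random((80, 4))
            y = g.permutation(np.repeat([0, 1], 40))
            sv = score_all(M, y, measure, seed=seed)
            means.append(sv.scores.mean())
        assert abs(np.mean(means)) < 0.12
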