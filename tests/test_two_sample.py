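import math

import numpy as np
import pytest
from scipy import stats

from homovar.exceptions import DegenerateDataError, ValidationError
from homovar.nulls import ansari_exact_null
from homovar.two_sample import (
    ansari_bradley_test,
    f_test,
    jackknife_test,
    moses_test,
    walsh_means,
    welch_df,
    welch_t_test,
)


class TestFTest:
    def test_hand_value(self):
        res = f_test([0.0, 2.0], [0.0, 4.0])
        assert res.statistic == pytest.approx(0.25)
        assert res.df == (1.0, 1.0)

    def test_equal_samples_give_unity_and_p_one(self, rng):
        x = rng.normal(size=20)
        res = f_test(x, x.copy())
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_sided_doubles_one_sided_for_equal_dfs(self, rng):
        x = rng.normal(0, 2, 15)
        y = rng.normal(0, 1, 15)
        if f_test(x, y).statistic < 1:
            x, y = y, x
        two = f_test(x, y).p_value
        one = f_test(x, y, alternative="greater").p_value
        assert two == pytest.approx(min(1.0, 2 * one))

    def test_rejection_matches_f22_critical_value(self, rng):
        # n=3 per group: two-sided alpha=.05 rejects iff F > 39.0 or F < 1/39
        for _ in range(50):
            x, y = rng.normal(0, 1, 3), rng.normal(0, 1, 3)
            res = f_test(x, y)
            should_reject = res.statistic > 39.0 or res.statistic < 1 / 39.0
            assert (res.p_value < 0.05) == should_reject

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            f_test([1.0, 1.0], [0.0, 2.0])


class TestWelch:
    def test_df_bounds_and_symmetric_case(self):
        assert welch_df(2.0, 2.0, 8, 8) == pytest.approx(14.0)
        assert welch_df(5.0, 1e-12, 10, 7) == pytest.approx(9.0, abs=1e-6)

    def test_df_formula_value(self):
        assert welch_df(25.0, 1.0, 15, 15) == pytest.approx(15.12, abs=0.01)

    def test_identical_samples_t_zero(self, rng):
        x = rng.normal(size=12)
        res = welch_t_test(x, x.copy())
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_equal_n_pooled_and_welch_statistics_match(self, rng):
        x, y = rng.normal(0, 1, 14), rng.normal(1, 3, 14)
        pooled = welch_t_test(x, y, assume_equal_variance=True)
        welch = welch_t_test(x, y)
        assert pooled.statistic == pytest.approx(welch.statistic)
        assert pooled.df != welch.df

    def test_against_scipy(self, two_normal_groups):
        x, y = two_normal_groups
        mine = welch_t_test(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue)


class TestWalshMeans:
    def test_count_and_small_example(self):
        assert walsh_means(np.arange(5.0)).size == 15
        np.testing.assert_allclose(np.sort(walsh_means([1.0, 3.0])), [1.0, 2.0, 3.0])

    def test_constant_sample(self):
        np.testing.assert_allclose(walsh_means([2.0] * 4), 2.0)


class TestAnsariBradley:
    def test_extreme_configuration_hits_support_minimum(self):
        # group 1 occupies the five outermost positions of the pooled order
        x = np.array([1.0, 2.0, 3.0, 102.0, 103.0])
        y = np.array([4.0, 5.0, 6.0, 7.0, 8.0])
        res = ansari_bradley_test(x, y, alternative="greater")
        assert res.statistic == 9.0
        assert res.p_value == pytest.approx(2 / 252)

    def test_exact_p_matches_scipy(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(4, 10))
            y = rng.normal(0, 2, rng.integers(4, 10))
            mine = ansari_bradley_test(x, y)
            ref = stats.ansari(x, y)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        # the reported p must equal the tail mass of the exact null
        x = rng.normal(0, 1, 5)
        y = rng.normal(0, 1, 7)
        res = ansari_bradley_test(x, y, alternative="greater")
        null = ansari_exact_null(5, 7)
        assert res.p_value == pytest.approx(null.cdf(res.statistic), abs=1e-12)

    def test_shift_invariance_with_alignment(self, rng):
        x = rng.normal(0, 1, 9)
        y = rng.normal(0, 2, 11)
        base = ansari_bradley_test(x, y, align_medians=True)
        shifted = ansari_bradley_test(x + 17.3, y - 4.2, align_medians=True)
        assert shifted.statistic == pytest.approx(base.statistic)

    def test_ties_fall_back_to_approximation(self):
        x = [1.0, 1.0, 2.0, 3.0]
        y = [1.0, 2.0, 2.0, 4.0]
        res = ansari_bradley_test(x, y)
        assert res.extras["ties"]
        assert "normal" in res.reference
        with pytest.raises(ValidationError):
            ansari_bradley_test(x, y, mode="exact")

    def test_identical_observations_degenerate(self):
        with pytest.raises(DegenerateDataError):
            ansari_bradley_test([1.0, 1.0], [1.0, 1.0])


class TestMoses:
    def test_subset_sum_of_squares_definition(self, rng):
        # a single subset of {1,2,3} has D = 2; forcing subset_size = n
        res = moses_test(
            np.tile([1.0, 2.0, 3.0], 2), np.tile([2.0, 4.0, 6.0], 2),
            subset_size=3, repartitions=5, seed=1,
        )
        assert res.extras["subsets"] == (2, 2)

    def test_leftovers_discarded(self, rng):
        x = rng.normal(size=11)
        y = rng.normal(size=11)
        res = moses_test(x, y, subset_size=3, repartitions=3, seed=0)
        assert res.extras["subsets"] == (3, 3)
        assert res.extras["discarded"] == (2, 2)

    def test_requires_enough_subsets(self, rng):
        with pytest.raises(ValidationError):
            moses_test(rng.normal(size=5), rng.normal(size=30), subset_size=3, seed=0)

    def test_seed_reproducibility(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = moses_test(x, y, seed=7)
        b = moses_test(x, y, seed=7)
        assert a.p_value == b.p_value

    def test_detects_scale_difference(self, rng):
        x = rng.normal(0, 1, 60)
        res = moses_test(x, 3.0 * rng.normal(0, 1, 60), alternative="less", seed=3)
        assert res.p_value < 0.01


class TestJackknife:
    def test_identical_samples(self, rng):
        x = rng.normal(size=15)
        res = jackknife_test(x, x.copy())
        assert res.statistic == pytest.approx(0.0)
        assert res.extras["gamma2"] == pytest.approx(1.0)

    def test_scaling_identity_gamma2_equals_c_squared(self, rng):
        x = rng.normal(size=21)
        for c in (0.5, 2.7, 10.0):
            res = jackknife_test(x, c * x)
            assert res.extras["gamma2"] == pytest.approx(c * c, rel=1e-12)

    def test_location_shift_leaves_statistic_unchanged(self, rng):
        x, y = rng.normal(0, 1, 13), rng.normal(0, 2, 17)
        a = jackknife_test(x, y)
        b = jackknife_test(x + 100.0, y)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-9)

    def test_mode_controls_reference(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0, 2, 10)
        assert jackknife_test(x, y, mode="exact_t").reference == "t(18)"
        assert jackknife_test(x, y, mode="normal").reference == "standard normal"

    def test_duplicate_pair_degenerate(self):
        # dropping one of three values where the other two are equal
        with pytest.raises(DegenerateDataError):
            jackknife_test([1.0, 1.0, 2.0], [1.0, 2.0, 3.0])

    def test_consistency_of_variance_ratio_estimate(self, rng):
        # median gamma2 over replicates approaches the true ratio
        ratio, reps, n = 4.0, 1000, 200
        estimates = np.empty(reps)
        for i in range(reps):
            x = rng.normal(0, 1, n)
            y = rng.normal(0, math.sqrt(ratio), n)
            estimates[i] = jackknife_test(x, y).extras["gamma2"]
        assert np.median(estimates) == pytest.approx(ratio, rel=0.05)


class TestScaleInvariance:
    """All scale tests are invariant to multiplying both groups by c > 0."""

    @pytest.mark.parametrize(
        "testfn",
        [
            lambda x, y: f_test(x, y),
            lambda x, y: ansari_bradley_test(x, y),
            lambda x, y: jackknife_test(x, y),
            lambda x, y: moses_test(x, y, seed=11),
        ],
    )
    def test_common_rescaling(self, rng, testfn):
        x, y = rng.normal(0, 1, 18), rng.normal(0, 2, 24)
        base = testfn(x, y)
        scaled = testfn(3.7 * x, 3.7 * y)
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-9)
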