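import math

import numpy as np
import pytest
from scipy import stats

from homovar.exceptions import DegenerateDataError, ValidationError
from homovar.multi_sample import (
    bartlett_test,
    brown_forsythe,
    cochran_c_test,
    fligner_killeen_test,
    hartley_test,
    levene_test,
    one_way_anova,
    welch_anova,
)
from homovar.samples import GroupedSample
from homovar.two_sample import welch_df, welch_t_test


def random_sample(rng, k=3, sizes=None, scales=None):
    sizes = sizes or [rng.integers(5, 15) for _ in range(k)]
    scales = scales or [1.0] * k
    return GroupedSample.from_arrays(
        [rng.normal(0, s, n) for s, n in zip(scales, sizes)]
    )


class TestLeveneFamily:
    @pytest.mark.parametrize("center", ["mean", "median"])
    def test_matches_scipy(self, rng, center):
        for _ in range(10):
            s = random_sample(rng, scales=[1.0, 2.0, 0.5])
            mine = levene_test(s, center=center)
            ref = stats.levene(*s.groups, center=center)
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_statistic_is_anova_f_on_absolute_deviations(self, rng):
        # the defining identity: W equals the one-way ANOVA F computed on Z
        for _ in range(100):
            s = random_sample(rng, k=int(rng.integers(2, 5)))
            mine = levene_test(s, center="mean")
            z = [np.abs(g - g.mean()) for g in s.groups]
            ref = stats.f_oneway(*z)
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-10)

    def test_identical_groups_give_zero_statistic(self):
        g = [1.0, 2.0, 5.0, 7.0]
        s = GroupedSample.from_arrays([g, list(g)])
        res = levene_test(s, center="mean")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_point_groups_are_degenerate(self):
        # |deviation from mean| is constant within any 2-point group
        s = GroupedSample.from_arrays([[0.0, 2.0], [0.0, 8.0]])
        with pytest.raises(DegenerateDataError):
            levene_test(s, center="mean")

    def test_brown_forsythe_is_median_levene(self, three_group_sample):
        a = brown_forsythe(three_group_sample)
        b = levene_test(three_group_sample, center="median")
        assert a == b

    def test_trimmed_center_uses_interior_mean(self, rng):
        # with trim 0.25, a group of 8 drops 2 from each tail
        g1 = np.array([100.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, -50.0])
        g2 = rng.normal(0, 1, 8)
        s = GroupedSample.from_arrays([g1, g2])
        res = levene_test(s, center="trimmed", trim_fraction=0.25)
        interior = np.sort(g1)[2:-2].mean()
        z1 = np.abs(g1 - interior)
        z2 = np.abs(g2 - stats.trim_mean(g2, 0.25))
        ref = stats.f_oneway(z1, z2)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)

    def test_trimming_everything_rejected(self):
        s = GroupedSample.from_arrays([[1.0, 2.0], [3.0, 4.0, 5.0]])
        with pytest.raises(ValidationError):
            levene_test(s, center="trimmed", trim_fraction=0.5)

    def test_rank_variant_uses_pooled_midranks(self, rng):
        s = random_sample(rng)
        mine = levene_test(s, center="rank")
        pooled = np.concatenate(s.groups)
        ranks = stats.rankdata(pooled)
        cuts = np.cumsum(s.sizes)[:-1]
        ref = stats.levene(*np.split(ranks, cuts), center="mean")
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)


class TestBartlett:
    def test_hand_value_and_scipy(self):
        # groups with sample variances exactly 1 and 2 (n=11 each):
        # numerator 20 ln 1.5 - 10 ln 2, correction 1 + (0.2 - 0.05)/3
        x = np.arange(11.0) / math.sqrt(11.0)
        y = np.arange(11.0) * math.sqrt(2.0 / 11.0)
        s = GroupedSample.from_arrays([x, y])
        expected = (20 * math.log(1.5) - 10 * math.log(2.0)) / 1.05
        res = bartlett_test(s)
        assert res.statistic == pytest.approx(expected, rel=1e-10)
        ref = stats.bartlett(x, y)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_equal_variances_give_zero(self):
        s = GroupedSample.from_arrays([[0.0, 1.0, 2.0], [5.0, 6.0, 7.0]])
        assert bartlett_test(s).statistic == pytest.approx(0.0)
        assert bartlett_test(s).p_value == pytest.approx(1.0)

    def test_scale_invariance(self, three_group_sample):
        base = bartlett_test(three_group_sample)
        scaled = bartlett_test(
            GroupedSample.from_arrays([7.0 * g for g in three_group_sample.groups])
        )
        assert scaled.statistic == pytest.approx(base.statistic, rel=1e-9)

    def test_zero_variance_degenerate(self):
        s = GroupedSample.from_arrays([[1.0, 1.0], [0.0, 2.0]])
        with pytest.raises(DegenerateDataError):
            bartlett_test(s)


class TestHartley:
    def test_equal_variances_never_reject(self):
        g = [0.0, 1.0, 2.0]
        s = GroupedSample.from_arrays([g, [x + 5 for x in g]])
        res = hartley_test(s)
        assert res.statistic == pytest.approx(1.0)
        assert res.rejected is False
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("k,crit", [(2, 39.0), (3, 87.5)])
    def test_critical_values_k_groups_n3(self, rng, k, crit):
        s = GroupedSample.from_arrays([rng.normal(size=3) for _ in range(k)])
        res = hartley_test(s, alpha=0.05)
        assert res.extras["critical_value"] == pytest.approx(crit, rel=1e-3)
        assert res.rejected == (res.statistic > crit)

    def test_unbalanced_uses_smallest_df(self, rng):
        s = GroupedSample.from_arrays([rng.normal(size=4), rng.normal(size=9)])
        res = hartley_test(s)
        assert res.extras["df"] == 3
        assert "unbalanced" in res.extras["note"]


class TestCochran:
    def test_equal_variances_give_one_over_k(self):
        g = [0.0, 1.0, 2.0]
        s = GroupedSample.from_arrays([g, [v + 1 for v in g], [v - 3 for v in g]])
        res = cochran_c_test(s)
        assert res.statistic == pytest.approx(1.0 / 3.0)
        assert res.rejected is False

    def test_inflated_variance_detected(self, rng):
        s = GroupedSample.from_arrays(
            [rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(0, 30, 20)]
        )
        res = cochran_c_test(s)
        assert res.extras["tested_group"] == "g3"
        assert res.rejected is True

    def test_k2_n3_upper_limit(self, rng):
        s = GroupedSample.from_arrays([rng.normal(size=3), rng.normal(size=3)])
        res = cochran_c_test(s, alpha=0.05)
        assert res.extras["upper_limit"] == pytest.approx(0.975, abs=1e-10)

    def test_unbalanced_rejected(self, rng):
        s = GroupedSample.from_arrays([rng.normal(size=4), rng.normal(size=5)])
        with pytest.raises(ValidationError):
            cochran_c_test(s)


class TestFlignerKilleen:
    def test_matches_scipy(self, rng):
        for _ in range(10):
            s = random_sample(rng, scales=[1.0, 1.5, 3.0])
            mine = fligner_killeen_test(s)
            ref = stats.fligner(*s.groups)
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_normal_scores_small_sample(self):
        # N=3 scores must be Phi^-1(0.625), Phi^-1(0.75), Phi^-1(0.875)
        expected = stats.norm.ppf([0.625, 0.75, 0.875])
        np.testing.assert_allclose(
            expected, [0.3186, 0.6745, 1.1503], atol=5e-5
        )

    def test_identical_groups_zero_statistic(self):
        g = [1.0, 4.0, 6.0, 9.0]
        s = GroupedSample.from_arrays([g, list(g)])
        assert fligner_killeen_test(s).statistic == pytest.approx(0.0)

    def test_per_group_shift_invariance(self, three_group_sample):
        base = fligner_killeen_test(three_group_sample)
        shifted = GroupedSample.from_arrays(
            [g + d for g, d in zip(three_group_sample.groups, (5.0, -2.0, 9.0))]
        )
        assert fligner_killeen_test(shifted).statistic == pytest.approx(
            base.statistic, rel=1e-9
        )


class TestWelchAnova:
    def test_reduces_to_welch_t_squared_at_k2(self, rng):
        for _ in range(100):
            x = rng.normal(0, 1, int(rng.integers(5, 20)))
            y = rng.normal(1, 2, int(rng.integers(5, 20)))
            wa = welch_anova(GroupedSample.from_arrays([x, y]))
            wt = welch_t_test(x, y)
            assert wa.statistic == pytest.approx(wt.statistic**2, rel=1e-10)
            assert wa.df[1] == pytest.approx(
                welch_df(x.var(ddof=1), y.var(ddof=1), x.size, y.size), rel=1e-10
            )

    def test_matches_pingouin_at_k3(self, three_group_sample):
        import pingouin as pg

        res = pg.welch_anova(
            data=three_group_sample.to_frame(), dv="value", between="group"
        )
        mine = welch_anova(three_group_sample)
        assert mine.statistic == pytest.approx(float(res["F"][0]), rel=1e-10)
        assert mine.df[1] == pytest.approx(float(res["ddof2"][0]), rel=1e-10)
        assert mine.p_value == pytest.approx(float(res["p_unc"][0]), rel=1e-8)

    def test_equal_means_give_zero(self):
        s = GroupedSample.from_arrays([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0]])
        res = welch_anova(s)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_plain_anova_for_equal_n_equal_variance_k2(self, rng):
        # at k=2 the small-sample correction vanishes, so with identical
        # group variances and sizes the Welch statistic is the plain ANOVA F
        g = rng.normal(0, 1, 10)
        s = GroupedSample.from_arrays([g, g + 0.5])
        assert welch_anova(s).statistic == pytest.approx(
            one_way_anova(s).statistic, rel=1e-10
        )


class TestOneWayAnova:
    def test_matches_scipy(self, three_group_sample):
        mine = one_way_anova(three_group_sample)
        ref = stats.f_oneway(*three_group_sample.groups)
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_constant_data_degenerate(self):
        s = GroupedSample.from_arrays([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(DegenerateDataError):
            one_way_anova(s)

    def test_f_equals_pooled_t_squared_at_k2(self, rng):
        x, y = rng.normal(0, 1, 9), rng.normal(1, 1, 13)
        anova = one_way_anova(GroupedSample.from_arrays([x, y]))
        t = welch_t_test(x, y, assume_equal_variance=True)
        assert anova.statistic == pytest.approx(t.statistic**2, rel=1e-10)

    def test_f_increases_with_group_shift(self, rng):
        g = rng.normal(0, 1, 10)
        stats_by_delta = [
            one_way_anova(
                GroupedSample.from_arrays([g, g + delta, g - 0.1])
            ).statistic
            for delta in (0.5, 1.0, 2.0, 4.0)
        ]
        assert stats_by_delta == sorted(stats_by_delta)


class TestCommonInvariances:
    """Location/scale invariances shared by every homogeneity statistic."""

    @pytest.mark.parametrize(
        "testfn",
        [
            lambda s: levene_test(s, center="mean"),
            lambda s: levene_test(s, center="median"),
            lambda s: levene_test(s, center="trimmed"),
            bartlett_test,
            hartley_test,
            fligner_killeen_test,
        ],
    )
    def test_global_shift_and_scale(self, rng, testfn):
        # odd group sizes: even sizes create an exact tie in |Y - median|
        # that float rounding can break under an affine transform
        s = random_sample(rng, sizes=[9, 9, 11], scales=[1.0, 2.0, 1.0])
        base = testfn(s)
        moved = GroupedSample.from_arrays([2.5 * g + 40.0 for g in s.groups])
        res = testfn(moved)
        assert res.statistic == pytest.approx(base.statistic, rel=1e-9)
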