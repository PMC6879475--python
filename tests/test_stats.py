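"""Agreement and comparison statistics against closed forms/enumeration."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from cnvquant.errors import NoInformationError, SampleSizeError, ValidationError
from cnvquant.stats import (
    bland_altman,
    group_summary,
    mann_whitney_u,
    paired_t_test,
    pearson_correlation,
    unpaired_t_test,
    wilcoxon_signed_rank,
)


class TestBlandAltman:
    def test_identical_methods_collapse_to_zero(self):
        ba = bland_altman([3.0, 7.0, 11.0], [3.0, 7.0, 11.0])
        assert ba.mean_diff == 0.0 and ba.sd_diff == 0.0
        assert (ba.loa_low, ba.loa_high) == (0.0, 0.0)

    def test_hand_computed_example(self):
        ba = bland_altman([1, 2, 3], [2, 2, 4])
        assert ba.mean_diff == pytest.approx(-2.0 / 3.0)
        assert ba.sd_diff == pytest.approx(0.57735, abs=1e-5)
        assert ba.loa_low == pytest.approx(-1.798, abs=1e-3)
        assert ba.loa_high == pytest.approx(0.465, abs=1e-3)
        assert ba.ci_mean[0] < ba.mean_diff < ba.ci_mean[1]
        assert np.allclose(ba.pairs[:, 0], [1.5, 2.0, 3.5])

    def test_large_sample_converges_to_population_values(self):
        rng = np.random.default_rng(7)
        y = rng.normal(10.0, 3.0, 20000)
        x = y + rng.normal(0.5, 1.0, 20000)
        ba = bland_altman(x, y)
        assert ba.mean_diff == pytest.approx(0.5, abs=0.03)
        assert ba.loa_high - ba.loa_low == pytest.approx(3.92, abs=0.06)

    def test_loa_coverage_near_95pct(self):
        rng = np.random.default_rng(11)
        d = rng.normal(1.0, 2.0, 50000)
        ba = bland_altman(d, np.zeros_like(d))
        covered = np.mean((d >= ba.loa_low) & (d <= ba.loa_high))
        assert covered == pytest.approx(0.95, abs=0.02)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(SampleSizeError):
            bland_altman([1, 2], [1, 2])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1, 2, np.nan], [1, 2, 3])


class TestPearson:
    def test_perfect_positive_affine(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pearson_correlation(x, 2 * x + 1).statistic == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson_correlation(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        r = pearson_correlation(x, y).statistic
        expect = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(expect, abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.random(30)
        y = rng.random(30)
        r0 = pearson_correlation(x, y).statistic
        r1 = pearson_correlation(3.0 * x + 2.0, 0.5 * y - 7.0).statistic
        assert r0 == pytest.approx(r1, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPairedT:
    def test_equal_samples(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_zero_mean_differences(self):
        res = paired_t_test([1.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0])
        assert res.statistic == pytest.approx(0.0)

    def test_closed_form_small_sample(self):
        # d = (1, 2, 3): t = mean / (sd / sqrt(3)) = 2 / (1/sqrt(3))
        res = paired_t_test([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        expect_t = 2.0 / (1.0 / np.sqrt(3.0))
        assert res.statistic == pytest.approx(expect_t, abs=1e-12)
        assert res.p_value == pytest.approx(2 * sps.t.sf(expect_t, 2), abs=1e-12)

    def test_shift_invariance_of_differences(self, rng):
        x = rng.random(12)
        y = rng.random(12)
        r0 = paired_t_test(x, y)
        r1 = paired_t_test(x + 5.0, y + 5.0)
        assert r0.statistic == pytest.approx(r1.statistic, abs=1e-9)

    def test_constant_nonzero_difference_edge(self):
        res = paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.p_value == 0.0 and np.isinf(res.statistic)


class TestWilcoxon:
    def test_all_ties_carry_no_information(self):
        with pytest.raises(NoInformationError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_symmetric_differences_accept_null(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = x + np.array([0.5, -0.5, 0.5, -0.5, 0.5, -0.5])
        assert wilcoxon_signed_rank(x, y).p_value >= 0.9

    def test_six_positive_differences_exact_p(self):
        res = wilcoxon_signed_rank([2, 3, 4, 5, 6, 7], [1, 1, 1, 1, 1, 1])
        assert res.statistic == 21.0
        assert res.p_value == pytest.approx(1.0 / 32.0, abs=1e-15)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(-6, 7, size=rng.integers(6, 12))
        d = d[d != 0]
        if len(d) < 5:
            d = np.concatenate([d, [1, -2, 3, 4, -5]])
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        lows = highs = total = 0
        for signs in itertools.product((0, 1), repeat=len(d)):
            w = sum(r for s, r in zip(signs, ranks) if s)
            lows += w <= w_obs + 1e-9
            highs += w >= w_obs - 1e-9
            total += 1
        expect = min(1.0, 2.0 * min(lows / total, highs / total))
        got = wilcoxon_signed_rank(d.astype(float), np.zeros(len(d))).p_value
        assert got == pytest.approx(expect, abs=1e-12)

    def test_large_n_uses_normal_approximation(self, rng):
        d = rng.normal(0.3, 1.0, 40)
        d = d[d != 0]
        res = wilcoxon_signed_rank(d, np.zeros_like(d))
        ref = sps.wilcoxon(d, alternative="two-sided", correction=False, method="approx")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_too_few_informative_pairs(self):
        with pytest.raises(SampleSizeError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0], [0.0, 2.0, 3.0, 4.0])


class TestUnpairedT:
    def test_identical_groups(self):
        res = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)

    def test_swap_negates_t_keeps_p(self, rng):
        x = rng.random(8)
        y = rng.random(5) + 0.3
        r_xy = unpaired_t_test(x, y)
        r_yx = unpaired_t_test(y, x)
        assert r_xy.statistic == pytest.approx(-r_yx.statistic, abs=1e-12)
        assert r_xy.p_value == pytest.approx(r_yx.p_value, abs=1e-12)

    def test_welch_closed_form(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([4.0, 5.0, 6.0])
        res = unpaired_t_test(x, y)
        se = np.sqrt(x.var(ddof=1) / 3 + y.var(ddof=1) / 3)
        assert res.statistic == pytest.approx((x.mean() - y.mean()) / se, abs=1e-12)

    def test_group_too_small_rejected(self):
        with pytest.raises(SampleSizeError):
            unpaired_t_test([1.0], [1.0, 2.0])


class TestGroupSummary:
    def test_singleton_flags_undefined_sd(self):
        s = group_summary([5.0])
        assert s.mean == 5.0 and s.sd == 0.0 and s.sd_undefined

    def test_quantile_convention_linear_interpolation(self):
        s = group_summary([1.0, 2.0, 3.0, 4.0])
        assert (s.median, s.q1, s.q3) == (2.5, 1.75, 3.25)

    def test_constant_values(self):
        s = group_summary([2.0, 2.0, 2.0])
        assert s.sd == 0.0 and (s.q1, s.q3) == (2.0, 2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            group_summary([])


def test_mann_whitney_available_for_unpaired_groups(rng):
    x = rng.normal(0, 1, 10)
    y = rng.normal(1, 1, 12)
    res = mann_whitney_u(x, y)
    ref = sps.mannwhitneyu(x, y, alternative="two-sided")
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue)
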