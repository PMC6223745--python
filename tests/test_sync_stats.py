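"""Synchronization statistics: binning, widths, CV, McKay CI, t-test, yield."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from embryosync import (
    BinnedDistribution,
    GerminationRecord,
    LengthSample,
    bin_lengths,
    cv,
    germination_rates,
    mckay_ci,
    ttest_two_sample,
    width_at_fraction,
    widths,
    yield_per_gfw,
)
from embryosync.sync_stats import cv_estimate, replicate_width_summary

GAUSS_WIDTH = {f: 2 * np.sqrt(2 * np.log(1 / f)) for f in (0.50, 0.66, 0.75)}  # for sigma = 1


class TestBinLengths:
    def test_hand_counted_example(self):
        d = bin_lengths([0.5, 1.5, 1.6, 2.5], delta=1.0)
        assert list(d.counts) == [1, 2, 1]
        assert np.allclose(d.phi, [0.5, 1.0, 0.5])
        assert np.allclose(d.centers, [0.5, 1.5, 2.5])

    def test_single_bin(self):
        d = bin_lengths([2.1, 2.2, 2.9], delta=1.0)
        assert d.counts[-1] == 3 and d.phi[-1] == 1.0

    def test_halving_delta_preserves_total(self):
        lengths = np.linspace(0.2, 4.8, 57)
        assert bin_lengths(lengths, 0.5).n == bin_lengths(lengths, 1.0).n == 57

    def test_normalization_peaks_at_one(self):
        rng = np.random.default_rng(0)
        d = bin_lengths(rng.uniform(0.1, 5, 200), 0.5)
        assert d.phi.max() == 1.0
        assert d.n == 200

    def test_errors(self):
        with pytest.raises(ValueError):
            bin_lengths([], 1.0)
        with pytest.raises(ValueError):
            bin_lengths([1.0], -1.0)
        with pytest.raises(ValueError, match="origin"):
            bin_lengths([0.5], 1.0, origin=1.0)


class TestWidths:
    def test_triangular_fwhm(self, triangular_dist):
        assert width_at_fraction(triangular_dist, 0.5) == pytest.approx(2.0)

    def test_triangular_three_quarters(self, triangular_dist):
        assert width_at_fraction(triangular_dist, 0.75) == pytest.approx(1.0)

    def test_triangular_width_set(self, triangular_dist):
        w = widths(triangular_dist)
        assert (w.width_50, w.width_66, w.width_75) == pytest.approx((2.0, 1.36, 1.0))

    def test_gaussian_widths_match_closed_form_without_noise(self):
        # oracle: FWHM of a normal density is 2*sigma*sqrt(2 ln 2), and
        # analogously 2*sigma*sqrt(2 ln(1/f)) at fraction f; checked on the
        # exact expected histogram so only interpolation error remains
        from scipy.stats import norm

        delta = 0.05
        edges = np.arange(6.0, 14.0001, delta)
        counts = np.diff(norm.cdf(edges, 10.0, 1.0)) * 1e5
        d = BinnedDistribution(delta=delta, origin=6.0, counts=counts)
        # residual error: linear interpolation plus the sub-bin peak fit
        for f, expected in GAUSS_WIDTH.items():
            assert width_at_fraction(d, f) == pytest.approx(expected, rel=5e-3)

    def test_monotone_non_increasing_in_fraction(self, triangular_dist):
        fs = np.linspace(0.05, 0.95, 19)
        ws = [width_at_fraction(triangular_dist, f) for f in fs]
        assert all(a >= b for a, b in zip(ws, ws[1:]))

    @given(counts=st.lists(st.integers(0, 50), min_size=1, max_size=12).filter(lambda c: sum(c) > 0))
    def test_monotone_in_fraction_property(self, counts):
        d = BinnedDistribution(delta=1.0, origin=0.0, counts=np.array(counts))
        ws = [width_at_fraction(d, f) for f in (0.2, 0.5, 0.66, 0.75, 0.9)]
        assert all(a >= b - 1e-12 for a, b in zip(ws, ws[1:]))

    @given(scale=st.integers(2, 1000))
    def test_invariant_to_count_rescaling(self, scale):
        counts = np.array([1, 4, 9, 5, 2])
        d1 = BinnedDistribution(1.0, 0.0, counts)
        d2 = BinnedDistribution(1.0, 0.0, counts * scale)
        for f in (0.5, 0.66, 0.75):
            assert width_at_fraction(d1, f) == pytest.approx(width_at_fraction(d2, f), rel=1e-12)

    def test_errors(self, triangular_dist):
        with pytest.raises(ValueError):
            width_at_fraction(triangular_dist, 1.5)
        with pytest.raises(ValueError, match="zero"):
            width_at_fraction(BinnedDistribution(1.0, 0.0, np.array([0, 0])), 0.5)


class TestReplicateWidthSummary:
    def test_identical_replicates_zero_sd(self):
        s = LengthSample([1.2, 2.5, 2.6, 3.4])
        df = replicate_width_summary([s, s, s], delta=1.0)
        assert np.allclose(df["width_sd"], 0.0)

    def test_single_replicate_sd_absent(self):
        df = replicate_width_summary([LengthSample([1.2, 2.5, 3.1])], delta=1.0)
        assert df["width_sd"].isna().all()
        assert np.isfinite(df["width_mean"]).all()


class TestCV:
    def test_hand_example(self):
        assert cv([1, 2, 3]) == pytest.approx(0.5)  # mean 2, sample SD 1

    def test_constant_sample(self):
        assert cv([4.2, 4.2, 4.2]) == 0.0

    def test_summary_input_check(self):
        # ratio of reported SD to mean for the dispersed bioreactor group
        assert round(0.74 / 3.05, 2) == 0.24

    @given(
        values=st.lists(st.floats(0.1, 100), min_size=3, max_size=30),
        c=st.floats(0.01, 50),
    )
    def test_scale_invariance(self, values, c):
        x = np.asarray(values)
        assert cv(c * x) == pytest.approx(cv(x), rel=1e-9, abs=1e-12)

    def test_nonpositive_mean_fails(self):
        with pytest.raises(ValueError):
            cv([-1.0, -2.0, 3.0])


class TestMcKayCI:
    def test_reported_bioreactor_intervals(self):
        low, high = mckay_ci(0.24, 1037, 0.90)
        assert (round(low, 2), round(high, 2)) == (0.23, 0.25)
        low, high = mckay_ci(0.27, 1176, 0.90)
        assert (round(low, 2), round(high, 2)) == (0.26, 0.28)

    def test_contains_point_estimate(self):
        low, high = mckay_ci(0.3, 50, 0.95)
        assert low < 0.3 < high

    def test_narrows_with_sample_size(self):
        w = [np.diff(mckay_ci(0.25, n, 0.90))[0] for n in (10, 100, 1000, 10000)]
        assert all(a > b for a, b in zip(w, w[1:]))

    def test_vanishing_level_collapses_to_estimate(self):
        low, high = mckay_ci(0.24, 1000, 1e-9)
        assert low == pytest.approx(high, rel=1e-6)
        assert low == pytest.approx(0.24, rel=0.01)

    def test_impossible_radicand_fails_with_reason(self):
        with pytest.raises(ValueError, match="radicand"):
            mckay_ci(5.0, 2, 0.99)

    def test_estimate_wrapper_brackets(self):
        est = cv_estimate(np.random.default_rng(0).normal(3, 0.7, 500), level=0.90)
        assert est.ci_low <= est.cv <= est.ci_high
        assert est.n == 500


class TestTTest:
    def test_identical_groups(self):
        r = ttest_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.pvalue > 0.99

    def test_degenerate_equal_constant_groups(self):
        r = ttest_two_sample([2.0, 2.0], [2.0, 2.0])
        assert (r.statistic, r.pvalue) == (0.0, 1.0)

    def test_hand_pooled_example(self):
        # pooled variance 1, se = sqrt(2/3), t = -3/se, 4 df
        r = ttest_two_sample([1, 2, 3], [4, 5, 6])
        assert r.statistic == pytest.approx(-3.6742, abs=1e-4)
        assert r.df == 4
        assert r.pvalue == pytest.approx(0.0213, abs=1e-3)

    def test_constant_groups_with_unequal_means_fail(self):
        with pytest.raises(ValueError, match="zero variance"):
            ttest_two_sample([1.0, 1.0], [2.0, 2.0])

    def test_welch_flag(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [10.0, 30.0, 22.0, 18.0, 25.0]
        assert ttest_two_sample(a, b, welch=True).df < ttest_two_sample(a, b).df


class TestYield:
    def test_extrapolation(self):
        assert yield_per_gfw(150, 0.15, 2.0).embryos_per_gfw == pytest.approx(500.0)

    def test_full_sampling(self):
        assert yield_per_gfw(80, 1.0, 2.0).embryos_per_gfw == pytest.approx(40.0)

    def test_sampled_fraction_asymmetry(self):
        # the same harvested count extrapolates 5x higher at 15% sampling than at 75%
        lo = yield_per_gfw(150, 0.75, 2.0).embryos_per_gfw
        hi = yield_per_gfw(150, 0.15, 2.0).embryos_per_gfw
        assert hi == pytest.approx(5 * lo)

    def test_errors(self):
        with pytest.raises(ValueError):
            yield_per_gfw(10, 0.0, 1.0)
        with pytest.raises(ValueError):
            yield_per_gfw(10, 0.5, 0.0)


class TestGermination:
    @pytest.mark.parametrize(
        "rec,expected",
        [
            (GerminationRecord(1006, 865, 748), (86, 74)),
            (GerminationRecord(605, 340, 303), (56, 50)),
            (GerminationRecord(10, 10, 10), (100, 100)),
        ],
    )
    def test_rates(self, rec, expected):
        assert germination_rates(rec) == expected

    def test_zero_collected_fails(self):
        with pytest.raises(ValueError):
            germination_rates(GerminationRecord(0, 0, 0))

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            GerminationRecord(10, 12, 3)
        with pytest.raises(ValueError):
            GerminationRecord(10, 5, 7)
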