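"""Contrast enhancement, baseline filtering, half-life fitting, spectral
correlation, loading arithmetic and t-tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from paquant.exceptions import NumericalError, ValidationError
from paquant.quantify import (ExponentialDecayModel, baseline_filter, ce_image,
                              ce_statistic, compare_groups, fit_halflife,
                              loading_ratio, spectral_correlation)
from paquant.simulate import make_decay_series


class TestCEImage:
    def test_no_change_is_zero(self):
        pre = np.full((2, 3, 3), 0.2)
        assert np.allclose(ce_image(pre.copy(), pre), 0.0)

    def test_arithmetic(self):
        pre = np.array([[[0.1]]])
        post = np.array([[[0.3]]])
        assert ce_image(post, pre)[0, 0, 0] == pytest.approx(2.0)

    def test_zero_pre_voxel_invalid(self):
        pre = np.array([[[0.0, 0.1]]])
        post = np.array([[[0.5, 0.2]]])
        out = ce_image(post, pre)
        assert np.isnan(out[0, 0, 0])
        assert out[0, 0, 1] == pytest.approx(1.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            ce_image(np.zeros((1, 2, 2)), np.zeros((1, 3, 3)))

    def test_positivity_semantics(self):
        """CE > 0 exactly where post exceeds pre, over all valid voxels."""
        rng = np.random.default_rng(1)
        pre = rng.uniform(0.05, 1.0, (3, 8, 8))
        post = rng.uniform(0.0, 1.5, pre.shape)
        out = ce_image(post, pre)
        valid = np.isfinite(out)
        assert np.array_equal(out[valid] > 0, post[valid] > pre[valid])


class TestBaselineFilter:
    def test_identical_slices(self):
        vol = np.tile(np.arange(9.0).reshape(1, 3, 3), (3, 1, 1))
        roi = np.ones_like(vol, dtype=bool)
        flt = baseline_filter(vol, roi)
        assert flt.mean == 0.0 and flt.sd == 0.0
        assert flt.excludes(np.array([0.0]))[0]
        assert not flt.excludes(np.array([1e-9]))[0]

    def test_constant_offset(self):
        vol = np.stack([np.zeros((4, 4)), np.full((4, 4), 0.7)])
        roi = np.ones_like(vol, dtype=bool)
        flt = baseline_filter(vol, roi)
        assert flt.mean == pytest.approx(0.7)
        assert flt.sd == pytest.approx(0.0)

    def test_single_slice_rejected(self):
        vol = np.zeros((1, 4, 4))
        with pytest.raises(ValidationError):
            baseline_filter(vol, np.ones_like(vol, dtype=bool))

    def test_standard_normal_exclusion_fraction(self):
        """With standard-normal slice differences the filter excludes
        Phi(1) - Phi(-1) ~= 68.3% of standard-normal CE values."""
        rng = np.random.default_rng(0)
        base = rng.normal(0, 5.0, (200, 200))
        vol = np.stack([base, base + rng.normal(0, 1.0, base.shape)])
        roi = np.ones_like(vol, dtype=bool)
        flt = baseline_filter(vol, roi)
        ce_values = rng.normal(0, 1.0, 100_000)
        frac = flt.excludes(ce_values).mean()
        assert frac == pytest.approx(stats.norm.cdf(1) - stats.norm.cdf(-1), abs=0.02)

    def test_filtered_mean_unbiased_on_pure_noise(self):
        """Removing the noise core must not shift the sign of the surviving
        mean: |mean| < 3 standard errors on pure-noise CE maps."""
        rng = np.random.default_rng(7)
        base = rng.normal(0, 3.0, (120, 120))
        vol = np.stack([base, base + rng.normal(0, 1.0, base.shape)])
        roi3 = np.ones_like(vol, dtype=bool)
        flt = baseline_filter(vol, roi3)
        ce_map = rng.normal(0, 1.0, (1, 300, 300))
        res = ce_statistic(ce_map, np.ones_like(ce_map, dtype=bool), flt)
        survivors_sd = 1.0  # upper bound on the survivor SD
        assert abs(res.ce) < 3 * survivors_sd / np.sqrt(res.n_survivors)


class TestCEStatistic:
    def test_uniform_ce(self):
        ce_map = np.full((1, 5, 5), 1.5)
        res = ce_statistic(ce_map, np.ones_like(ce_map, dtype=bool))
        assert res.ce == pytest.approx(1.5)
        assert res.n_survivors == 25

    def test_zero_survivors_errors(self):
        from paquant.quantify import BaselineFilter

        ce_map = np.zeros((1, 3, 3))
        flt = BaselineFilter(mean=0.0, sd=1.0, n_differences=10)
        with pytest.raises(ValidationError):
            ce_statistic(ce_map, np.ones_like(ce_map, dtype=bool), flt)


class TestHalfLife:
    def test_noiseless_exact(self):
        s = make_decay_series(1.0, 10.0, np.linspace(0, 15, 40), 0.0)
        fit = fit_halflife(s.times_min, s.values)
        assert fit.half_life_min == pytest.approx(10.0, rel=1e-9)

    def test_halflife_lambda_identity(self):
        s = make_decay_series(2.0, 7.3, np.linspace(0, 20, 30), 0.01, seed=4)
        fit = fit_halflife(s.times_min, s.values)
        assert fit.half_life_min * fit.lam == pytest.approx(np.log(2), rel=1e-12)

    def test_known_lambda(self):
        t = np.linspace(0, 30, 40)
        y = 5.0 * np.exp(-0.1 * t)
        fit = fit_halflife(t, y)
        assert fit.half_life_min == pytest.approx(np.log(2) / 0.1, rel=1e-9)

    def test_time_rebased_to_peak(self):
        t = np.linspace(0, 20, 30)
        y = 1.0 * np.exp(-0.2 * np.maximum(t - 5.0, 0.0))
        y[t < 5.0] = 0.2  # pre-injection baseline below the peak
        fit = fit_halflife(t, y)
        assert fit.half_life_min == pytest.approx(np.log(2) / 0.2, rel=1e-6)

    def test_recovery_within_5pct_at_2pct_noise(self):
        """Mean recovered half-life over 100 noisy replicates stays within
        5% of the 10 min truth at 2% amplitude noise."""
        est = []
        for seed in range(100):
            s = make_decay_series(1.0, 10.0, np.linspace(0, 15, 46),
                                  noise_sd=0.02, seed=seed)
            est.append(fit_halflife(s.times_min, s.values).half_life_min)
        assert np.mean(est) == pytest.approx(10.0, rel=0.05)

    def test_nondecaying_series_fails(self):
        # peak first, then a rising trend: fitted lambda <= 0
        t = np.linspace(0, 10, 8)
        y = np.array([1.0, 0.90, 0.92, 0.94, 0.96, 0.97, 0.98, 0.99])
        with pytest.raises(NumericalError):
            ExponentialDecayModel(t, y).fit()

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            fit_halflife([0.0, 1.0, 2.0], [3.0, 2.0, 1.0])

    def test_ci_covers_truth_noiseless_limit(self):
        s = make_decay_series(1.0, 10.0, np.linspace(0, 15, 46), 0.005, seed=9)
        fit = fit_halflife(s.times_min, s.values)
        lo, hi = fit.half_life_ci()
        assert lo < 10.0 < hi


class TestSpectralCorrelation:
    def test_identity_and_affine_invariance(self):
        v = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        assert spectral_correlation(v, v) == pytest.approx(1.0)
        assert spectral_correlation(v, 2.5 * v + 1.0) == pytest.approx(1.0)

    def test_anticorrelated(self):
        assert spectral_correlation([1.0, 0.0, 1.0, 0.0],
                                    [0.0, 1.0, 0.0, 1.0]) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            spectral_correlation([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestLoadingRatio:
    def test_printed_value(self):
        assert loading_ratio(1.37e15, 8.88e8) == pytest.approx(1.54e6, rel=1e-3)

    def test_identity_and_arithmetic(self):
        assert loading_ratio(3.3e7, 3.3e7) == 1.0
        assert loading_ratio(1e10, 2e5) == pytest.approx(5.00e4)

    def test_zero_denominator(self):
        with pytest.raises(ValidationError):
            loading_ratio(1e10, 0.0)


class TestCompareGroups:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0]
        t, p = compare_groups(a, a, tail="two")
        assert p == pytest.approx(1.0)
        _, p1 = compare_groups(a, a, tail="one")
        assert p1 == pytest.approx(0.5)

    def test_separated_groups(self):
        a = [10.0, 10.01, 9.99]
        b = [0.0, 0.01, -0.01]
        _, p = compare_groups(a, b, tail="one")
        assert p < 1e-3

    def test_matches_textbook_formula(self):
        """Pooled-variance two-sample t on a 3+3 fixture vs the closed
        form."""
        a = np.array([2.1, 2.5, 2.3])
        b = np.array([1.7, 1.9, 1.8])
        t_stat, p = compare_groups(a, b, tail="two")
        sp2 = ((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4
        expect = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t_stat == pytest.approx(expect, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(expect), 4), rel=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(shift=st.floats(-2, 2))
    def test_tail_consistency(self, shift):
        rng = np.random.default_rng(0)
        a = rng.normal(shift, 1, 10)
        b = rng.normal(0, 1, 10)
        t_stat, p_g = compare_groups(a, b, tail="greater")
        _, p_l = compare_groups(a, b, tail="less")
        assert p_g + p_l == pytest.approx(1.0)
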