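"""Distributional core: logistic-G kernel, LN and skew-LN laws."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

import logisnorm as lg
from logisnorm.errors import DomainError, InvalidParameterError


class TestLogisticG:
    def test_kernel_values(self):
        # symmetry point, identity at lam=1, and one hand-computed value:
        # u=0.75, lam=2 -> 0.5625 / (0.5625 + 0.0625) = 0.9
        assert lg.logistic_g_cdf(0.5, 7.3) == pytest.approx(0.5)
        assert lg.logistic_g_cdf(0.3, 1.0) == pytest.approx(0.3)
        assert lg.logistic_g_cdf(0.75, 2.0) == pytest.approx(0.9)

    @given(st.floats(0.0, 1.0), st.floats(0.05, 20.0))
    def test_kernel_bounds_and_monotonicity(self, u, lam):
        v = lg.logistic_g_cdf(u, lam)
        assert 0.0 <= v <= 1.0
        assert lg.logistic_g_cdf(min(u + 0.01, 1.0), lam) >= v - 1e-12

    def test_kernel_errors(self):
        with pytest.raises(InvalidParameterError):
            lg.logistic_g_cdf(0.5, -1.0)
        with pytest.raises(DomainError):
            lg.logistic_g_cdf(1.2, 1.0)

    @pytest.mark.parametrize("lam", [0.3, 1.0, 3.0])
    def test_quantile_round_trip_with_normal_baseline(self, lam):
        baseline = stats.norm(loc=1.0, scale=2.0)
        p = np.linspace(0.01, 0.99, 99)
        x = lg.logistic_g_quantile(p, baseline, lam)
        back = lg.logistic_g_cdf(baseline.cdf(x), lam)
        assert np.allclose(back, p, atol=1e-10)

    def test_quantile_median_and_identity_reduction(self):
        baseline = stats.norm(3.0, 0.5)
        assert lg.logistic_g_quantile(0.5, baseline, 4.2) == pytest.approx(3.0)
        p = np.linspace(0.05, 0.95, 19)
        assert np.allclose(lg.logistic_g_quantile(p, baseline, 1.0),
                           baseline.ppf(p), atol=1e-12)


class TestLNDistribution:
    def test_cdf_at_location_is_half(self):
        assert lg.ln_cdf(3.0, lg.LNParams(2.7, 3.0, 1.4)) == pytest.approx(0.5)

    def test_lam_one_reduces_to_normal(self):
        params = lg.LNParams(1.0, 0.5, 2.0)
        x = np.linspace(-8, 9, 61)
        assert np.allclose(lg.ln_cdf(x, params), stats.norm.cdf(x, 0.5, 2.0),
                           atol=1e-10)
        assert np.allclose(lg.ln_logpdf(x, params),
                           stats.norm.logpdf(x, 0.5, 2.0), atol=1e-10)
        p = np.linspace(0.01, 0.99, 25)
        assert np.allclose(lg.ln_quantile(p, params),
                           stats.norm.ppf(p, 0.5, 2.0), atol=1e-10)

    @pytest.mark.parametrize("lam", [0.3, 2.0])
    @pytest.mark.parametrize("d", [0.5, 1.0, 3.0])
    def test_cdf_symmetry_identity(self, lam, d):
        params = lg.LNParams(lam, 1.0, 0.7)
        total = lg.ln_cdf(1.0 + d, params) + lg.ln_cdf(1.0 - d, params)
        assert total == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(-6.0, 6.0), st.floats(0.1, 10.0))
    def test_density_symmetric_about_mu(self, d, lam):
        params = lg.LNParams(lam, 2.0, 1.3)
        assert lg.ln_logpdf(2.0 + d, params) == pytest.approx(
            lg.ln_logpdf(2.0 - d, params), rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("lam", [0.1, 0.2, 0.5, 1.0, 3.0, 10.0])
    def test_density_normalizes(self, lam):
        params = lg.LNParams(lam)
        val, _ = integrate.quad(lambda t: lg.ln_pdf(t, params), -40, 40,
                                limit=300)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_log_scale_stability_far_in_the_tail(self):
        params = lg.LNParams(2.0)
        assert np.isfinite(lg.ln_logcdf(-40.0, params))
        assert np.isfinite(lg.ln_logpdf(40.0, params))

    @pytest.mark.parametrize("lam", [0.3, 1.0, 2.5])
    def test_quantile_cdf_round_trip(self, lam):
        params = lg.LNParams(lam, -1.0, 2.2)
        p = np.linspace(0.01, 0.99, 99)
        assert np.allclose(lg.ln_cdf(lg.ln_quantile(p, params), params), p,
                           atol=1e-10)
        assert lg.ln_quantile(0.5, params) == pytest.approx(-1.0)

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            lg.LNParams(-0.5)
        with pytest.raises(InvalidParameterError):
            lg.LNParams(1.0, 0.0, -1.0)
        with pytest.raises(DomainError):
            lg.ln_quantile(1.5, lg.LNParams(1.0))


class TestLNSampling:
    @pytest.mark.parametrize("lam", [0.3, 1.0, 2.0])
    def test_sample_matches_cdf(self, lam):
        params = lg.LNParams(lam, 2.0, 1.0)
        x = lg.ln_rvs(10_000, params, seed=123)
        d = lg.ks_statistic(x, lambda v: lg.ln_cdf(v, params))
        assert d < 0.02

    def test_sample_median_near_mu(self):
        params = lg.LNParams(0.7, 5.0, 2.0)
        x = lg.ln_rvs(4000, params, seed=7)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        assert abs(np.median(x) - 5.0) < 3 * iqr / np.sqrt(x.size)

    def test_seed_determinism(self):
        params = lg.LNParams(1.5, 0.0, 1.0)
        assert np.array_equal(lg.ln_rvs(100, params, seed=5),
                              lg.ln_rvs(100, params, seed=5))
        with pytest.raises(DomainError):
            lg.ln_rvs(0, params, seed=1)


class TestLNModes:
    def test_unimodal_case(self):
        res = lg.ln_modes(lg.LNParams(2.0, 3.0, 1.0))
        assert not res.is_bimodal
        assert res.modes[0] == pytest.approx(3.0, abs=1e-8)

    def test_bimodal_case_symmetric_pair(self):
        res = lg.ln_modes(lg.LNParams(0.3, 1.0, 2.0))
        assert res.is_bimodal
        a, b = res.modes
        assert a < 1.0 < b
        assert (a + b) / 2 == pytest.approx(1.0, abs=1e-8)
        # mu sits in a density trough between the two modes
        assert lg.ln_logpdf(1.0, lg.LNParams(0.3, 1.0, 2.0)) < lg.ln_logpdf(
            b, lg.LNParams(0.3, 1.0, 2.0))

    @pytest.mark.parametrize("lam", [0.1, 0.2, 0.3, 0.4])
    def test_bimodal_below_half(self, lam):
        assert lg.ln_modes(lg.LNParams(lam)).is_bimodal

    @pytest.mark.parametrize("lam", [0.6, 0.8, 1.0, 2.0, 5.0, 10.0])
    def test_unimodal_above_threshold(self, lam):
        res = lg.ln_modes(lg.LNParams(lam))
        assert not res.is_bimodal
        assert res.modes[0] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("lam", [0.25, 0.45, 1.7])
    def test_modes_agree_with_grid_argmax(self, lam):
        params = lg.LNParams(lam)
        grid = np.linspace(-6, 6, 100_001)
        dens = lg.ln_pdf(grid, params)
        peak = grid[np.argmax(dens)]
        nearest = min(lg.ln_modes(params).modes, key=lambda m: abs(m - peak))
        assert abs(nearest - peak) <= 2 * (grid[1] - grid[0])


class TestLNMoments:
    def test_first_moment_is_mu(self):
        assert lg.ln_moment(1, lg.LNParams(2.0, 1.0, 2.0)).value == pytest.approx(
            1.0, abs=1e-8)

    def test_standard_normal_variance(self):
        assert lg.ln_moment(2, lg.LNParams(1.0)).value == pytest.approx(1.0, abs=1e-8)

    def test_zeroth_moment_and_odd_xi_vanish(self):
        res = lg.ln_moment(3, lg.LNParams(0.6))
        assert res.xi[0] == 1.0
        assert res.xi[1] == pytest.approx(0.0, abs=1e-8)
        assert res.value == pytest.approx(0.0, abs=1e-7)

    def test_third_moment_against_monte_carlo(self):
        params = lg.LNParams(2.0, 1.0, 2.0)
        exact = lg.ln_moment(3, params).value
        x = lg.ln_rvs(400_000, params, seed=99)
        mc = np.mean(x**3)
        se = np.std(x**3) / np.sqrt(x.size)
        assert abs(exact - mc) < 3 * se

    def test_moment_matches_quantile_integral(self):
        # independent oracle: E[X^2] = int_0^1 Q(p)^2 dp
        params = lg.LNParams(0.5, 0.5, 1.5)
        val, _ = integrate.quad(lambda p: lg.ln_quantile(p, params) ** 2,
                                0, 1, limit=300)
        assert lg.ln_moment(2, params).value == pytest.approx(val, rel=1e-6)


class TestLNTails:
    def test_ratio_symmetric(self):
        assert lg.ln_tail_ratio(8.0, 1.3) == pytest.approx(
            lg.ln_tail_ratio(-8.0, 1.3))

    def test_ratio_stabilizes(self):
        r8 = np.log(lg.ln_tail_ratio(8.0, 1.0))
        r10 = np.log(lg.ln_tail_ratio(10.0, 1.0))
        assert abs(r10 - r8) < 0.05 * max(abs(r8), 1e-3) + 1e-6

    def test_heavier_shape_means_lighter_tail(self):
        # for lam > 1 the log-density falls faster than the normal's -z^2/2
        lam = 3.0
        drop_ln = lg.ln_logpdf(6.0, lg.LNParams(lam)) - lg.ln_logpdf(
            5.0, lg.LNParams(lam))
        drop_normal = stats.norm.logpdf(6.0) - stats.norm.logpdf(5.0)
        assert drop_ln < drop_normal


class TestSkewLN:
    def test_alpha_one_reduces_to_ln(self):
        base = lg.LNParams(0.7, 1.0, 2.0)
        skew = lg.SkewLNParams(0.7, 1.0, 2.0, 1.0)
        x = np.linspace(-8, 10, 50)
        assert np.allclose(lg.skew_ln_cdf(x, skew), lg.ln_cdf(x, base))
        assert np.allclose(lg.skew_ln_logpdf(x, skew), lg.ln_logpdf(x, base))

    def test_lam_one_reduces_to_exponentiated_normal(self):
        params = lg.SkewLNParams(1.0, 0.0, 1.0, 2.5)
        x = np.linspace(-4, 4, 41)
        assert np.allclose(lg.skew_ln_cdf(x, params),
                           stats.norm.cdf(x) ** 2.5, atol=1e-12)

    def test_both_one_reduces_to_normal(self):
        params = lg.SkewLNParams(1.0, 1.0, 2.0, 1.0)
        x = np.linspace(-6, 8, 41)
        assert np.allclose(lg.skew_ln_cdf(x, params),
                           stats.norm.cdf(x, 1.0, 2.0), atol=1e-12)

    @pytest.mark.parametrize("lam", [0.5, 2.0])
    @pytest.mark.parametrize("alpha", [0.5, 3.0])
    def test_density_normalizes(self, lam, alpha):
        params = lg.SkewLNParams(lam, 0.0, 1.0, alpha)
        val, _ = integrate.quad(lambda t: lg.skew_ln_pdf(t, params), -60, 60,
                                limit=400)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_pdf_is_derivative_of_cdf(self):
        params = lg.SkewLNParams(0.8, 0.5, 1.2, 2.0)
        x = np.linspace(-4, 5, 37)
        h = 1e-5
        numeric = (lg.skew_ln_cdf(x + h, params) -
                   lg.skew_ln_cdf(x - h, params)) / (2 * h)
        assert np.allclose(numeric, lg.skew_ln_pdf(x, params), atol=1e-6)

    def test_quantile_round_trip(self):
        params = lg.SkewLNParams(0.7, 0.0, 1.0, 2.5)
        p = np.linspace(0.01, 0.99, 99)
        assert np.allclose(lg.skew_ln_cdf(lg.skew_ln_quantile(p, params), params),
                           p, atol=1e-8)
        # p = 0.5^alpha maps back to the location parameter
        assert lg.skew_ln_quantile(0.5**2.5, params) == pytest.approx(0.0, abs=1e-10)

    def test_sampling_consistency_and_determinism(self):
        params = lg.SkewLNParams(2.0, 0.0, 1.0, 3.0)
        x = lg.skew_ln_rvs(10_000, params, seed=11)
        d = lg.ks_statistic(x, lambda v: lg.skew_ln_cdf(v, params))
        assert d < 0.02
        assert np.array_equal(x, lg.skew_ln_rvs(10_000, params, seed=11))

    def test_reduction_sampling_matches_normal_moments(self):
        params = lg.SkewLNParams(1.0, 2.0, 1.5, 1.0)
        x = lg.skew_ln_rvs(50_000, params, seed=3)
        assert np.mean(x) == pytest.approx(2.0, abs=4 * 1.5 / np.sqrt(x.size))
        assert np.std(x) == pytest.approx(1.5, rel=0.02)

    def test_invalid_alpha_raises(self):
        with pytest.raises(InvalidParameterError):
            lg.SkewLNParams(1.0, 0.0, 1.0, -2.0)
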