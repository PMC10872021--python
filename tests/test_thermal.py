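"""GLS variogram fitting and pool climate metrics."""

import numpy as np
import pytest

from rockpool.simulate import PoolParams, generate_temperature, pool_params, \
    true_pool_climate, SyntheticConfig
from rockpool.thermal import (
    TemperatureSeries,
    VariogramGLS,
    fit_gls_quadratic,
    summarize_pool,
)

DAYS = np.arange(166, 289, dtype=float)


def _series(daily_max, daily_mean=None, pool="p1", days=DAYS):
    if daily_mean is None:
        daily_mean = daily_max - 2.0
    return TemperatureSeries(pool, days, np.asarray(daily_max, float),
                             np.asarray(daily_mean, float))


class TestSeriesValidation:
    def test_days_strictly_increasing(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            _series(np.full(3, 20.0), days=np.array([166.0, 166.0, 167.0]))

    def test_temperature_bounds(self):
        with pytest.raises(ValueError, match="plausible"):
            _series(np.full(len(DAYS), 80.0))

    def test_minimum_observations(self):
        short = TemperatureSeries("p", DAYS[:10], np.full(10, 20.0),
                                  np.full(10, 18.0))
        with pytest.raises(ValueError, match=">= 30 observations"):
            VariogramGLS(short)


class TestGlsFit:
    def test_noiseless_quadratic_recovered(self):
        trend = 28.0 - 0.0016 * (DAYS - 213.0) ** 2
        fit = fit_gls_quadratic(_series(trend))
        a, b, c = fit.trend_coefficients
        assert np.allclose(a + b * DAYS + c * DAYS**2, trend, atol=1e-8)
        assert fit.residual_sd < 1e-8
        assert fit.converged

    def test_white_noise_matches_sample_sd(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 1.2, len(DAYS))
        trend = 26.0 - 0.001 * (DAYS - 210.0) ** 2
        fit = fit_gls_quadratic(_series(trend + noise))
        # residual SD equals the sample SD of the detrended residuals
        assert abs(fit.residual_sd - noise.std(ddof=3)) / noise.std() < 0.05
        # no autocorrelation: fitted range pinned near its lower bound
        assert fit.variogram_range < 1.0

    def test_simulate_and_refit_recovery(self):
        """Mean recovered range within 30% of 5 d, SD within 10% of 1.5."""
        params = PoolParams("x", 28.0, 213.0, 0.0016, 1.5, 5.0, 2.0)
        ranges, sds = [], []
        for seed in range(50):
            fit = fit_gls_quadratic(generate_temperature(params, seed))
            ranges.append(fit.variogram_range)
            sds.append(fit.residual_sd)
        assert abs(np.mean(ranges) - 5.0) / 5.0 < 0.30
        assert abs(np.mean(sds) - 1.5) / 1.5 < 0.10

    def test_detrending_idempotent(self):
        rng = np.random.default_rng(3)
        trend = 27.0 - 0.0015 * (DAYS - 215.0) ** 2
        y = trend + rng.normal(0, 1.0, len(DAYS))
        fit = fit_gls_quadratic(_series(y))
        a, b, c = fit.trend_coefficients
        resid = y - (a + b * DAYS + c * DAYS**2)
        refit = fit_gls_quadratic(_series(resid + 20.0, resid + 18.0))
        _, b2, c2 = refit.trend_coefficients
        assert abs(b2) < 0.05 and abs(c2) < 1e-3

    def test_estimated_sd_monotone_in_generating_sd(self):
        estimates = []
        for sd in (0.5, 1.0, 2.0, 3.0):
            params = PoolParams("x", 28.0, 213.0, 0.0016, sd, 4.0, 2.0)
            fit = fit_gls_quadratic(generate_temperature(params, 11))
            estimates.append(fit.residual_sd)
        assert all(a <= b for a, b in zip(estimates, estimates[1:]))

    def test_ml_solution_beats_perturbed_parameters(self):
        params = PoolParams("x", 28.0, 213.0, 0.0016, 1.5, 5.0, 2.0)
        model = VariogramGLS(generate_temperature(params, 21))
        fit = model.fit()
        for r in (fit.variogram_range * 0.5, fit.variogram_range * 2.0, 1.0):
            assert fit.log_likelihood >= model.log_likelihood_at(r) - 1e-6


class TestPoolClimate:
    def test_constant_series(self):
        fit = fit_gls_quadratic(_series(np.full(len(DAYS), 20.0),
                                        np.full(len(DAYS), 20.0)))
        clim = summarize_pool(_series(np.full(len(DAYS), 20.0),
                                      np.full(len(DAYS), 20.0)), fit)
        assert clim.seasonal_range == 0.0
        assert clim.daily_sd < 1e-8
        assert clim.mean_daily_mean == 20.0

    def test_seasonal_range_matches_direct_scan(self):
        rng = np.random.default_rng(8)
        y = 25.0 + rng.normal(0, 2.0, len(DAYS))
        s = _series(y)
        fit = fit_gls_quadratic(s)
        clim = summarize_pool(s, fit)
        lo = hi = y[0]
        for v in y[1:]:
            lo, hi = min(lo, v), max(hi, v)
        assert clim.seasonal_range == pytest.approx(hi - lo)

    def test_hottest_month_restriction_and_empirical(self):
        trend = 28.0 - 0.0016 * (DAYS - 213.0) ** 2
        s = _series(trend)
        fit = fit_gls_quadratic(s)
        clim = summarize_pool(s, fit, hottest_month=8)
        aug = (DAYS >= 213) & (DAYS <= 243)
        assert clim.hottest_month_mean_daily_max == pytest.approx(
            trend[aug].mean())
        # trend peaks Aug 1 -> empirical hottest month is August
        emp = summarize_pool(s, fit, hottest_month="empirical")
        assert emp.hottest_month_mean_daily_max == \
            clim.hottest_month_mean_daily_max

    def test_missing_month_errors(self):
        s = _series(np.full(len(DAYS), 20.0), np.full(len(DAYS), 19.0))
        fit = fit_gls_quadratic(s)
        with pytest.raises(ValueError, match="month 12"):
            summarize_pool(s, fit, hottest_month=12)

    def test_generator_offsets_propagate(self):
        """Pools generated 1 unit apart in every metric differ by exactly 1."""
        p0 = PoolParams("a", peak_max=27.0, peak_day=213.0, curvature=0.0016,
                        resid_sd=1.0, vario_range=4.0, diurnal_offset=2.0)
        p1 = PoolParams("b", peak_max=28.0, peak_day=213.0, curvature=0.0016,
                        resid_sd=2.0, vario_range=5.0, diurnal_offset=2.0)
        c0, c1 = true_pool_climate(p0), true_pool_climate(p1)
        assert c1.hottest_month_mean_daily_max - \
            c0.hottest_month_mean_daily_max == pytest.approx(1.0)
        assert c1.daily_sd - c0.daily_sd == pytest.approx(1.0)
        assert c1.predictability_days - c0.predictability_days == \
            pytest.approx(1.0)
        assert c1.mean_daily_mean - c0.mean_daily_mean == pytest.approx(1.0)
        assert c1.seasonal_range == pytest.approx(c0.seasonal_range)


class TestGeneratedSeries:
    def test_zero_noise_equals_trend(self):
        p = PoolParams("z", 28.0, 213.0, 0.0016, 0.0, 5.0, 2.5)
        s = generate_temperature(p, 0)
        assert np.allclose(s.daily_max, p.trend(s.day))
        assert np.allclose(s.daily_max - s.daily_mean, 2.5)

    def test_deterministic_given_seed(self):
        p = pool_params(SyntheticConfig(), 3)
        a = generate_temperature(p, 99)
        b = generate_temperature(p, 99)
        assert np.array_equal(a.daily_max, b.daily_max)
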