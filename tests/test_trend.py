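"""PACF-driven order selection, AR fitting and forecasting."""

import numpy as np
import pytest

from tdcal.params import ParameterSpec
from tdcal.trend import (
    adf_test,
    compute_pacf,
    fit_ar,
    fit_linear_trend,
    fit_trend_model,
    forecast_ar,
    select_order,
)


def _ar1(beta0, beta1, sd, n, seed, x0=0.0):
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = x0
    for i in range(1, n):
        x[i] = beta0 + beta1 * x[i - 1] + rng.normal(0.0, sd)
    return x


def _sequential_ols_pacf(series, max_lag):
    """Independent oracle: lag-k coefficient of an order-k OLS autoregression."""
    out = []
    for k in range(1, max_lag + 1):
        target = series[k:]
        design = np.column_stack(
            [np.ones(len(series) - k)] + [series[k - i : len(series) - i] for i in range(1, k + 1)]
        )
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        out.append(coef[-1])
    return np.array(out)


class TestComputePacf:
    def test_white_noise_mostly_inside_band(self):
        rng = np.random.default_rng(42)
        series = rng.normal(size=500)
        vals, degenerate = compute_pacf(series, max_lag=10)
        assert not degenerate
        band = 1.96 / np.sqrt(500)
        assert np.mean(np.abs(vals) < band) >= 0.9

    def test_ar1_lag_one_near_coefficient(self):
        series = _ar1(0.0, 0.8, 1.0, 500, seed=7)
        vals, _ = compute_pacf(series, max_lag=5)
        assert vals[0] == pytest.approx(0.8, abs=0.1)
        oracle = _sequential_ols_pacf(series, 5)
        assert np.allclose(vals, oracle, atol=0.05)

    def test_linear_series_lag_one_near_unity(self):
        series = np.arange(1.0, 51.0)
        vals, _ = compute_pacf(series, max_lag=3)
        assert vals[0] == pytest.approx(1.0, abs=0.05)

    def test_constant_series_degenerate(self):
        vals, degenerate = compute_pacf(np.full(30, 3.3), max_lag=4)
        assert degenerate
        assert np.all(vals == 0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            compute_pacf(np.arange(5.0), max_lag=5)


class TestSelectOrder:
    @pytest.mark.parametrize(
        "pacf_vals,expected",
        [((0.9, 0.05, 0.02), 1), ((0.9, 0.4, 0.02), 2), ((0.1, 0.05, 0.02), 1)],
    )
    def test_band_rule(self, pacf_vals, expected):
        assert select_order(np.array(pacf_vals), series_length=100) == expected

    def test_sign_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(-0.9, 0.9, size=6)
        for _ in range(10):
            signs = rng.choice([-1.0, 1.0], size=6)
            assert select_order(vals * signs, 80) == select_order(np.abs(vals), 80)

    def test_max_order_cap(self):
        vals = np.array([0.9, 0.8, 0.7, 0.6])
        assert select_order(vals, 100, max_order=2) == 2


class TestFitAR:
    def test_noiseless_recursion_recovered_exactly(self):
        series = 0.5 ** np.arange(20)  # x_y = 0.5 x_{y-1}, x_1 = 1
        model = fit_ar(series, 1)
        assert model.betas[0] == pytest.approx(0.5, abs=1e-8)
        assert model.beta0 == pytest.approx(0.0, abs=1e-8)
        fc, _ = forecast_ar(model, series)
        assert fc[0] == pytest.approx(series[-1] * 0.5, abs=1e-8)

    def test_constant_series_is_fixed_point(self):
        series = np.full(20, 4.2)
        model = fit_ar(series, 2)
        assert model.degenerate
        fc, _ = forecast_ar(model, series)
        assert fc[0] == pytest.approx(4.2, abs=1e-12)

    def test_ar1_simulation_recovery(self):
        series = _ar1(1.0, 0.8, 0.1, 200, seed=13, x0=5.0)
        model = fit_ar(series, 1)
        assert 0.7 <= model.betas[0] <= 0.9

    def test_residual_mean_zero_with_intercept(self):
        series = _ar1(0.5, 0.6, 0.3, 150, seed=3)
        model = fit_ar(series, 2)
        design_resid_mean = np.mean(
            series[2:]
            - (model.beta0 + model.betas[0] * series[1:-1] + model.betas[1] * series[:-2])
        )
        assert abs(design_resid_mean) < 1e-8

    def test_cross_check_against_statsmodels_autoreg(self):
        """Conditional-least-squares fit agrees with the established
        AutoReg implementation on a stochastic series."""
        from statsmodels.tsa.ar_model import AutoReg

        series = _ar1(1.0, 0.7, 0.2, 120, seed=9, x0=3.0)
        model = fit_ar(series, 2)
        ref = AutoReg(series, lags=2, trend="c").fit()
        assert model.beta0 == pytest.approx(ref.params[0], abs=1e-8)
        assert np.allclose(model.betas, ref.params[1:], atol=1e-8)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_ar(np.arange(5.0), 2)


class TestForecast:
    def test_direct_substitution(self):
        from tdcal.trend import ARModel

        model = ARModel(order=1, beta0=0.0, betas=np.array([0.5]), residual_sd=0.0, n_obs=10)
        fc, clipped = forecast_ar(model, np.array([1.0, 0.25]))
        assert fc[0] == pytest.approx(0.125)
        assert not clipped

    def test_clipped_into_bounds_and_flagged(self):
        from tdcal.trend import ARModel

        spec = ParameterSpec("rue", 1.4, 1.85, "g dm/mj")
        model = ARModel(order=1, beta0=1.0, betas=np.array([1.0]), residual_sd=0.0, n_obs=10)
        fc, clipped = forecast_ar(model, np.array([1.8]), bounds=spec)
        assert fc[0] == 1.85
        assert clipped

    def test_multi_step_recursion(self):
        from tdcal.trend import ARModel

        model = ARModel(order=1, beta0=0.0, betas=np.array([0.5]), residual_sd=0.0, n_obs=10)
        fc, _ = forecast_ar(model, np.array([1.0]), horizon=3)
        assert np.allclose(fc, [0.5, 0.25, 0.125])


class TestADF:
    def test_random_walk_fails_to_reject(self):
        rng = np.random.default_rng(21)
        walk = np.cumsum(rng.normal(size=300))
        _, pvalue, degenerate = adf_test(walk)
        assert not degenerate
        assert pvalue > 0.05

    def test_stationary_series_rejects(self):
        series = _ar1(0.0, 0.2, 1.0, 300, seed=8)
        _, pvalue, _ = adf_test(series)
        assert pvalue < 0.05

    def test_constant_series_degenerate(self):
        stat, pvalue, degenerate = adf_test(np.full(30, 1.0))
        assert degenerate and stat is None and pvalue is None

    def test_diagnostic_never_gates_the_fit(self):
        """A trending series (unit root not rejected) still gets an AR fit."""
        series = np.arange(1.0, 41.0) + _ar1(0.0, 0.3, 0.5, 40, seed=2)
        model, diag = fit_trend_model(series)
        assert model.order >= 1
        assert diag.adf_pvalue is not None


class TestFitTrendModel:
    def test_pipeline_selects_and_forecasts(self):
        series = _ar1(2.0, 0.6, 0.2, 60, seed=17, x0=5.0)
        model, diag = fit_trend_model(series)
        assert diag.selected_order == model.order
        assert np.all(np.abs(diag.pacf) <= 1.0)
        fc, _ = forecast_ar(model, series)
        assert np.isfinite(fc[0])

    def test_serialization_round_trip(self):
        series = _ar1(1.0, 0.5, 0.3, 40, seed=1)
        model, diag = fit_trend_model(series)
        d = model.to_dict()
        assert d["order"] == model.order and len(d["betas"]) == model.order
        assert set(diag.to_dict()) == {
            "pacf", "selected_order", "adf_statistic", "adf_pvalue", "degenerate",
        }


def test_linear_trend_fallback_recovers_slope():
    series = 2.0 + 0.3 * np.arange(1, 31)
    fit = fit_linear_trend(series)
    assert fit.slope == pytest.approx(0.3, abs=1e-10)
    assert fit.residual_sd < 1e-10
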