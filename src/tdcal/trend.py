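"""Autoregressive trend models for yearly parameter series.

Each calibrated parameter has one value per training year; the series
is modeled as AR(t),

    P_y = beta0 + sum_{i=1}^{t} beta_i * P_{y-i} + eps_y,

with the order t chosen from the partial autocorrelation function
(largest lag whose PACF exceeds the 95% significance band) and the
coefficients fitted by conditional least squares.  The Augmented
Dickey-Fuller unit-root test is reported as a diagnostic of trend
autocorrelation; it never gates the AR fit.  One-step forecasts give
the test-year parameter value, clipped into the parameter's
physiological bounds when those are supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.tsa.stattools import adfuller, pacf

from .params import ParameterSpec

__all__ = [
    "ARModel",
    "TrendDiagnostics",
    "compute_pacf",
    "select_order",
    "fit_ar",
    "forecast_ar",
    "adf_test",
    "fit_trend_model",
    "fit_linear_trend",
]

_CONST_TOL = 1e-12


@dataclass
class ARModel:
    """Fitted autoregression of order ``t``.

    ``betas`` holds beta_1..beta_t; ``degenerate`` flags a series whose
    lagged design was singular (e.g. constant), in which case the model
    collapses to an intercept-only fit.
    """

    order: int
    beta0: float
    betas: np.ndarray
    residual_sd: float
    n_obs: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "order": int(self.order),
            "beta0": float(self.beta0),
            "betas": [float(b) for b in self.betas],
            "residual_sd": float(self.residual_sd),
            "n_obs": int(self.n_obs),
            "degenerate": bool(self.degenerate),
        }


@dataclass
class TrendDiagnostics:
    """PACF, selected order and unit-root diagnostics for one series."""

    pacf: np.ndarray
    selected_order: int
    adf_statistic: float | None
    adf_pvalue: float | None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "pacf": [float(v) for v in self.pacf],
            "selected_order": int(self.selected_order),
            "adf_statistic": None if self.adf_statistic is None else float(self.adf_statistic),
            "adf_pvalue": None if self.adf_pvalue is None else float(self.adf_pvalue),
            "degenerate": bool(self.degenerate),
        }


def _is_constant(series: np.ndarray) -> bool:
    return float(np.ptp(series)) <= _CONST_TOL * max(1.0, float(np.max(np.abs(series))))


def compute_pacf(series: np.ndarray, max_lag: int) -> tuple[np.ndarray, bool]:
    """Partial autocorrelations at lags 1..max_lag.

    Uses the sequential-regression definition: the PACF at lag k is
    the lag-k coefficient of an order-k autoregression.  A constant
    series has undefined correlations; it yields zeros and a
    degenerate flag.

    Returns
    -------
    (pacf_values, degenerate)
    """
    series = np.asarray(series, dtype=float)
    if series.size <= max_lag + 1:
        raise ValueError(f"series length {series.size} must exceed max_lag + 1 = {max_lag + 1}")
    if _is_constant(series):
        return np.zeros(max_lag), True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vals = pacf(series, nlags=max_lag, method="ols")
    out = np.clip(np.asarray(vals[1:], dtype=float), -1.0, 1.0)
    return out, False


def select_order(pacf_values: np.ndarray, series_length: int, max_order: int | None = None) -> int:
    """AR order from the PACF: the largest lag whose partial
    autocorrelation exceeds the 95% band ``1.96 / sqrt(length)``;
    falls back to 1 when no lag is significant."""
    pacf_values = np.asarray(pacf_values, dtype=float)
    if max_order is None:
        max_order = len(pacf_values)
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    band = 1.96 / np.sqrt(series_length)
    significant = [
        k + 1 for k in range(min(max_order, len(pacf_values))) if abs(pacf_values[k]) > band
    ]
    return max(significant) if significant else 1


def fit_ar(series: np.ndarray, order: int) -> ARModel:
    """Fit AR(order) by conditional least squares (OLS on the lagged
    design over observations order+1..Y).  A singular design — a
    constant series, for example — degrades to an intercept-only
    model, flagged ``degenerate``."""
    series = np.asarray(series, dtype=float)
    Y = series.size
    if order < 0:
        raise ValueError("order must be non-negative")
    if Y < 2 * order + 2:
        raise ValueError(f"series length {Y} too short for AR({order}); need >= {2 * order + 2}")

    if order == 0 or _is_constant(series):
        resid = series - np.mean(series)
        return ARModel(
            order=0, beta0=float(np.mean(series)), betas=np.zeros(0),
            residual_sd=float(np.std(resid)), n_obs=Y, degenerate=_is_constant(series) and order > 0,
        )

    target = series[order:]
    design = np.column_stack(
        [np.ones(Y - order)] + [series[order - i : Y - i] for i in range(1, order + 1)]
    )
    coef, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < design.shape[1]:
        resid = series - np.mean(series)
        return ARModel(
            order=0, beta0=float(np.mean(series)), betas=np.zeros(0),
            residual_sd=float(np.std(resid)), n_obs=Y, degenerate=True,
        )
    resid = target - design @ coef
    return ARModel(
        order=order, beta0=float(coef[0]), betas=np.asarray(coef[1:], dtype=float),
        residual_sd=float(np.std(resid)), n_obs=Y,
    )


def forecast_ar(
    model: ARModel,
    series: np.ndarray,
    horizon: int = 1,
    bounds: ParameterSpec | None = None,
) -> tuple[np.ndarray, bool]:
    """Forecast ``horizon`` steps ahead by recursive substitution.

    Returns the forecasts and a flag marking whether any step had to
    be clipped into the parameter bounds.
    """
    series = np.asarray(series, dtype=float)
    if series.size < model.order:
        raise ValueError("series shorter than the model order")
    history = list(series)
    out = []
    clipped = False
    for _ in range(horizon):
        value = model.beta0
        for i, beta in enumerate(model.betas, start=1):
            value += beta * history[-i]
        if bounds is not None:
            bounded = bounds.clip(value)
            clipped = bool(clipped or bounded != value)
            value = bounded
        out.append(value)
        history.append(value)
    return np.asarray(out), clipped


def adf_test(series: np.ndarray) -> tuple[float | None, float | None, bool]:
    """Augmented Dickey-Fuller unit-root test (constant term,
    augmentation lags chosen by AIC up to ``(length - 1) // 3``).

    Purely diagnostic: callers fit the AR model regardless of the
    outcome.  Returns ``(statistic, pvalue, degenerate)``; a constant
    series yields ``(None, None, True)``.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 10:
        raise ValueError("ADF test needs at least 10 observations")
    if _is_constant(series):
        return None, None, True
    maxlag = max(1, (series.size - 1) // 3)
    # adfuller requires maxlag < nobs/2 - 2 for the regression to be estimable
    maxlag = min(maxlag, series.size // 2 - 3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, pvalue, *_ = adfuller(series, maxlag=maxlag, regression="c", autolag="AIC")
    return float(stat), float(pvalue), False


def fit_trend_model(
    series: np.ndarray,
    max_order: int | None = None,
) -> tuple[ARModel, TrendDiagnostics]:
    """PACF -> order selection -> AR fit -> ADF diagnostic, end to end.

    ``max_order`` defaults to ``min(5, Y // 6)`` (at least 1) so that
    short calibration series cannot be over-parameterized.
    """
    series = np.asarray(series, dtype=float)
    Y = series.size
    if max_order is None:
        max_order = max(1, min(5, Y // 6))
    max_order = min(max_order, (Y - 2) // 2, Y - 2)
    pacf_vals, degenerate = compute_pacf(series, max_lag=max_order)
    order = 1 if degenerate else select_order(pacf_vals, Y, max_order)
    model = fit_ar(series, order)
    if degenerate:
        adf_stat, adf_p, _ = None, None, True
    else:
        adf_stat, adf_p, adf_degen = adf_test(series) if Y >= 10 else (None, None, False)
        degenerate = degenerate or adf_degen
    diag = TrendDiagnostics(
        pacf=pacf_vals, selected_order=model.order,
        adf_statistic=adf_stat, adf_pvalue=adf_p, degenerate=degenerate,
    )
    return model, diag


@dataclass
class LinearTrend:
    """Straight-line alternative trend fitter: value = a + b * year."""

    intercept: float
    slope: float
    residual_sd: float


def fit_linear_trend(series: np.ndarray) -> LinearTrend:
    """Least-squares line through (year index, value); the simple
    alternative when a parameter's trajectory is believed linear."""
    series = np.asarray(series, dtype=float)
    years = np.arange(1, series.size + 1, dtype=float)
    slope, intercept = np.polyfit(years, series, 1)
    resid = series - (intercept + slope * years)
    return LinearTrend(intercept=float(intercept), slope=float(slope), residual_sd=float(np.std(resid)))
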