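"""End-to-end time-dependent calibration pipeline.

For each location the pipeline calibrates every time-window of the
window scheme against the county observed-yield series with parallel
Bayesian optimization, combines per-window estimates into per-year
parameter vectors, fits an autoregressive trend per parameter, and
forecasts the test-year parameter values; county-level predictions
are the median over the county's locations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .metrics import evaluate_all
from .params import ParameterSpace, default_parameter_space
from .pbo import PBOConfig, PBOTrace, run_pbo
from .toycrop import Environment, growth_multiplier, yield_response
from .trend import ARModel, TrendDiagnostics, fit_trend_model, forecast_ar
from .windows import (
    TimeWindow,
    WindowEstimate,
    WindowingConfig,
    WindowSet,
    YearlyParameterSeries,
    build_windows,
    combine_yearly,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CropModelInterface",
    "ToyCropModel",
    "CalibrationResult",
    "window_objective",
    "calibrate",
    "predict_test_year",
]


class CropModelInterface(Protocol):
    """Contract for a pluggable crop model.

    Implementations must be deterministic for fixed inputs within one
    calibration run.  An adapter for an external process-based
    simulator satisfies this protocol by templating its input files
    from ``(theta, env, year_index)`` and parsing simulated yield from
    its output.
    """

    name: str

    def __call__(self, theta: np.ndarray, env: Environment, year_index: int) -> float:
        """Simulated yield in kg/ha."""
        ...


@dataclass(frozen=True)
class ToyCropModel:
    """The built-in synthetic crop model (see :mod:`tdcal.toycrop`)."""

    space: ParameterSpace
    name: str = "toycrop"

    def __call__(self, theta: np.ndarray, env: Environment, year_index: int) -> float:
        return yield_response(theta, env, year_index, self.space)


def window_objective(
    model: CropModelInterface,
    env: Environment,
    observed: Mapping[int, float],
    window: TimeWindow,
) -> Callable[[np.ndarray], float]:
    """Loss for one (location, window): RMSE between the model's
    yields and the county observed yields over the window's years,
    with the candidate parameter vector held constant across them.

    ``observed`` maps training-year index -> observed county yield.
    """
    years = range(window.start_year, window.end_year + 1)
    missing = [y for y in years if y not in observed]
    if missing:
        raise ValueError(f"observed yields missing for year indices {missing} in window {window.index}")
    obs = np.array([observed[y] for y in years], dtype=float)

    def objective(theta: np.ndarray) -> float:
        sim = np.array([model(theta, env, y) for y in years])
        return float(np.sqrt(np.mean((sim - obs) ** 2)))

    return objective


@dataclass
class CalibrationResult:
    """Everything the calibration produced, keyed by location."""

    space: ParameterSpace
    windowing: WindowingConfig
    window_set: WindowSet
    estimates: dict[str, list[WindowEstimate]]
    yearly: dict[str, YearlyParameterSeries]
    trend: dict[str, dict[str, tuple[ARModel, TrendDiagnostics]]]
    forecasts: dict[str, dict[str, float]]
    clipped: dict[str, dict[str, bool]]
    county_of: dict[str, str]
    seed: int = 0

    @property
    def locations(self) -> tuple[str, ...]:
        return tuple(self.estimates)

    def yearly_frame(self) -> pd.DataFrame:
        """Long table: location, calendar year, one column per parameter."""
        frames = []
        for loc, series in self.yearly.items():
            f = series.to_frame()
            f.insert(0, "location", loc)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def mean_g_series(self) -> np.ndarray:
        """Growth multiplier G of the recovered yearly parameters,
        averaged over locations (toy-crop recovery diagnostic)."""
        g = []
        for series in self.yearly.values():
            vals = series.values[list(self.space.names)].to_numpy()
            g.append([growth_multiplier(row, self.space) for row in vals])
        return np.mean(np.array(g), axis=0)

    def estimates_frame(self) -> pd.DataFrame:
        """Per-window calibrated parameters and achieved RMSE."""
        rows = []
        for loc, ests in self.estimates.items():
            for est in ests:
                row = {
                    "location": loc,
                    "window_index": est.window.index,
                    "kind": est.window.kind.value,
                    "objective_rmse_kg_ha": est.objective,
                }
                row.update(est.values)
                rows.append(row)
        return pd.DataFrame(rows)

    def trend_json(self) -> dict:
        out: dict = {}
        for loc, per_param in self.trend.items():
            out[loc] = {}
            for name, (model, diag) in per_param.items():
                out[loc][name] = {
                    "ar": model.to_dict(),
                    "diagnostics": diag.to_dict(),
                    "forecast": self.forecasts[loc][name],
                    "clipped": self.clipped[loc][name],
                }
        return out

    def save(self, directory) -> None:
        """Write windows.csv, window_estimates.csv,
        yearly_parameters.csv and ar_models.json."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.window_set.to_csv(directory / "windows.csv")
        self.estimates_frame().to_csv(directory / "window_estimates.csv", index=False)
        self.yearly_frame().to_csv(directory / "yearly_parameters.csv", index=False)
        with open(directory / "ar_models.json", "w") as fh:
            json.dump(self.trend_json(), fh, indent=2)


def _window_seed(master: int, loc_index: int, window_ordinal: int, attempt: int = 0) -> int:
    state = np.random.SeedSequence([master, loc_index, window_ordinal, attempt]).generate_state(1)
    return int(state[0] % (2**31))


def calibrate(
    observed: pd.DataFrame,
    environments: Sequence[Environment],
    model: CropModelInterface,
    windowing: WindowingConfig,
    pbo_config: PBOConfig,
    space: ParameterSpace | None = None,
    locations: Sequence[str] | None = None,
    max_order: int | None = None,
    seed: int = 0,
) -> CalibrationResult:
    """Run the full calibration over every (location, window) pair.

    ``observed`` must have columns county, year (calendar),
    yield_kg_ha and cover training years 1..Y for every county
    represented in ``environments``.  ``pbo_config`` is a template:
    its instances and budget are reused for every window while the
    seed is re-derived per (location, window) from ``seed``.
    ``locations`` restricts calibration to a subset of location ids.

    A window whose optimization fails is retried once with a shifted
    seed; a second failure aborts with the window identified.
    """
    space = space or default_parameter_space()
    window_set = build_windows(windowing)
    envs = {e.location: e for e in environments}
    if locations is None:
        locations = tuple(envs)
    else:
        unknown = set(locations) - set(envs)
        if unknown:
            raise ValueError(f"unknown locations: {sorted(unknown)}")

    obs_by_county: dict[str, dict[int, float]] = {}
    for county, group in observed.groupby("county"):
        obs_by_county[county] = {
            windowing.from_calendar(int(r.year)): float(r.yield_kg_ha)
            for r in group.itertuples()
        }

    estimates: dict[str, list[WindowEstimate]] = {}
    yearly: dict[str, YearlyParameterSeries] = {}
    trend: dict[str, dict[str, tuple[ARModel, TrendDiagnostics]]] = {}
    forecasts: dict[str, dict[str, float]] = {}
    clipped: dict[str, dict[str, bool]] = {}
    county_of: dict[str, str] = {}

    for li, loc in enumerate(locations):
        env = envs[loc]
        county_of[loc] = env.county
        county_obs = obs_by_county[env.county]
        loc_estimates: list[WindowEstimate] = []
        for wi, window in enumerate(window_set):
            objective = window_objective(model, env, county_obs, window)
            trace = _run_window(objective, space, pbo_config, seed, li, wi, window)
            loc_estimates.append(
                WindowEstimate(
                    window=window,
                    values=space.to_dict(trace.best_x),
                    objective=trace.best_f,
                )
            )
        estimates[loc] = loc_estimates
        series = combine_yearly(loc_estimates, windowing)
        yearly[loc] = series

        trend[loc] = {}
        forecasts[loc] = {}
        clipped[loc] = {}
        for name in space.names:
            values = series.values[name].to_numpy()
            ar_model, diag = fit_trend_model(values, max_order=max_order)
            fc, was_clipped = forecast_ar(ar_model, values, horizon=1, bounds=space[name])
            trend[loc][name] = (ar_model, diag)
            forecasts[loc][name] = float(fc[0])
            clipped[loc][name] = was_clipped

    return CalibrationResult(
        space=space, windowing=windowing, window_set=window_set,
        estimates=estimates, yearly=yearly, trend=trend,
        forecasts=forecasts, clipped=clipped, county_of=county_of, seed=seed,
    )


def _run_window(objective, space, pbo_config, seed, li, wi, window) -> PBOTrace:
    for attempt in range(2):
        cfg = PBOConfig(
            instances=pbo_config.instances,
            T=pbo_config.T,
            init_design_size=pbo_config.init_design_size,
            restarts=pbo_config.restarts,
            improvement_threshold=pbo_config.improvement_threshold,
            seed=_window_seed(seed, li, wi, attempt),
        )
        try:
            return run_pbo(objective, space.bounds, cfg)
        except Exception:
            if attempt == 0:
                logger.warning(
                    "optimization failed on window %s (%s); retrying with shifted seed",
                    window.index, window.kind.value,
                )
                continue
            raise RuntimeError(
                f"optimization failed twice on window {window.index} ({window.kind.value})"
            )


def predict_test_year(
    result: CalibrationResult,
    model: CropModelInterface,
    environments: Sequence[Environment],
    test_year_index: int | None = None,
) -> pd.DataFrame:
    """Simulate the test year with the forecast parameter vectors.

    Each calibrated location is simulated with its own forecast
    parameters; the county prediction is the median over its
    locations (robust to outlier locations).  Returns a frame with
    columns county, location, prediction plus per-county rows where
    location is NaN and prediction is the county median.
    """
    if test_year_index is None:
        test_year_index = result.windowing.Y + 1
    envs = {e.location: e for e in environments}
    rows = []
    for loc in result.locations:
        theta = result.space.to_array(result.forecasts[loc])
        pred = model(theta, envs[loc], test_year_index)
        rows.append({"county": result.county_of[loc], "location": loc, "prediction": float(pred)})
    frame = pd.DataFrame(rows)
    county = (
        frame.groupby("county")["prediction"].median().reset_index().assign(location=np.nan)
    )
    return pd.concat([frame, county[["county", "location", "prediction"]]], ignore_index=True)


def county_predictions(frame: pd.DataFrame) -> pd.Series:
    """County-median predictions from a :func:`predict_test_year` frame."""
    return frame[frame["location"].isna()].set_index("county")["prediction"]


def evaluate_predictions(pred: pd.Series, obs: pd.Series) -> dict[str, float]:
    """RMSE / RRMSE / R^2 on aligned county series."""
    joined = pd.concat([pred.rename("pred"), obs.rename("obs")], axis=1).dropna()
    return evaluate_all(joined["pred"].to_numpy(), joined["obs"].to_numpy())
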