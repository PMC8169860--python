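"""Yield-prediction evaluation criteria: RMSE, RRMSE and R^2."""

from __future__ import annotations

import numpy as np

__all__ = ["rmse", "rrmse", "r2", "evaluate_all"]


def _check(pred, obs) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: pred {pred.shape} vs obs {obs.shape}")
    if pred.size == 0:
        raise ValueError("empty inputs")
    return pred, obs


def rmse(pred, obs) -> float:
    """Root mean square error, in the units of the inputs (kg/ha)."""
    pred, obs = _check(pred, obs)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def rrmse(pred, obs) -> float:
    """Relative RMSE, percent of the mean observed value."""
    pred, obs = _check(pred, obs)
    mean_obs = float(np.mean(obs))
    if mean_obs == 0:
        raise ValueError("mean of observations is zero; RRMSE undefined")
    return 100.0 * rmse(pred, obs) / mean_obs


def r2(pred, obs) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    May be negative when predictions are worse than the observed
    mean.  Raises on zero-variance observations, for which R^2 is
    undefined.
    """
    pred, obs = _check(pred, obs)
    ss_tot = float(np.sum((obs - np.mean(obs)) ** 2))
    if ss_tot == 0:
        raise ValueError("observations have zero variance; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def evaluate_all(pred, obs) -> dict[str, float]:
    """All three criteria in one dict (keys: rmse, rrmse, r2)."""
    return {"rmse": rmse(pred, obs), "rrmse": rrmse(pred, obs), "r2": r2(pred, obs)}
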