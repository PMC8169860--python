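"""A synthetic county/location crop simulator with known ground truth.

Stands in for a full process-based crop model during development and
testing of the calibration framework.  It emulates the shape of a US
Corn Belt county study — 5 counties, 5 soil-distinct locations per
county, 34 years of county-level observed maize yields rising roughly
1.5-fold — while exposing the true time-varying cultivar parameters,
so parameter-recovery can be measured exactly.

The yield response is deliberately simple and deliberately
equifinal: yield depends on the parameter vector only through a
scalar growth multiplier

    G(theta) = 1 + sum_j w_j (u_j - 0.5),

where u_j is the bound-scaled parameter in [0, 1] and the fixed
weights w_j sum to 1 in absolute value.  Any two parameter vectors
with equal G give identical yields, so recovery is assessed on
G(theta), never on individual components — the same identifiability
ceiling a real crop model imposes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .params import ParameterSpace, default_parameter_space

__all__ = [
    "RESPONSE_WEIGHTS",
    "Environment",
    "SyntheticTruth",
    "growth_multiplier",
    "yield_response",
    "true_trajectory",
    "generate_dataset",
]

#: Sensitivity of the growth multiplier to each bound-scaled
#: parameter.  Signs follow the direction each trait has drifted under
#: decades of maize breeding: radiation use efficiency, grain number
#: and grain growth rate upward; vegetative-phase thermal time, leaf
#: appearance interval and flowering-to-grain-fill interval downward;
#: grain N concentration and transpiration efficiency flat.
RESPONSE_WEIGHTS: Mapping[str, float] = {
    "rue": 0.30,
    "head_grain_no_max": 0.20,
    "grain_gth_rate": 0.20,
    "tt_flower_to_maturity": 0.15,
    "tt_emerg_to_endjuv": -0.05,
    "tt_flower_to_start_grain": -0.05,
    "leaf_app_rate1": -0.05,
    "n_conc_crit_grain": 0.0,
    "transp_eff_cf": 0.0,
}


@dataclass(frozen=True)
class Environment:
    """One simulated location: a soil within a county."""

    county: str
    location: str
    base_potential: float            # county yield potential, kg/ha
    soil_factor: float               # multiplicative soil productivity
    season_anomaly: np.ndarray       # per-year multiplicative deviation (county-wide)

    def __post_init__(self) -> None:
        if self.base_potential <= 0:
            raise ValueError("base_potential must be positive")

    def anomaly(self, year_index: int) -> float:
        if not 1 <= year_index <= self.season_anomaly.size:
            raise ValueError(f"no season anomaly for year index {year_index}")
        return float(self.season_anomaly[year_index - 1])

    def to_dict(self) -> dict:
        return {
            "county": self.county,
            "location": self.location,
            "base_potential": float(self.base_potential),
            "soil_factor": float(self.soil_factor),
            "season_anomaly": [float(a) for a in self.season_anomaly],
        }


@dataclass(frozen=True)
class SyntheticTruth:
    """The generating process: true yearly parameters and noise level."""

    space: ParameterSpace
    theta: np.ndarray          # (Y, d) true parameter vectors, original units
    slopes: np.ndarray         # (d,) per-year linear slope of each parameter
    noise_sd: float            # observation noise, kg/ha
    seed: int

    @property
    def n_years(self) -> int:
        return self.theta.shape[0]

    def theta_at(self, year_index: int) -> np.ndarray:
        return self.theta[year_index - 1]

    def g_series(self) -> np.ndarray:
        """True growth multiplier G(theta*(y)) for y = 1..Y."""
        return np.array([growth_multiplier(t, self.space) for t in self.theta])

    def to_dict(self) -> dict:
        return {
            "parameters": list(self.space.names),
            "theta": self.theta.tolist(),
            "slopes": self.slopes.tolist(),
            "noise_sd": float(self.noise_sd),
            "seed": int(self.seed),
        }


def growth_multiplier(theta: np.ndarray, space: ParameterSpace | None = None) -> float:
    """G(theta) = 1 + sum_j w_j (u_j - 0.5) on bound-scaled inputs.

    Ranges over [0.5, 1.5] because the absolute weights sum to 1.
    """
    space = space or default_parameter_space()
    u = space.scale(np.asarray(theta, dtype=float))
    w = np.array([RESPONSE_WEIGHTS[name] for name in space.names])
    return float(1.0 + np.sum(w * (u - 0.5)))


def yield_response(
    theta: np.ndarray,
    env: Environment,
    year_index: int,
    space: ParameterSpace | None = None,
) -> float:
    """Noiseless simulated yield (kg/ha) for one location-year.

    yield = base_potential * soil_factor * G(theta) * (1 + anomaly).
    """
    space = space or default_parameter_space()
    theta = np.asarray(theta, dtype=float)
    if not space.contains(theta):
        raise ValueError("theta outside parameter bounds")
    g = growth_multiplier(theta, space)
    return env.base_potential * env.soil_factor * g * (1.0 + env.anomaly(year_index))


def true_trajectory(
    n_years: int,
    seed: int = 0,
    space: ParameterSpace | None = None,
) -> SyntheticTruth:
    """Linearly drifting true parameters over ``n_years``.

    Parameters with a positive response weight move (bound-scaled)
    from 0.3 to 0.7 across the period, negative-weight parameters from
    0.7 to 0.3, and zero-weight parameters stay at 0.5.  The true
    growth multiplier therefore rises linearly from 0.8 to 1.2 — a
    1.5-fold yield ratio over the period, matching the magnitude of
    the historical US Corn Belt maize increase.
    """
    if n_years < 2:
        raise ValueError("need at least 2 years")
    space = space or default_parameter_space()
    d = len(space)
    frac = np.linspace(0.0, 1.0, n_years)
    u = np.empty((n_years, d))
    slopes = np.empty(d)
    widths = space.bounds[:, 1] - space.bounds[:, 0]
    for j, name in enumerate(space.names):
        w = RESPONSE_WEIGHTS[name]
        if w > 0:
            u[:, j] = 0.3 + 0.4 * frac
        elif w < 0:
            u[:, j] = 0.7 - 0.4 * frac
        else:
            u[:, j] = 0.5
        slopes[j] = (u[-1, j] - u[0, j]) / (n_years - 1) * widths[j]
    theta = np.array([space.unscale(row) for row in u])
    return SyntheticTruth(space=space, theta=theta, slopes=slopes, noise_sd=0.0, seed=seed)


def generate_dataset(
    n_counties: int = 5,
    n_soils: int = 5,
    n_years: int = 34,
    noise_sd: float = 250.0,
    seed: int = 0,
    first_year: int = 1985,
    space: ParameterSpace | None = None,
) -> tuple[pd.DataFrame, list[Environment], SyntheticTruth]:
    """Generate a county-level observed-yield dataset with ground truth.

    County yield potential is Uniform(9000, 11000) kg/ha, each
    location's soil factor Uniform(0.85, 1.10), and each county-year
    gets a Normal(0, 0.08) multiplicative season anomaly shared by its
    locations.  Observed county yield is the mean over the county's
    locations of the noiseless response plus Normal(0, noise_sd) kg/ha
    measurement noise.  Anomalies are drawn for ``n_years + 1`` years
    so a held-out test year can be simulated; observations cover the
    training years only.

    Returns ``(observed, environments, truth)`` where ``observed`` has
    columns county, year (calendar), yield_kg_ha.
    """
    if min(n_counties, n_soils, n_years) < 1:
        raise ValueError("counties, soils and years must all be >= 1")
    space = space or default_parameter_space()
    rng = np.random.default_rng(seed)
    truth = true_trajectory(max(n_years, 2), seed=seed, space=space)

    environments: list[Environment] = []
    for c in range(n_counties):
        county = f"county_{c + 1}"
        base = rng.uniform(9000.0, 11000.0)
        anomalies = rng.normal(0.0, 0.08, size=n_years + 1)
        for k in range(n_soils):
            environments.append(
                Environment(
                    county=county,
                    location=f"{county}_loc_{k + 1}",
                    base_potential=base,
                    soil_factor=float(rng.uniform(0.85, 1.10)),
                    season_anomaly=anomalies,
                )
            )

    rows = []
    for c in range(n_counties):
        county = f"county_{c + 1}"
        envs = [e for e in environments if e.county == county]
        for y in range(1, n_years + 1):
            clean = float(
                np.mean([yield_response(truth.theta_at(y), e, y, space) for e in envs])
            )
            obs = clean + rng.normal(0.0, noise_sd) if noise_sd > 0 else clean
            rows.append({"county": county, "year": first_year + y - 1, "yield_kg_ha": obs})

    observed = pd.DataFrame(rows)
    truth = SyntheticTruth(
        space=space, theta=truth.theta, slopes=truth.slopes, noise_sd=noise_sd, seed=seed
    )
    return observed, environments, truth


def save_environments(environments: list[Environment], path) -> None:
    with open(path, "w") as fh:
        json.dump([e.to_dict() for e in environments], fh, indent=2)


def load_environments(path) -> list[Environment]:
    with open(path) as fh:
        raw = json.load(fh)
    return [
        Environment(
            county=r["county"],
            location=r["location"],
            base_potential=r["base_potential"],
            soil_factor=r["soil_factor"],
            season_anomaly=np.asarray(r["season_anomaly"], dtype=float),
        )
        for r in raw
    ]
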