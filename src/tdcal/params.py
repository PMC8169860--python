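"""Cultivar parameter space: named, bounded crop-model parameters.

The default space is the nine APSIM-maize cultivar parameters commonly
calibrated in US Corn Belt yield studies — thermal-time durations of
phenological phases, grain number and growth potential, radiation and
transpiration use efficiency, leaf appearance rate and grain nitrogen
concentration — each with its physiological range and units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["ParameterSpec", "ParameterSpace", "default_parameter_space"]


@dataclass(frozen=True)
class ParameterSpec:
    """A bounded scalar crop-model parameter."""

    name: str
    lower: float
    upper: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower bound {self.lower} must be < upper {self.upper}")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def scale(self, value: float) -> float:
        """Map a value in [lower, upper] to the unit interval."""
        return (value - self.lower) / self.width

    def unscale(self, u: float) -> float:
        return self.lower + u * self.width

    def contains(self, value: float, rtol: float = 1e-9) -> bool:
        pad = rtol * self.width
        return self.lower - pad <= value <= self.upper + pad

    def clip(self, value: float) -> float:
        return float(min(max(value, self.lower), self.upper))


class ParameterSpace:
    """Ordered collection of :class:`ParameterSpec` with array helpers."""

    def __init__(self, specs: Sequence[ParameterSpec]):
        if len({s.name for s in specs}) != len(specs):
            raise ValueError("duplicate parameter names")
        self.specs = tuple(specs)

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def __getitem__(self, name: str) -> ParameterSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    @property
    def bounds(self) -> np.ndarray:
        """(d, 2) array of [lower, upper] per parameter."""
        return np.array([[s.lower, s.upper] for s in self.specs])

    def to_array(self, values: Mapping[str, float]) -> np.ndarray:
        return np.array([float(values[s.name]) for s in self.specs])

    def to_dict(self, x: Iterable[float]) -> dict[str, float]:
        return {s.name: float(v) for s, v in zip(self.specs, x, strict=True)}

    def scale(self, x: np.ndarray) -> np.ndarray:
        """Map parameter vectors (original units) to the unit hypercube."""
        b = self.bounds
        return (np.asarray(x, dtype=float) - b[:, 0]) / (b[:, 1] - b[:, 0])

    def unscale(self, u: np.ndarray) -> np.ndarray:
        b = self.bounds
        return b[:, 0] + np.asarray(u, dtype=float) * (b[:, 1] - b[:, 0])

    def contains(self, x: np.ndarray, rtol: float = 1e-9) -> bool:
        return all(s.contains(v, rtol) for s, v in zip(self.specs, np.asarray(x), strict=True))

    def clip(self, x: np.ndarray) -> np.ndarray:
        b = self.bounds
        return np.clip(np.asarray(x, dtype=float), b[:, 0], b[:, 1])


#: The nine-parameter maize cultivar space with physiological bounds.
_DEFAULT_SPECS = (
    ParameterSpec("tt_emerg_to_endjuv", 150.0, 300.0, "degCd"),
    ParameterSpec("tt_flower_to_maturity", 600.0, 900.0, "degCd"),
    ParameterSpec("head_grain_no_max", 600.0, 850.0, "kernel/ear"),
    ParameterSpec("grain_gth_rate", 5.0, 9.0, "mg/grain/d"),
    ParameterSpec("tt_flower_to_start_grain", 120.0, 200.0, "degCd"),
    ParameterSpec("n_conc_crit_grain", 0.008, 0.016, "g N/g biomass"),
    ParameterSpec("leaf_app_rate1", 50.0, 75.0, "deg day"),
    ParameterSpec("rue", 1.4, 1.85, "g dm/mj"),
    ParameterSpec("transp_eff_cf", 0.075, 0.095, "kpa"),
)


def default_parameter_space() -> ParameterSpace:
    """The nine-parameter maize cultivar space (fresh instance)."""
    return ParameterSpace(_DEFAULT_SPECS)
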