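"""Overlapping time-windows for time-dependent parameter calibration.

A training period of ``Y`` years is covered by main windows of length
``n`` (successive windows overlap by ``n - 1`` years) plus short
auxiliary windows at the head and tail of the period, so that every
year is covered by exactly ``n`` windows.  Per-window parameter
estimates are then combined into a per-year parameter vector by a
length-weighted average over the windows covering that year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WindowingConfig",
    "WindowKind",
    "TimeWindow",
    "WindowSet",
    "WindowEstimate",
    "YearlyParameterSeries",
    "build_windows",
    "covering_windows",
    "yearly_weighted_average",
]


class WindowingError(ValueError):
    """Raised for an ill-formed windowing configuration or year index."""


class WindowKind(str, Enum):
    MAIN = "main"
    AUX_HEAD = "aux_head"
    AUX_TAIL = "aux_tail"


@dataclass(frozen=True)
class WindowingConfig:
    """Window-scheme configuration.

    Parameters
    ----------
    Y : int
        Number of training years.  Must satisfy ``Y >= 2 * n``; for
        smaller ``Y`` the tail auxiliary scheme is ill-formed.
    n : int
        Main-window length in years, ``n >= 2``.
    first_year : int
        Calendar year of training-year index 1 (presentation only;
        all internal indexing is 1-based training-year indices).
    """

    Y: int
    n: int
    first_year: int = 1

    def __post_init__(self) -> None:
        if self.n < 2:
            raise WindowingError(f"main-window length n must be >= 2, got n={self.n}")
        if self.Y < 2 * self.n:
            raise WindowingError(
                f"training period must satisfy Y >= 2n, got Y={self.Y}, n={self.n}"
            )

    def to_calendar(self, year_index: int) -> int:
        return self.first_year + year_index - 1

    def from_calendar(self, calendar_year: int) -> int:
        return calendar_year - self.first_year + 1


@dataclass(frozen=True)
class TimeWindow:
    """A contiguous span of training years, 1-based and inclusive."""

    index: int
    kind: WindowKind
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise WindowingError(
                f"window {self.index}: start_year {self.start_year} > end_year {self.end_year}"
            )

    @property
    def length(self) -> int:
        return self.end_year - self.start_year + 1

    def covers(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year

    @property
    def key(self) -> tuple[str, int]:
        """Hashable identity used to attach estimates to windows."""
        return (self.kind.value, self.index)


@dataclass(frozen=True)
class WindowSet:
    config: WindowingConfig
    windows: tuple[TimeWindow, ...]

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def main_windows(self) -> tuple[TimeWindow, ...]:
        return tuple(w for w in self.windows if w.kind is WindowKind.MAIN)

    @property
    def auxiliary_windows(self) -> tuple[TimeWindow, ...]:
        return tuple(w for w in self.windows if w.kind is not WindowKind.MAIN)

    def to_frame(self) -> pd.DataFrame:
        """Tabulate the window scheme with calendar years."""
        cfg = self.config
        rows = [
            {
                "window_index": w.index,
                "kind": w.kind.value,
                "start_year": cfg.to_calendar(w.start_year),
                "end_year": cfg.to_calendar(w.end_year),
                "length": w.length,
            }
            for w in self.windows
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class WindowEstimate:
    """Calibrated parameter vector for one window.

    ``values`` maps parameter name -> calibrated value; ``objective``
    is the loss achieved by the optimizer on that window (kg/ha RMSE
    for yield calibration).
    """

    window: TimeWindow
    values: Mapping[str, float]
    objective: float = float("nan")


@dataclass
class YearlyParameterSeries:
    """Per-year combined parameter vectors, years 1..Y."""

    config: WindowingConfig
    values: pd.DataFrame = field(default_factory=pd.DataFrame)
    # values: index = training-year 1..Y, columns = parameter names

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, "year", [self.config.to_calendar(y) for y in out.index])
        return out.reset_index(drop=True)


def build_windows(config: WindowingConfig) -> WindowSet:
    """Construct the main and auxiliary windows for ``config``.

    Main windows ``W_i`` cover years ``i .. i+n-1`` for
    ``i = 1 .. Y-n+1``.  Head auxiliaries cover years ``1 .. i-1`` for
    ``i = 2 .. n`` and tail auxiliaries cover years ``i+n .. Y`` for
    ``i = Y-2n+2 .. Y-n``, so every year is covered by exactly ``n``
    windows and auxiliary weights equal window lengths.
    """
    Y, n = config.Y, config.n
    windows: list[TimeWindow] = []
    for i in range(1, Y - n + 2):
        windows.append(TimeWindow(i, WindowKind.MAIN, i, i + n - 1))
    for i in range(2, n + 1):
        windows.append(TimeWindow(i, WindowKind.AUX_HEAD, 1, i - 1))
    for i in range(Y - 2 * n + 2, Y - n + 1):
        windows.append(TimeWindow(i, WindowKind.AUX_TAIL, i + n, Y))
    return WindowSet(config=config, windows=tuple(windows))


def covering_windows(ws: WindowSet, y: int) -> tuple[TimeWindow, ...]:
    """All windows of ``ws`` whose span contains training year ``y``."""
    if not 1 <= y <= ws.config.Y:
        raise WindowingError(f"year index {y} outside 1..{ws.config.Y}")
    return tuple(w for w in ws.windows if w.covers(y))


def _estimate_lookup(
    estimates: Iterable[WindowEstimate],
) -> dict[tuple[str, int], WindowEstimate]:
    return {est.window.key: est for est in estimates}


def yearly_weighted_average(
    estimates: Sequence[WindowEstimate],
    y: int,
    config: WindowingConfig,
) -> dict[str, float]:
    """Combine window estimates into the year-``y`` parameter vector.

    Evaluates the three-branch weighted average: in the interior
    (``n <= y <= Y-n+1``) the unweighted mean of the ``n`` covering
    main windows; near either edge, covering main windows enter with
    weight ``n`` and covering auxiliaries with weight equal to their
    length, normalized to sum to one.
    """
    Y, n = config.Y, config.n
    if not 1 <= y <= Y:
        raise WindowingError(f"year index {y} outside 1..{Y}")
    lookup = _estimate_lookup(estimates)

    def get(kind: WindowKind, i: int) -> Mapping[str, float]:
        est = lookup.get((kind.value, i))
        if est is None:
            raise WindowingError(f"missing estimate for window ({kind.value}, index {i})")
        return est.values

    terms: list[tuple[float, Mapping[str, float]]] = []
    if y < n:
        for i in range(1, y + 1):
            terms.append((float(n), get(WindowKind.MAIN, i)))
        for i in range(y + 1, n + 1):
            terms.append((float(i - 1), get(WindowKind.AUX_HEAD, i)))
    elif y <= Y - n + 1:
        for i in range(y - n + 1, y + 1):
            terms.append((1.0, get(WindowKind.MAIN, i)))
    else:
        for i in range(y - n + 1, Y - n + 2):
            terms.append((float(n), get(WindowKind.MAIN, i)))
        for i in range(Y - 2 * n + 2, y - n + 1):
            terms.append((float(Y - n - i + 1), get(WindowKind.AUX_TAIL, i)))

    total = sum(w for w, _ in terms)
    names = list(terms[0][1].keys())
    out: dict[str, float] = {}
    for name in names:
        out[name] = float(sum(w * vals[name] for w, vals in terms) / total)
    return out


def combine_yearly(
    estimates: Sequence[WindowEstimate], config: WindowingConfig
) -> YearlyParameterSeries:
    """Apply :func:`yearly_weighted_average` to every training year."""
    rows = {y: yearly_weighted_average(estimates, y, config) for y in range(1, config.Y + 1)}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "year_index"
    return YearlyParameterSeries(config=config, values=frame)


def implied_weights(config: WindowingConfig, y: int) -> np.ndarray:
    """Normalized weights over the covering windows of year ``y``.

    Ordered as the covering windows appear in :func:`build_windows`
    output.  Exposed for testing the normalization and symmetry of the
    scheme.
    """
    ws = build_windows(config)
    cover = covering_windows(ws, y)
    w = np.array([float(tw.length) for tw in cover])
    return w / w.sum()
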