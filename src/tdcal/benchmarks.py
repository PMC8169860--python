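"""Published county-level calibration benchmarks for comparison.

Reference RMSE values (kg/ha, 1985-2018 simulation period) reported
for the five-county US Corn Belt maize case study that motivated this
framework, under three calibration strategies: manual expert
calibration, classic Bayesian optimization (BO) and parallel Bayesian
optimization (PBO).  These published numbers are inputs for
head-to-head reporting — the percent error reduction one calibration
strategy achieves over another — not outputs of this package.
"""

from __future__ import annotations

__all__ = ["CASE_STUDY_RMSE", "percent_reduction"]

#: RMSE in kg/ha by method and county over the 1985-2018 period.
CASE_STUDY_RMSE: dict[str, dict[str, float]] = {
    "manual": {
        "Logan": 2386.0, "Greene": 2820.0, "Keokuk": 2612.0, "Boone": 2357.0, "Obrien": 2482.0,
    },
    "bo": {
        "Logan": 1442.0, "Greene": 1520.0, "Keokuk": 1590.0, "Boone": 1288.0, "Obrien": 992.0,
    },
    "pbo": {
        "Logan": 1266.0, "Greene": 1459.0, "Keokuk": 1358.0, "Boone": 1076.0, "Obrien": 865.0,
    },
}


def percent_reduction(baseline: float, improved: float) -> int:
    """Percent RMSE reduction of ``improved`` relative to ``baseline``,
    rounded to the nearest integer (the convention used when reporting
    calibration head-to-heads)."""
    if baseline <= 0:
        raise ValueError("baseline RMSE must be positive")
    return int(round(100.0 * (baseline - improved) / baseline))


def case_study_reductions() -> dict[str, dict[str, int]]:
    """Percent RMSE reduction of PBO over manual and over BO, per county."""
    out: dict[str, dict[str, int]] = {"pbo_vs_manual": {}, "pbo_vs_bo": {}}
    for county, manual in CASE_STUDY_RMSE["manual"].items():
        out["pbo_vs_manual"][county] = percent_reduction(manual, CASE_STUDY_RMSE["pbo"][county])
    for county, bo in CASE_STUDY_RMSE["bo"].items():
        out["pbo_vs_bo"][county] = percent_reduction(bo, CASE_STUDY_RMSE["pbo"][county])
    return out
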