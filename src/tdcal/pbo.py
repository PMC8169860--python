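"""Parallel Bayesian optimization (PBO) with a shared evaluation pool.

``N`` heterogeneous Bayesian-optimization instances — each with its
own acquisition function, kernel family and hyperparameters — propose
one point per iteration.  All proposals are evaluated and appended to
a single shared history, so at the next iteration every instance
refits its surrogate on everything any instance has learned.  A
single-instance loop (classic BO) is provided as the comparison
baseline; it is literally PBO with ``N = 1``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .surrogate import (
    DEDUP_TOL,
    AcquisitionSpec,
    EvaluationRecord,
    GPPosterior,
    KernelSpec,
    acquisition_value,
    fit_gp,
    latin_hypercube,
    propose_next,
)

logger = logging.getLogger(__name__)

__all__ = ["PBOConfig", "PBOTrace", "run_pbo", "run_bo", "default_instances"]


def default_instances(n: int = 6) -> tuple[tuple[AcquisitionSpec, KernelSpec], ...]:
    """Default heterogeneous roster: {EI, PI, LCB} x {Matern-5/2, RBF}.

    For ``n`` below 6 the roster is truncated in the listed order, so
    ``n = 3`` gives the three acquisition families on Matern-5/2.
    """
    roster = []
    for family in ("matern52", "rbf"):
        for acq in ("ei", "pi", "lcb"):
            roster.append((AcquisitionSpec(family=acq), KernelSpec(family=family)))
    if n > len(roster):
        raise ValueError(f"default roster supports at most {len(roster)} instances")
    return tuple(roster[:n])


@dataclass(frozen=True)
class PBOConfig:
    """Configuration of one PBO run.

    ``instances`` supplies one (acquisition, kernel) pair per parallel
    instance; ``T`` caps the number of sharing iterations, and the
    optional ``improvement_threshold`` stops early once one iteration
    improves the incumbent by less than the threshold.
    """

    instances: Sequence[tuple[AcquisitionSpec, KernelSpec]]
    T: int = 30
    init_design_size: int | None = None  # None -> max(10, 2d)
    restarts: int = 10
    improvement_threshold: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.instances) < 1:
            raise ValueError("need at least one BO instance")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.init_design_size is not None and self.init_design_size < 2:
            raise ValueError("init_design_size must be >= 2")

    @property
    def N(self) -> int:
        return len(self.instances)


@dataclass
class PBOTrace:
    """Evaluation history and incumbent path of one run."""

    records: list[EvaluationRecord]
    incumbent_objective: list[float]   # one entry per iteration, after init
    incumbent_point: list[np.ndarray]  # original units
    stop_reason: str
    config: PBOConfig | None = None
    bounds: np.ndarray | None = None

    @property
    def best_f(self) -> float:
        return float(min(r.f for r in self.records))

    @property
    def best_x(self) -> np.ndarray:
        return min(self.records, key=lambda r: r.f).x

    @property
    def n_evaluations(self) -> int:
        return len(self.records)

    def to_frame(self, parameter_names: Sequence[str] | None = None) -> pd.DataFrame:
        d = self.records[0].x.size
        names = list(parameter_names) if parameter_names else [f"x{j}" for j in range(d)]
        rows = []
        best = np.inf
        for r in self.records:
            best = min(best, r.f)
            row = {"iteration": r.iteration, "instance": r.source_instance}
            row.update({nm: v for nm, v in zip(names, r.x, strict=True)})
            row["objective"] = r.f
            row["incumbent"] = best
            rows.append(row)
        return pd.DataFrame(rows)

    def metadata(self) -> dict:
        meta = {
            "stop_reason": self.stop_reason,
            "n_evaluations": self.n_evaluations,
            "best_objective": self.best_f,
        }
        if self.config is not None:
            meta["config"] = {
                "N": self.config.N,
                "T": self.config.T,
                "init_design_size": self.config.init_design_size,
                "restarts": self.config.restarts,
                "improvement_threshold": self.config.improvement_threshold,
                "seed": self.config.seed,
                "instances": [
                    {"acquisition": a.family, "xi": a.xi, "kappa": a.kappa,
                     "kernel": k.family, "length_scale": k.length_scale,
                     "tuned": k.tune_by_likelihood}
                    for a, k in self.config.instances
                ],
            }
        return meta

    def save_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


def _scale(x: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    return (x - bounds[:, 0]) / (bounds[:, 1] - bounds[:, 0])


def _unscale(u: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    return bounds[:, 0] + u * (bounds[:, 1] - bounds[:, 0])


def _evaluate(
    objective: Callable[[np.ndarray], float],
    u: np.ndarray,
    bounds: np.ndarray,
    source: str,
    iteration: int,
    rng: np.random.Generator,
) -> EvaluationRecord:
    """Evaluate one scaled point; a raising objective gets one retry
    at the same point and then a uniform-random replacement."""
    for attempt in range(2):
        x = _unscale(u, bounds)
        try:
            f = float(objective(x))
        except Exception:  # noqa: BLE001 - black-box objective
            if attempt == 0:
                logger.warning("objective raised at %s; retrying once", x)
                continue
            logger.warning("objective raised twice; replacing with a random point")
            u = rng.uniform(size=u.size)
        else:
            return EvaluationRecord(x=x, x_scaled=u, f=f, source_instance=source, iteration=iteration)
    x = _unscale(u, bounds)
    f = float(objective(x))
    return EvaluationRecord(x=x, x_scaled=u, f=f, source_instance=source, iteration=iteration)


def run_pbo(
    objective: Callable[[np.ndarray], float],
    bounds: np.ndarray | Sequence[Sequence[float]],
    config: PBOConfig,
) -> PBOTrace:
    """Minimize a black-box objective over a bounded box with PBO.

    The run starts from a Latin-hypercube initial design shared by all
    instances.  Each iteration then: (i) every instance refits its GP
    on the shared pool of all evaluations so far, (ii) proposes a
    point by maximizing its own acquisition, (iii) all ``N`` proposals
    are evaluated and appended to the pool, and (iv) the incumbent is
    updated.  Total objective calls are
    ``init_design_size + N * iterations``.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be a finite (d, 2) array")
    d = bounds.shape[0]
    n_init = config.init_design_size or max(10, 2 * d)

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.N + 2)
    design_rng = np.random.default_rng(children[0])
    repair_rng = np.random.default_rng(children[1])
    instance_rngs = [np.random.default_rng(c) for c in children[2:]]

    pool: list[EvaluationRecord] = []
    for u in latin_hypercube(n_init, d, design_rng):
        pool.append(_evaluate(objective, u, bounds, "init", 0, repair_rng))

    incumbent_f: list[float] = []
    incumbent_x: list[np.ndarray] = []
    best = min(pool, key=lambda r: r.f)
    stop_reason = f"max iterations T={config.T} reached"

    for t in range(1, config.T + 1):
        proposals: list[np.ndarray] = []
        for i, (acq, kernel) in enumerate(config.instances):
            gp = fit_gp(pool, kernel)
            u = propose_next(gp, acq, restarts=config.restarts, rng=instance_rngs[i])
            u = _dedup(u, pool, proposals, instance_rngs[i])
            proposals.append(u)
        prev_best = best.f
        for i, u in enumerate(proposals):
            rec = _evaluate(objective, u, bounds, f"instance_{i}", t, repair_rng)
            pool.append(rec)
            if rec.f < best.f:
                best = rec
        incumbent_f.append(best.f)
        incumbent_x.append(best.x)
        if (
            config.improvement_threshold is not None
            and prev_best - best.f < config.improvement_threshold
        ):
            stop_reason = (
                f"incumbent improvement {prev_best - best.f:.3g} below "
                f"threshold {config.improvement_threshold:.3g} at iteration {t}"
            )
            break

    return PBOTrace(
        records=pool,
        incumbent_objective=incumbent_f,
        incumbent_point=incumbent_x,
        stop_reason=stop_reason,
        config=config,
        bounds=bounds,
    )


def _dedup(
    u: np.ndarray,
    pool: list[EvaluationRecord],
    pending: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Replace a proposal that coincides with an already-evaluated or
    pending point by a uniform random point."""
    existing = [r.x_scaled for r in pool] + pending
    for v in existing:
        if np.max(np.abs(u - v)) <= DEDUP_TOL:
            logger.warning("duplicate proposal replaced by a random point")
            return rng.uniform(size=u.size)
    return u


def run_bo(
    objective: Callable[[np.ndarray], float],
    bounds: np.ndarray | Sequence[Sequence[float]],
    acq: AcquisitionSpec | None = None,
    kernel: KernelSpec | None = None,
    T: int = 30,
    init_design_size: int | None = None,
    seed: int = 0,
    restarts: int = 10,
    improvement_threshold: float | None = None,
) -> PBOTrace:
    """Classic single-instance Bayesian optimization baseline.

    Structurally identical to :func:`run_pbo` with ``N = 1``: one
    surrogate, one proposal and one objective evaluation per
    iteration.
    """
    acq = acq or AcquisitionSpec(family="ei")
    kernel = kernel or KernelSpec(family="matern52")
    config = PBOConfig(
        instances=[(acq, kernel)],
        T=T,
        init_design_size=init_design_size,
        restarts=restarts,
        improvement_threshold=improvement_threshold,
        seed=seed,
    )
    return run_pbo(objective, bounds, config)
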