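"""Gaussian-process surrogates and acquisition functions.

Each Bayesian-optimization instance owns a kernel specification and an
acquisition specification.  Surrogates are fitted on inputs scaled to
the unit hypercube and objectives standardized to zero mean / unit
variance, so a single length scale is meaningful across crop
parameters of wildly different units.  Gaussian-process regression is
delegated to scikit-learn; the acquisition algebra and the multi-start
bounded quasi-Newton inner maximization live here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm, qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process import kernels as skk

logger = logging.getLogger(__name__)

__all__ = [
    "KernelSpec",
    "AcquisitionSpec",
    "GPPosterior",
    "EvaluationRecord",
    "fit_gp",
    "acquisition_value",
    "propose_next",
]

_KERNEL_FAMILIES = ("rbf", "matern32", "matern52")
_ACQ_FAMILIES = ("ei", "pi", "lcb")

#: Default jitter on the standardized-objective scale, escalated by
#: decades up to JITTER_MAX when the covariance Cholesky fails.
JITTER_DEFAULT = 1e-6
JITTER_MAX = 1e-2

#: Two proposals closer than this (unit-hypercube distance) are
#: considered duplicates.
DEDUP_TOL = 1e-8


@dataclass(frozen=True)
class KernelSpec:
    """Covariance family and hyperparameters for one GP instance.

    ``length_scale`` and ``signal_variance`` are on the scaled-input /
    standardized-objective scale.  With ``tune_by_likelihood`` the
    stated values are the starting point of a marginal-likelihood
    refit at every surrogate update; otherwise they are held fixed.
    """

    family: str = "matern52"
    length_scale: float = 0.3
    signal_variance: float = 1.0
    tune_by_likelihood: bool = True

    def __post_init__(self) -> None:
        if self.family not in _KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; expected one of {_KERNEL_FAMILIES}")
        if self.length_scale <= 0 or self.signal_variance <= 0:
            raise ValueError("length_scale and signal_variance must be positive")

    def build(self) -> skk.Kernel:
        ls_bounds = (1e-2, 1e2)
        sv_bounds = (1e-3, 1e3)
        if self.family == "rbf":
            base = skk.RBF(length_scale=self.length_scale, length_scale_bounds=ls_bounds)
        else:
            nu = 1.5 if self.family == "matern32" else 2.5
            base = skk.Matern(length_scale=self.length_scale, length_scale_bounds=ls_bounds, nu=nu)
        return skk.ConstantKernel(self.signal_variance, constant_value_bounds=sv_bounds) * base


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition family with its exploration parameter.

    ``xi`` is the improvement margin for expected improvement (EI) and
    probability of improvement (PI); ``kappa`` is the exploration
    weight of the lower confidence bound (LCB).  Both are on the
    standardized objective scale.
    """

    family: str = "ei"
    xi: float = 0.01
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.family not in _ACQ_FAMILIES:
            raise ValueError(f"unknown acquisition family {self.family!r}; expected one of {_ACQ_FAMILIES}")
        if self.xi < 0 or self.kappa < 0:
            raise ValueError("xi and kappa must be non-negative")


@dataclass(frozen=True)
class EvaluationRecord:
    """One objective evaluation in the shared pool."""

    x: np.ndarray          # original units
    x_scaled: np.ndarray   # unit-hypercube image
    f: float               # loss (minimized)
    source_instance: str
    iteration: int


@dataclass
class GPPosterior:
    """Fitted GP over scaled inputs and standardized objectives."""

    gpr: GaussianProcessRegressor
    X: np.ndarray            # (m, d) scaled training inputs
    y_std_scale: float       # std of raw objectives (1.0 if degenerate)
    y_mean: float
    jitter: float
    kernel_spec: KernelSpec
    y_standardized: np.ndarray = field(default=None)

    @property
    def f_best(self) -> float:
        """Incumbent objective on the standardized scale."""
        return float(np.min(self.y_standardized))

    def predict(self, U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and sd (standardized scale) at scaled points."""
        U = np.atleast_2d(np.asarray(U, dtype=float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn warns when clipping tiny negative variances
            mu, sd = self.gpr.predict(U, return_std=True)
        return mu, np.maximum(sd, 0.0)

    def standardize(self, f: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(f, dtype=float) - self.y_mean) / self.y_std_scale


def _merge_duplicates(X: np.ndarray, y: np.ndarray, tol: float = DEDUP_TOL):
    """Average objective values of coincident inputs (within tol)."""
    keep_X: list[np.ndarray] = []
    keep_y: list[list[float]] = []
    for xi, yi in zip(X, y, strict=True):
        for j, xj in enumerate(keep_X):
            if np.max(np.abs(xi - xj)) <= tol:
                keep_y[j].append(yi)
                break
        else:
            keep_X.append(xi)
            keep_y.append([yi])
    if len(keep_X) < len(X):
        logger.warning("merged %d duplicate training inputs", len(X) - len(keep_X))
    return np.array(keep_X), np.array([float(np.mean(v)) for v in keep_y])


def fit_gp(records: list[EvaluationRecord], kernel: KernelSpec) -> GPPosterior:
    """Fit the GP posterior on the shared evaluation pool.

    Inputs are the records' unit-hypercube images; objectives are
    standardized per fit.  On a Cholesky failure the noise jitter is
    escalated by decades up to :data:`JITTER_MAX`.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 evaluation records to fit a GP")
    X = np.array([r.x_scaled for r in records], dtype=float)
    y = np.array([r.f for r in records], dtype=float)
    X, y = _merge_duplicates(X, y)
    if len(X) < 2:
        raise ValueError("fewer than 2 distinct inputs after merging duplicates")

    y_mean = float(np.mean(y))
    y_sd = float(np.std(y))
    if y_sd <= 0.0:
        y_sd = 1.0
    z = (y - y_mean) / y_sd

    jitter = JITTER_DEFAULT
    last_err: Exception | None = None
    while jitter <= JITTER_MAX * (1 + 1e-12):
        gpr = GaussianProcessRegressor(
            kernel=kernel.build(),
            alpha=jitter,
            optimizer="fmin_l_bfgs_b" if kernel.tune_by_likelihood else None,
            n_restarts_optimizer=0,
            normalize_y=False,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gpr.fit(X, z)
        except np.linalg.LinAlgError as err:  # singular covariance
            last_err = err
            jitter *= 10.0
            logger.warning("covariance Cholesky failed; escalating jitter to %g", jitter)
            continue
        return GPPosterior(
            gpr=gpr, X=X, y_std_scale=y_sd, y_mean=y_mean,
            jitter=jitter, kernel_spec=kernel, y_standardized=z,
        )
    raise np.linalg.LinAlgError(
        f"GP covariance remained singular up to jitter {JITTER_MAX}: {last_err}"
    )


def acquisition_value(
    acq: AcquisitionSpec,
    gp: GPPosterior,
    x: np.ndarray,
    f_best: float | None = None,
) -> np.ndarray | float:
    """Score points in the unit hypercube; larger is more desirable.

    All three families use the minimization convention with
    ``z = (f_best - mu - xi) / sigma``:

    - EI  = (f_best - mu - xi) Phi(z) + sigma phi(z)
    - PI  = Phi(z)
    - LCB score = -mu + kappa sigma

    ``f_best`` is on the standardized objective scale and defaults to
    the GP's training incumbent.  At sigma = 0 the deterministic
    limits apply: EI = max(f_best - mu - xi, 0), PI in {0, 1}.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    mu, sd = gp.predict(np.atleast_2d(x))
    if f_best is None:
        f_best = gp.f_best

    if acq.family == "lcb":
        out = -mu + acq.kappa * sd
    else:
        imp = f_best - mu - acq.xi
        with np.errstate(divide="ignore", invalid="ignore"):
            zscore = np.where(sd > 0, imp / np.where(sd > 0, sd, 1.0), 0.0)
        if acq.family == "ei":
            out = np.where(
                sd > 0,
                imp * norm.cdf(zscore) + sd * norm.pdf(zscore),
                np.maximum(imp, 0.0),
            )
        else:  # pi
            out = np.where(sd > 0, norm.cdf(zscore), (imp > 0).astype(float))
    return float(out[0]) if scalar else out


def _acq_neg_with_grad(u, acq, gp, f_best, h=1e-6):
    """Negative acquisition and a central-difference gradient.

    The 2d+1 evaluation points are batched into a single posterior
    call, which keeps the inner optimization loop cheap.
    """
    d = u.size
    pts = np.empty((2 * d + 1, d))
    pts[0] = u
    for j in range(d):
        up = u.copy()
        dn = u.copy()
        up[j] = min(u[j] + h, 1.0)
        dn[j] = max(u[j] - h, 0.0)
        pts[1 + 2 * j] = up
        pts[2 + 2 * j] = dn
    vals = acquisition_value(acq, gp, pts, f_best)
    grad = np.empty(d)
    for j in range(d):
        denom = pts[1 + 2 * j, j] - pts[2 + 2 * j, j]
        grad[j] = (vals[1 + 2 * j] - vals[2 + 2 * j]) / denom if denom > 0 else 0.0
    return -float(vals[0]), -grad


def propose_next(
    gp: GPPosterior,
    acq: AcquisitionSpec,
    restarts: int = 10,
    rng: np.random.Generator | None = None,
    f_best: float | None = None,
    maxiter: int = 50,
) -> np.ndarray:
    """Maximize the acquisition over the unit hypercube.

    Runs bounded L-BFGS-B from ``restarts`` uniform-random starting
    points and returns the best terminal point; the start points
    themselves are kept as fallback candidates, so the returned
    point's acquisition value is never below any start point's.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    d = gp.X.shape[1]
    if f_best is None:
        f_best = gp.f_best
    starts = rng.uniform(size=(restarts, d))
    candidates = [s for s in starts]
    improved = False
    for s in starts:
        res = minimize(
            _acq_neg_with_grad,
            s,
            args=(acq, gp, f_best),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * d,
            options={"maxiter": maxiter},
        )
        if res.success or res.status == 1:  # status 1: hit maxiter, still usable
            candidates.append(np.clip(res.x, 0.0, 1.0))
            improved = True
    if not improved:
        logger.warning("all acquisition maximizations failed; falling back to best start point")
    cand = np.array(candidates)
    scores = acquisition_value(acq, gp, cand, f_best)
    return cand[int(np.argmax(scores))]


def latin_hypercube(n: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """Space-filling design of ``n`` points in the unit hypercube."""
    sampler = qmc.LatinHypercube(d=d, seed=rng)
    return sampler.random(n)
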