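"""GP surrogate, acquisition functions and the inner maximization."""

import numpy as np
import pytest
from scipy.stats import norm

from tdcal.params import default_parameter_space
from tdcal.surrogate import (
    AcquisitionSpec,
    EvaluationRecord,
    KernelSpec,
    acquisition_value,
    fit_gp,
    latin_hypercube,
    propose_next,
)


def _records(X, y):
    X = np.atleast_2d(X)
    return [
        EvaluationRecord(x=xi, x_scaled=xi, f=float(fi), source_instance="t", iteration=0)
        for xi, fi in zip(X, y)
    ]


class _StubGP:
    """Posterior stub with prescribed mean/sd, for closed-form checks."""

    def __init__(self, mu, sd):
        self.mu, self.sd = float(mu), float(sd)
        self.y_standardized = np.array([0.0, 1.0])

    def predict(self, U):
        m = np.atleast_2d(U).shape[0]
        return np.full(m, self.mu), np.full(m, self.sd)

    @property
    def f_best(self):
        return 0.0


class TestScaling:
    def test_round_trip_to_1e12(self, rng):
        space = default_parameter_space()
        x = np.array([rng.uniform(s.lower, s.upper) for s in space])
        assert np.allclose(space.unscale(space.scale(x)), x, atol=1e-12)
        u = rng.uniform(size=len(space))
        assert np.allclose(space.scale(space.unscale(u)), u, atol=1e-12)


class TestFitGP:
    def test_interpolates_training_data(self):
        X = np.array([[0.2], [0.8]])
        y = np.array([1.0, 3.0])
        gp = fit_gp(_records(X, y), KernelSpec(tune_by_likelihood=False))
        mu, _ = gp.predict(X)
        assert np.allclose(mu, gp.standardize(y), atol=1e-5)

    def test_prior_reversion_far_from_data(self):
        X = np.array([[0.48], [0.52]])
        y = np.array([0.0, 1.0])
        gp = fit_gp(
            _records(X, y),
            KernelSpec(family="rbf", length_scale=0.02, tune_by_likelihood=False),
        )
        mu, sd = gp.predict(np.array([[0.0]]))  # > 10 length scales away
        assert abs(mu[0]) < 1e-3          # standardized training mean is 0
        assert sd[0] == pytest.approx(1.0, abs=1e-3)  # prior sd (signal_variance=1)

    def test_matches_handcoded_gp_algebra(self):
        """Oracle: explicit 5x5 kernel solve with the same Matern-5/2."""
        X = np.linspace(0, 1, 5).reshape(-1, 1)
        y = X.ravel().copy()
        spec = KernelSpec(family="matern52", length_scale=0.3, tune_by_likelihood=False)
        gp = fit_gp(_records(X, y), spec)

        def matern52(a, b, ls=0.3):
            r = np.abs(a[:, None] - b[None, :]) / ls
            s = np.sqrt(5.0) * r
            return (1 + s + s**2 / 3) * np.exp(-s)

        z = (y - y.mean()) / y.std()
        K = matern52(X.ravel(), X.ravel()) + 1e-6 * np.eye(5)
        xq = np.array([0.125])  # midpoint of two close training points
        kq = matern52(xq, X.ravel())
        mu_oracle = kq @ np.linalg.solve(K, z)
        mu, _ = gp.predict(xq.reshape(-1, 1))
        assert mu[0] == pytest.approx(mu_oracle[0], abs=1e-8)
        assert z[0] <= mu[0] <= z[1]  # between the neighbours for this smooth fit

    def test_duplicates_merged(self, caplog):
        X = np.array([[0.3], [0.3], [0.9]])
        y = np.array([1.0, 3.0, 5.0])
        with caplog.at_level("WARNING"):
            gp = fit_gp(_records(X, y), KernelSpec(tune_by_likelihood=False))
        assert gp.X.shape[0] == 2
        assert "merged" in caplog.text
        mu, _ = gp.predict(np.array([[0.3]]))
        # merged objective is the average 2.0
        assert mu[0] == pytest.approx(gp.standardize(2.0), abs=1e-4)

    def test_posterior_sd_small_at_training_inputs(self, rng):
        X = rng.uniform(size=(8, 2))
        y = rng.normal(size=8)
        gp = fit_gp(_records(X, y), KernelSpec())
        _, sd = gp.predict(X)
        assert np.all(sd <= 5e-2)  # jitter-limited

    def test_rejects_single_record(self):
        with pytest.raises(ValueError):
            fit_gp(_records([[0.5]], [1.0]), KernelSpec())


class TestAcquisitionValues:
    def test_ei_deterministic_limit(self):
        gp = _StubGP(mu=-0.5, sd=0.0)
        assert acquisition_value(AcquisitionSpec("ei", xi=0.0), gp, np.zeros(1), f_best=0.0) == pytest.approx(0.5)
        gp = _StubGP(mu=0.5, sd=0.0)
        assert acquisition_value(AcquisitionSpec("ei", xi=0.0), gp, np.zeros(1), f_best=0.0) == 0.0

    def test_closed_forms_at_z_zero(self):
        gp = _StubGP(mu=0.0, sd=1.0)
        ei = acquisition_value(AcquisitionSpec("ei", xi=0.0), gp, np.zeros(1), f_best=0.0)
        pi = acquisition_value(AcquisitionSpec("pi", xi=0.0), gp, np.zeros(1), f_best=0.0)
        assert ei == pytest.approx(norm.pdf(0.0), abs=1e-12)  # 0.3989
        assert pi == pytest.approx(0.5, abs=1e-12)

    def test_pi_deterministic_limit(self):
        assert acquisition_value(AcquisitionSpec("pi"), _StubGP(-0.5, 0.0), np.zeros(1), f_best=0.0) == 1.0
        assert acquisition_value(AcquisitionSpec("pi"), _StubGP(0.5, 0.0), np.zeros(1), f_best=0.0) == 0.0

    def test_lcb_score(self):
        gp = _StubGP(mu=0.3, sd=0.7)
        got = acquisition_value(AcquisitionSpec("lcb", kappa=2.0), gp, np.zeros(1), f_best=0.0)
        assert got == pytest.approx(-0.3 + 2.0 * 0.7)

    def test_ei_nonnegative_on_grid(self, rng):
        X = rng.uniform(size=(6, 2))
        y = rng.normal(size=6)
        gp = fit_gp(_records(X, y), KernelSpec())
        grid = rng.uniform(size=(200, 2))
        vals = acquisition_value(AcquisitionSpec("ei"), gp, grid)
        assert np.all(vals >= 0)

    def test_ei_increases_with_sd_below_incumbent(self):
        sds = np.linspace(0.05, 2.0, 20)
        vals = [
            acquisition_value(AcquisitionSpec("ei", xi=0.0), _StubGP(-0.2, s), np.zeros(1), f_best=0.0)
            for s in sds
        ]
        assert np.all(np.diff(vals) > 0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionSpec("entropy")
        with pytest.raises(ValueError):
            AcquisitionSpec("ei", xi=-0.1)
        with pytest.raises(ValueError):
            KernelSpec(family="periodic")
        with pytest.raises(ValueError):
            KernelSpec(length_scale=0.0)


class TestProposeNext:
    def test_matches_grid_oracle_for_pure_exploitation(self, rng):
        """LCB with kappa=0 maximizes -mean; compare to a dense grid."""
        X = np.linspace(0, 1, 9).reshape(-1, 1)
        y = (X.ravel() - 0.37) ** 2
        gp = fit_gp(_records(X, y), KernelSpec(tune_by_likelihood=False, length_scale=0.3))
        u = propose_next(gp, AcquisitionSpec("lcb", kappa=0.0), restarts=10, rng=rng)
        grid = np.linspace(0, 1, 10001).reshape(-1, 1)
        mu, _ = gp.predict(grid)
        u_oracle = grid[np.argmin(mu), 0]
        assert u[0] == pytest.approx(u_oracle, abs=1e-3)

    def test_more_restarts_never_worse(self, rng):
        X = rng.uniform(size=(12, 2))
        y = np.sin(6 * X[:, 0]) * np.cos(6 * X[:, 1])  # multimodal surface
        gp = fit_gp(_records(X, y), KernelSpec(length_scale=0.15, tune_by_likelihood=False))
        acq = AcquisitionSpec("ei")
        u1 = propose_next(gp, acq, restarts=1, rng=np.random.default_rng(3))
        u20 = propose_next(gp, acq, restarts=20, rng=np.random.default_rng(3))
        assert acquisition_value(acq, gp, u20) >= acquisition_value(acq, gp, u1) - 1e-12

    def test_proposal_in_bounds(self, rng):
        X = rng.uniform(size=(6, 3))
        y = rng.normal(size=6)
        gp = fit_gp(_records(X, y), KernelSpec())
        u = propose_next(gp, AcquisitionSpec("lcb"), restarts=4, rng=rng)
        assert np.all((u >= 0) & (u <= 1))


def test_latin_hypercube_stratification(rng):
    pts = latin_hypercube(10, 2, rng)
    assert pts.shape == (10, 2)
    for j in range(2):
        # one point in each of the 10 equal-width strata per dimension
        assert sorted(np.floor(pts[:, j] * 10).astype(int)) == list(range(10))
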