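"""Sparse variational GP classifier: gradients, recovery, contracts.

Small problem sizes keep these fast; the full-scale recovery checks live in
the acceptance suite.
"""

import numpy as np
import pytest
from scipy.linalg import solve_triangular
from scipy.special import expit
from scipy.stats import spearmanr

from popscale.calibrate import (
    GPCalibrator,
    fit_calibrator,
    fit_calibrators,
    popeve_score,
)
from popscale.errors import ConsistencyError, DegenerateDataError, ParameterError
from popscale.gp import SVGPClassifier, SVGPConfig, rbf_kernel
from popscale.simulate import TruthRecord, simulate_presence
from popscale.types import PresenceRecord, ScoredVariant, VariantKey

SMALL = SVGPConfig(n_inducing=25, max_iter=200)


@pytest.fixture(scope="module")
def fitted():
    """Calibrator fitted on y ~ Bernoulli(expit(-x)), modest n."""
    rng = np.random.default_rng(42)
    x = rng.normal(size=5000)
    y = (rng.random(5000) < expit(-x)).astype(float)
    return fit_calibrator(x, y, SMALL), x


def test_elbo_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    n, M = 60, 5
    X = rng.normal(size=(n, 1))
    y = (rng.random(n) < expit(-X[:, 0])).astype(float)
    gp = SVGPClassifier(SVGPConfig(n_inducing=M))
    gp.Z = gp._init_inducing(X)
    Lk = gp._kuu_chol()
    Kuf = rbf_kernel(gp.Z, X, gp.config.lengthscale, gp.config.signal_variance)
    A = solve_triangular(Lk, Kuf, lower=True)
    q = (A**2).sum(0)
    t, w = np.polynomial.hermite.hermgauss(20)
    w = w / np.sqrt(np.pi)
    theta = rng.normal(scale=0.3, size=M + M + M * (M - 1) // 2)
    _, g = gp._elbo_and_grad(theta, y, A, q, t, w)
    for i in rng.choice(len(theta), size=10, replace=False):
        e = np.zeros_like(theta)
        e[i] = 1e-6
        fp, _ = gp._elbo_and_grad(theta + e, y, A, q, t, w)
        fm, _ = gp._elbo_and_grad(theta - e, y, A, q, t, w)
        assert abs((fp - fm) / 2e-6 - g[i]) < 1e-5


def test_elbo_improves_and_is_monotone(fitted):
    cal, _ = fitted
    trace = np.array(cal.gp.elbo_trace)
    assert trace[-1] >= trace[0]
    # L-BFGS accepts only decreasing objective values
    assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))


def test_recovered_map_is_monotone(fitted):
    cal, x = fitted
    grid = np.linspace(np.quantile(x, 0.01), np.quantile(x, 0.99), 200)
    mean, _ = cal.predict_latent(grid)
    rho, _ = spearmanr(grid, mean)
    assert abs(rho) >= 0.99
    discordant = np.mean(np.diff(mean) > 0)  # decreasing truth
    assert discordant <= 0.01


def test_equal_inputs_equal_outputs(fitted):
    cal, _ = fitted
    mean, sd = cal.predict_latent(np.array([0.7, 0.7]))
    assert mean[0] == mean[1] and sd[0] == sd[1]


def test_zero_mean_prior_dominates_extrapolation(fitted):
    cal, x = fitted
    grid = np.linspace(x.min(), x.max(), 100)
    in_range, _ = cal.predict_latent(grid)
    far = x.max() + 10 * cal.lengthscale_raw
    mean, sd = cal.predict_latent(np.array([far]))
    assert abs(mean[0]) < 0.1 * np.abs(in_range).max()
    assert abs(sd[0] - cal.prior_sd) < 0.02 * cal.prior_sd


def test_latent_sd_grows_beyond_training_range(fitted):
    cal, x = fitted
    probes = x.max() + np.array([0.5, 1.0, 2.0, 4.0]) * cal.lengthscale_raw
    _, sd = cal.predict_latent(probes)
    assert np.all(np.diff(sd) > 0)


def test_persistence_bit_identical(fitted, tmp_path):
    cal, _ = fitted
    probes = np.linspace(-4, 4, 1000)
    m0, s0 = cal.predict_latent(probes)
    cal.to_json(tmp_path / "m.json")
    cal2 = GPCalibrator.from_json(tmp_path / "m.json")
    m1, s1 = cal2.predict_latent(probes)
    assert np.array_equal(m0, m1) and np.array_equal(s0, s1)


def test_degenerate_inputs_rejected():
    x = np.linspace(-1, 1, 200)
    with pytest.raises(DegenerateDataError):
        fit_calibrator(x, np.ones(200), SVGPConfig(n_inducing=10))
    with pytest.raises(ParameterError, match="n_inducing"):
        fit_calibrator(x[:15], np.arange(15) % 2.0, SVGPConfig(n_inducing=10))
    cal = fit_calibrator(x, (x < 0).astype(float), SVGPConfig(n_inducing=10, max_iter=50))
    with pytest.raises(ParameterError):
        cal.predict_latent(np.array([np.nan]))


class TestEnsemble:
    class _Stub:
        """Calibrator stub with a fixed latent output."""

        def __init__(self, mean, sd):
            self._m, self._s = mean, sd

        def predict_latent(self, x):
            n = len(np.atleast_1d(np.asarray(x, float).ravel()))
            return np.full(n, self._m), np.full(n, self._s)

    @staticmethod
    def _variant(**scores):
        return ScoredVariant(key=VariantKey("G", 1, "M", "R"), base_scores=scores)

    def test_mean_of_one_is_identity(self):
        out = popeve_score({"eve": self._Stub(-6.0, 1.0)}, self._variant(eve=-2.0))
        assert out.latent_mean == -6.0 and out.models == ("eve",)

    def test_two_models_arithmetic_mean(self):
        cals = {"eve": self._Stub(-6.0, 1.0), "esm": self._Stub(-4.0, 1.0)}
        out = popeve_score(cals, self._variant(eve=-2.0, esm=-2.0))
        assert out.latent_mean == -5.0
        assert out.latent_sd == 1.0  # RMS of equal sds

    def test_missing_overlap_is_error(self):
        with pytest.raises(ConsistencyError):
            popeve_score({"other": self._Stub(0.0, 1.0)}, self._variant(eve=-2.0))


def test_fit_calibrators_per_column_and_joint():
    rng = np.random.default_rng(7)
    n = 1200
    z = rng.normal(size=n)
    variants = [
        ScoredVariant(
            key=VariantKey(f"G{i // 40}", i % 40 + 1, "M", "R"),
            base_scores={"eve": float(z[i] + rng.normal(0, 0.5)),
                         "esm": float(z[i] + rng.normal(0, 0.5))},
        )
        for i in range(n)
    ]
    truth = TruthRecord(link_params={"a": -1.0, "b": 0.0})
    presence = simulate_presence(variants, truth, seed=8)
    cfg = SVGPConfig(n_inducing=15, max_iter=80)
    per_col = fit_calibrators(variants, presence, cfg)
    assert set(per_col) == {"eve", "esm"}
    joint = fit_calibrators(variants, presence, cfg, joint=True)
    assert set(joint) == {"joint"}
    out = popeve_score(joint, variants[0])
    assert np.isfinite(out.latent_mean)
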