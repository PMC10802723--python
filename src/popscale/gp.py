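r"""Sparse variational Gaussian-process classification of variant presence.

The calibration model: population presence of a variant is Bernoulli with
logistic link on a latent function :math:`f` of the (standardised) base
score,

.. math::

    f \sim \mathcal{GP}(0, k),\qquad
    y_i \mid f(x_i) \sim \mathrm{Bernoulli}(\sigma(f(x_i))),

with a squared-exponential kernel
:math:`k(x, x') = \sigma_f^2 \exp(-\lVert x - x'\rVert^2 / 2\ell^2)` and an
*exactly zero* prior mean, so that the posterior latent mean — the
calibrated score — reverts to 0 ("no evidence against neutrality") away
from data rather than extrapolating pathogenicity.

Inference is the standard sparse variational approximation: ``M`` inducing
inputs :math:`Z` with variational posterior
:math:`q(u) = \mathcal{N}(m, S)`, :math:`S = LL^\top`.  The evidence lower
bound

.. math::

    \mathrm{ELBO} = \sum_i \mathbb{E}_{q(f_i)}[\log p(y_i \mid f_i)]
                    - \mathrm{KL}(q(u)\,\|\,p(u))

is maximised over :math:`(m, L)` by full-batch L-BFGS with analytic
gradients; the one-dimensional Bernoulli expectations use Gauss–Hermite
quadrature.  Everything is deterministic given the data and configuration,
and the kernel hyperparameters are fixed, config-exposed quantities on the
standardised input scale.

The variational distribution is parameterised in *whitened* coordinates
:math:`u = L_K v` with :math:`L_K L_K^\top = K_{uu}` and
:math:`q(v) = \mathcal{N}(m, S)`, which removes the :math:`K_{uu}^{-1}`
ill-conditioning from the objective.  The marginals are then

.. math::

    q(f_i) = \mathcal{N}(\mu_i, s_i^2),\quad
    \mu_i = a_i^\top m,\quad
    s_i^2 = k_{ii} - \lVert a_i\rVert^2 + a_i^\top S a_i,

with :math:`a_i = L_K^{-1} k_{u i}`, and the KL collapses to the
standard-normal form
:math:`\tfrac12(\mathrm{tr}\,S + m^\top m - M - \log|S|)`.  Gradients
follow from :math:`\partial \mathbb{E}/\partial \mu_i =
\mathbb{E}[y_i - \sigma(f)]` (and the matching term for :math:`s_i^2`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.special import expit

from .errors import DegenerateDataError, ParameterError


def _as_2d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ParameterError(f"inputs must be 1- or 2-dimensional, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ParameterError("inputs contain non-finite values")
    return x


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # ||a_i - b_j||^2, numerically clipped at 0
    d = (a**2).sum(1)[:, None] + (b**2).sum(1)[None, :] - 2.0 * a @ b.T
    return np.maximum(d, 0.0)


def rbf_kernel(a: np.ndarray, b: np.ndarray, lengthscale: float, variance: float) -> np.ndarray:
    return variance * np.exp(-0.5 * _sq_dists(a, b) / lengthscale**2)


def _tril_indices(m: int) -> Tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(m, k=-1)


@dataclass
class SVGPConfig:
    """Tunables of the sparse variational classifier.

    All quantities refer to the *standardised* input scale (the calibrator
    wrapper standardises scores before fitting).
    """

    n_inducing: int = 100
    lengthscale: float = 1.0
    signal_variance: float = 25.0
    max_iter: int = 500
    gh_points: int = 20
    jitter: float = 1e-8
    seed: int = 0


class SVGPClassifier:
    """Sparse variational GP binary classifier with zero prior mean."""

    def __init__(self, config: Optional[SVGPConfig] = None):
        self.config = config or SVGPConfig()
        self.Z: Optional[np.ndarray] = None  # (M, d) inducing inputs
        self.m: Optional[np.ndarray] = None  # (M,) whitened variational mean
        self.L: Optional[np.ndarray] = None  # (M, M) lower chol of S
        self.elbo_trace: List[float] = []
        self._Lk: Optional[np.ndarray] = None  # chol of Kuu (cached)

    # -- setup ------------------------------------------------------------

    def _init_inducing(self, X: np.ndarray) -> np.ndarray:
        """Inducing inputs at empirical quantiles (per dimension; grid in 2-D)."""
        M, d = self.config.n_inducing, X.shape[1]
        if d == 1:
            qs = np.linspace(0.0, 1.0, M)
            return np.quantile(X[:, 0], qs)[:, None]
        per_dim = max(2, int(round(M ** (1.0 / d))))
        axes = [np.quantile(X[:, j], np.linspace(0.0, 1.0, per_dim)) for j in range(d)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([g.ravel() for g in mesh], axis=1)

    def _kuu_chol(self) -> np.ndarray:
        if self._Lk is None:
            Kuu = rbf_kernel(self.Z, self.Z, self.config.lengthscale, self.config.signal_variance)
            Kuu[np.diag_indices_from(Kuu)] += self.config.jitter * self.config.signal_variance
            self._Lk = cholesky(Kuu, lower=True)
        return self._Lk

    # -- ELBO -------------------------------------------------------------

    @staticmethod
    def _pack(m: np.ndarray, L: np.ndarray) -> np.ndarray:
        M = len(m)
        i, j = _tril_indices(M)
        return np.concatenate([m, np.log(np.diag(L)), L[i, j]])

    @staticmethod
    def _unpack(theta: np.ndarray, M: int) -> Tuple[np.ndarray, np.ndarray]:
        m = theta[:M]
        L = np.zeros((M, M))
        L[np.diag_indices(M)] = np.exp(theta[M : 2 * M])
        i, j = _tril_indices(M)
        L[i, j] = theta[2 * M :]
        return m, L

    def _elbo_and_grad(self, theta, y, A, q_diag, gh_t, gh_w):
        """Negative ELBO and gradient w.r.t. packed whitened (m, L).

        A = Lk^{-1} Kuf (M, n) so a_i is column i; q_diag_i = ||a_i||^2.
        """
        M = self.Z.shape[0]
        s2f = self.config.signal_variance
        m, L = self._unpack(theta, M)

        LtA = L.T @ A                     # (M, n)
        mu = A.T @ m                      # (n,)
        s2 = np.maximum(s2f - q_diag + (LtA**2).sum(0), 1e-12)
        sr = np.sqrt(2.0 * s2)

        F = mu[:, None] + sr[:, None] * gh_t[None, :]       # (n, gh)
        resid = y[:, None] - expit(F)
        # E[log p(y|f)]: y*f - softplus(f)
        ll = y[:, None] * F - np.logaddexp(0.0, F)
        E = ll @ gh_w
        g = resid @ gh_w                                    # dE/dmu
        h = (resid * gh_t[None, :]) @ gh_w / sr             # dE/ds2

        # whitened KL(q(v) || N(0, I))
        logdetS = 2.0 * float(np.log(np.diag(L)).sum())
        kl = 0.5 * (float((L**2).sum()) + float(m @ m) - M - logdetS)
        elbo = float(E.sum()) - kl

        grad_m = A @ g - m
        # dELBO/dS = A diag(h) A^T - 0.5 I + 0.5 S^{-1}; grad_L = 2 G L
        G = (A * h) @ A.T
        Linv = solve_triangular(L, np.eye(M), lower=True)
        G += -0.5 * np.eye(M) + 0.5 * (Linv.T @ Linv)
        grad_L = 2.0 * G @ L
        i, j = _tril_indices(M)
        grad = np.concatenate(
            [grad_m, np.diag(grad_L) * np.diag(L), grad_L[i, j]]
        )
        return -elbo, -grad

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y) -> "SVGPClassifier":
        X = _as_2d(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(X) != len(y):
            raise ParameterError("X and y must have equal length")
        classes = np.unique(y)
        if not np.all(np.isin(classes, [0.0, 1.0])):
            raise ParameterError("y must be binary 0/1")
        if len(classes) < 2:
            raise DegenerateDataError(
                "presence labels contain a single class; cannot calibrate"
            )
        if len(X) < 2 * self.config.n_inducing:
            raise ParameterError(
                f"need n >= 2M data points (n={len(X)}, M={self.config.n_inducing}); "
                "reduce n_inducing"
            )

        self.Z = self._init_inducing(X)
        self._Lk = None
        Lk = self._kuu_chol()
        Kuf = rbf_kernel(self.Z, X, self.config.lengthscale, self.config.signal_variance)
        A = solve_triangular(Lk, Kuf, lower=True)  # whitened projector
        q_diag = (A**2).sum(0)
        del Kuf

        t, w = np.polynomial.hermite.hermgauss(self.config.gh_points)
        w = w / np.sqrt(np.pi)

        M = self.Z.shape[0]
        m0 = np.zeros(M)
        L0 = np.eye(M)  # q(v) initialised at the whitened prior -> KL = 0
        theta0 = self._pack(m0, L0)

        self.elbo_trace = []
        last_f = [np.inf]

        def fun(theta):
            f, g = self._elbo_and_grad(theta, y, A, q_diag, t, w)
            last_f[0] = f
            return f, g

        # the line search evaluates the accepted iterate last, so last_f at
        # callback time is f(xk)
        def cb(theta):
            self.elbo_trace.append(-last_f[0])

        f0, _ = fun(theta0)
        self.elbo_trace.append(-f0)
        res = minimize(
            fun,
            theta0,
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={"maxiter": self.config.max_iter, "maxcor": 20},
        )
        self.m, self.L = self._unpack(res.x, M)
        self.elbo_trace.append(-float(res.fun))
        return self

    # -- prediction -------------------------------------------------------

    def predict_latent(self, X) -> Tuple[np.ndarray, np.ndarray]:
        """Posterior latent mean and sd at new inputs (deterministic)."""
        if self.m is None:
            raise ParameterError("model is not fitted")
        X = _as_2d(X)
        Lk = self._kuu_chol()
        Kus = rbf_kernel(self.Z, X, self.config.lengthscale, self.config.signal_variance)
        A = solve_triangular(Lk, Kus, lower=True)      # (M, n*), whitened
        mean = A.T @ self.m
        LtA = self.L.T @ A
        var = self.config.signal_variance - (A**2).sum(0) + (LtA**2).sum(0)
        return mean, np.sqrt(np.maximum(var, 0.0))

    @property
    def final_elbo(self) -> float:
        return self.elbo_trace[-1]

    @property
    def initial_elbo(self) -> float:
        return self.elbo_trace[0]

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "config": self.config.__dict__,
            "Z": self.Z.tolist(),
            "m": self.m.tolist(),
            "L": self.L.tolist(),
            "elbo_trace": [self.initial_elbo, self.final_elbo],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVGPClassifier":
        obj = cls(SVGPConfig(**d["config"]))
        obj.Z = np.array(d["Z"], dtype=float)
        obj.m = np.array(d["m"], dtype=float)
        obj.L = np.array(d["L"], dtype=float)
        obj.elbo_trace = list(d["elbo_trace"])
        return obj
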