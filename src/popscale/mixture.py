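"""Two-component Gaussian mixture over cohort scores and severity thresholds.

The score distribution of de-novo mutations pooled across cases and
controls (unlabelled) is modelled as a two-component Gaussian mixture: a
low-mean "low fitness" component capturing pathogenic variants and a
high-mean background component.  A score is called *severely pathogenic*
where its posterior probability of belonging to the low-fitness component
exceeds a high level (default 0.9999) and *moderately pathogenic* above a
lower level (default 0.99); the corresponding score cutoffs are solved from
the fitted mixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .errors import DegenerateDataError, NoThresholdError, ParameterError

VARIANCE_FLOOR = 1e-6


@dataclass
class MixtureFit:
    """Fitted two-component mixture; component 0 has the lower mean."""

    weights: tuple
    means: tuple
    variances: tuple
    log_likelihood: float
    n_observations: int

    def __post_init__(self) -> None:
        w0, w1 = self.weights
        if not (0.0 < w0 < 1.0 and 0.0 < w1 < 1.0):
            raise ParameterError(f"weights must be in (0,1): {self.weights}")
        if abs(w0 + w1 - 1.0) > 1e-9:
            raise ParameterError(f"weights must sum to 1: {self.weights}")
        if not self.means[0] < self.means[1]:
            raise ParameterError("component 0 must have the lower mean")
        if min(self.variances) <= 0:
            raise ParameterError("variances must be > 0")


@dataclass
class Thresholds:
    """Severity cutoffs on the calibrated score scale (more negative = worse)."""

    severe_cutoff: float
    moderate_cutoff: float
    severe_level: float = 0.9999
    moderate_level: float = 0.99

    def __post_init__(self) -> None:
        if self.severe_cutoff > self.moderate_cutoff:
            raise ParameterError(
                "severe cutoff must lie at or below the moderate cutoff"
            )


class Band(str, Enum):
    SEVERE = "severe"
    MODERATE = "moderate"
    NOT_FLAGGED = "not_flagged"


def fit_gmm2(scores: Sequence[float], seed: int = 0) -> MixtureFit:
    """EM fit of the two-component mixture, best of 10 k-means-seeded restarts.

    Converges at relative log-likelihood change < 1e-8 (or 1000 iterations);
    components are relabelled so index 0 is the lower mean.  A variance
    floor guards EM degeneracy; inputs with (near-)zero spread are rejected.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1 or len(x) < 20:
        raise ParameterError(f"need >= 20 one-dimensional scores, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ParameterError("scores contain non-finite values")
    if np.var(x) < 1e-10:
        raise DegenerateDataError(
            "scores have (near-)zero variance; mixture components would be "
            "degenerate — add spread or raise the variance floor"
        )
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=10,
        init_params="kmeans",
        tol=1e-8,
        max_iter=1000,
        reg_covar=VARIANCE_FLOOR,
        random_state=seed,
    ).fit(x[:, None])
    means = gm.means_.ravel()
    variances = gm.covariances_.ravel()
    weights = gm.weights_.ravel()
    if np.min(variances) < 1e-10:
        raise DegenerateDataError(
            "a mixture component collapsed (variance < 1e-10); raise the "
            "variance floor"
        )
    order = np.argsort(means)
    return MixtureFit(
        weights=tuple(float(weights[i]) for i in order),
        means=tuple(float(means[i]) for i in order),
        variances=tuple(float(variances[i]) for i in order),
        log_likelihood=float(gm.score(x[:, None]) * len(x)),
        n_observations=len(x),
    )


def posterior_pathogenic(fit: MixtureFit, s) -> np.ndarray | float:
    """Posterior probability that a score belongs to the low-fitness component.

    Computed in log space so the far-pathogenic tail saturates to 1 without
    underflow:  w0 φ(s; μ0, σ0²) / Σk wk φ(s; μk, σk²).
    """
    s_arr = np.asarray(s, dtype=float)
    logp0 = np.log(fit.weights[0]) + norm.logpdf(
        s_arr, fit.means[0], np.sqrt(fit.variances[0])
    )
    logp1 = np.log(fit.weights[1]) + norm.logpdf(
        s_arr, fit.means[1], np.sqrt(fit.variances[1])
    )
    post = np.exp(logp0 - np.logaddexp(logp0, logp1))
    return float(post) if np.isscalar(s) else post


def solve_threshold(fit: MixtureFit, level: float) -> float:
    """Largest score t <= μ1 with posterior >= level on the whole prefix (-inf, t].

    A coarse 1000-point grid from μ0 - 6σ0 to μ1 locates the first grid
    point where the posterior drops below ``level``; bisection then refines
    the boundary to |Δs| < 1e-6.  The "largest valid prefix" rule keeps the
    threshold well defined when unequal variances make the posterior
    non-monotone.
    """
    if not 0.5 < level < 1.0:
        raise ParameterError(f"level must be in (0.5, 1), got {level}")
    mu0, mu1 = fit.means
    sd0 = float(np.sqrt(fit.variances[0]))
    if posterior_pathogenic(fit, mu0) < level:
        raise NoThresholdError(
            f"posterior at the low-fitness mean ({posterior_pathogenic(fit, mu0):.4f}) "
            f"is below the requested level {level}; no threshold exists"
        )
    grid = np.linspace(mu0 - 6.0 * sd0, mu1, 1000)
    post = posterior_pathogenic(fit, grid)
    below = np.nonzero(post < level)[0]
    if len(below) == 0:
        return float(grid[-1])  # entire search range satisfies the level
    first_bad = below[0]
    if first_bad == 0:
        # level already violated deep in the tail: shift the grid start down
        lo = mu0 - 20.0 * sd0
        if posterior_pathogenic(fit, lo) < level:
            raise NoThresholdError(f"level {level} unattainable anywhere")
    else:
        lo = float(grid[first_bad - 1])
    hi = float(grid[first_bad])
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if posterior_pathogenic(fit, mid) >= level:
            lo = mid
        else:
            hi = mid
    return lo


def derive_thresholds(
    fit: MixtureFit, severe_level: float = 0.9999, moderate_level: float = 0.99
) -> Thresholds:
    return Thresholds(
        severe_cutoff=solve_threshold(fit, severe_level),
        moderate_cutoff=solve_threshold(fit, moderate_level),
        severe_level=severe_level,
        moderate_level=moderate_level,
    )


def classify(score: float, thresholds: Thresholds) -> Band:
    """Band a score: severe / moderate / not_flagged (boundaries inclusive below)."""
    if score <= thresholds.severe_cutoff:
        return Band.SEVERE
    if score <= thresholds.moderate_cutoff:
        return Band.MODERATE
    return Band.NOT_FLAGGED
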