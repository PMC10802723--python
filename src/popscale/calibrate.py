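"""Calibrator API: fit presence models per score column and ensemble them.

A :class:`GPCalibrator` wraps the sparse variational GP classifier with
input standardisation and training metadata.  The calibrated score of a
variant is the posterior latent mean — the log-odds of population presence
— so 0 is neutral and more negative means more constrained.  Per-model
calibrators are fitted independently and ensembled by averaging latent
means (latent sds combine as root-mean-square); a joint multi-dimensional
calibrator over several score columns is available as an alternative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ConsistencyError, DegenerateDataError, ParameterError
from .gp import SVGPClassifier, SVGPConfig
from .types import PresenceRecord, ScoredVariant, VariantKey


@dataclass
class CalibratedScore:
    """Calibrated (latent-logit) score with posterior uncertainty."""

    key: VariantKey
    latent_mean: float
    latent_sd: float
    models: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.latent_mean) or not np.isfinite(self.latent_sd):
            raise ParameterError(f"{self.key}: non-finite calibrated score")
        if self.latent_sd < 0:
            raise ParameterError(f"{self.key}: latent_sd must be >= 0")


class GPCalibrator:
    """A fitted presence model for one score column (or a joint set)."""

    def __init__(self, gp: SVGPClassifier, center: np.ndarray, scale: np.ndarray,
                 model_name: str = "score"):
        self.gp = gp
        self.center = np.atleast_1d(np.asarray(center, float))
        self.scale = np.atleast_1d(np.asarray(scale, float))
        self.model_name = model_name

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.shape[1] != len(self.center):
            raise ParameterError(
                f"expected {len(self.center)}-dimensional inputs, got {x.shape[1]}"
            )
        return (x - self.center) / self.scale

    def predict_latent(self, x) -> Tuple[np.ndarray, np.ndarray]:
        """Posterior latent mean and sd on the raw score scale of the input."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ParameterError("non-finite score passed to predict_latent")
        return self.gp.predict_latent(self._standardize(x))

    @property
    def prior_sd(self) -> float:
        return float(np.sqrt(self.gp.config.signal_variance))

    @property
    def lengthscale_raw(self) -> float:
        """Kernel lengthscale expressed in raw score units (1-D only)."""
        return float(self.gp.config.lengthscale * self.scale[0])

    # -- persistence: single JSON file, bit-identical reload --------------

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "model_name": self.model_name,
                    "center": self.center.tolist(),
                    "scale": self.scale.tolist(),
                    "gp": self.gp.to_dict(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "GPCalibrator":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            gp=SVGPClassifier.from_dict(d["gp"]),
            center=np.array(d["center"]),
            scale=np.array(d["scale"]),
            model_name=d["model_name"],
        )


def fit_calibrator(
    x,
    y,
    config: Optional[SVGPConfig] = None,
    model_name: str = "score",
) -> GPCalibrator:
    """Fit a presence calibrator on base scores ``x`` and presence flags ``y``.

    ``x`` may be (n,) for a single score column or (n, d) for a joint fit.
    Inputs are standardised to zero mean, unit variance; the output latent
    scale is left raw so 0 always means "no evidence against neutrality".
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.all(np.isfinite(x)):
        raise ParameterError("scores contain non-finite values")
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    if np.any(scale <= 0):
        raise DegenerateDataError("a score column has zero spread")
    gp = SVGPClassifier(config or SVGPConfig())
    gp.fit((x - center) / scale, y)
    return GPCalibrator(gp=gp, center=center, scale=scale, model_name=model_name)


def fit_calibrators(
    scores: Sequence[ScoredVariant],
    presence: Sequence[PresenceRecord],
    config: Optional[SVGPConfig] = None,
    joint: bool = False,
) -> Dict[str, GPCalibrator]:
    """Fit one calibrator per base-score column against cohort presence.

    With ``joint=True`` a single calibrator conditioning on all columns at
    once is fitted instead (returned under the key ``"joint"``); variants
    missing any column are dropped from training.
    """
    present = {p.key: p.present for p in presence}
    missing = [v.key for v in scores if v.key not in present]
    if missing:
        raise ConsistencyError(
            f"{len(missing)} scored variants lack presence records, e.g. {missing[0]}"
        )
    columns = sorted({c for v in scores for c in v.base_scores})
    if joint:
        rows = [v for v in scores if all(c in v.base_scores for c in columns)]
        X = np.array([[v.base_scores[c] for c in columns] for v in rows])
        y = np.array([present[v.key] for v in rows], dtype=float)
        return {"joint": fit_calibrator(X, y, config, model_name="joint")}
    out: Dict[str, GPCalibrator] = {}
    for c in columns:
        rows = [v for v in scores if c in v.base_scores]
        xs = np.array([v.base_scores[c] for v in rows])
        ys = np.array([present[v.key] for v in rows], dtype=float)
        out[c] = fit_calibrator(xs, ys, config, model_name=c)
    return out


def popeve_score(
    calibrators: Mapping[str, GPCalibrator],
    variant: ScoredVariant,
) -> CalibratedScore:
    """Ensemble calibrated score: mean of per-model latent means.

    Latent sds combine as root-mean-square.  Only calibrators whose score
    column is present on the variant contribute; the contributing model
    names are recorded on the result.
    """
    if "joint" in calibrators:
        cal = calibrators["joint"]
        cols = sorted(variant.base_scores)
        if len(cols) != len(cal.center):
            raise ConsistencyError(
                f"{variant.key}: joint calibrator expects {len(cal.center)} scores, "
                f"variant has {len(cols)}"
            )
        mean, sd = cal.predict_latent(
            np.array([[variant.base_scores[c] for c in cols]])
        )
        return CalibratedScore(
            key=variant.key, latent_mean=float(mean[0]), latent_sd=float(sd[0]),
            models=("joint",),
        )
    avail = [name for name in sorted(calibrators) if name in variant.base_scores]
    if not avail:
        raise ConsistencyError(
            f"{variant.key}: no base score overlaps the fitted calibrators "
            f"{sorted(calibrators)}"
        )
    means, var = [], []
    for name in avail:
        mean, sd = calibrators[name].predict_latent(
            np.array([variant.base_scores[name]])
        )
        means.append(float(mean[0]))
        var.append(float(sd[0]) ** 2)
    return CalibratedScore(
        key=variant.key,
        latent_mean=float(np.mean(means)),
        latent_sd=float(np.sqrt(np.mean(var))),
        models=tuple(avail),
    )


def apply_calibrators(
    calibrators: Mapping[str, GPCalibrator],
    scores: Sequence[ScoredVariant],
) -> List[ScoredVariant]:
    """Vectorised ensemble scoring: fills ``popeve_score`` on every variant."""
    if "joint" in calibrators:
        cal = calibrators["joint"]
        cols = sorted({c for v in scores for c in v.base_scores})
        X = np.array([[v.base_scores[c] for c in cols] for v in scores])
        mean, _ = cal.predict_latent(X)
        return [
            ScoredVariant(key=v.key, base_scores=dict(v.base_scores),
                          popeve_score=float(m))
            for v, m in zip(scores, mean)
        ]
    # batch per column, then average available columns per variant
    col_means: Dict[str, np.ndarray] = {}
    for name, cal in calibrators.items():
        xs = np.array([v.base_scores.get(name, np.nan) for v in scores])
        ok = np.isfinite(xs)
        vals = np.full(len(scores), np.nan)
        if ok.any():
            mean, _ = cal.predict_latent(xs[ok])
            vals[ok] = mean
        col_means[name] = vals
    out = []
    stacked = np.vstack([col_means[n] for n in sorted(col_means)])
    with np.errstate(invalid="ignore"):
        ens = np.nanmean(stacked, axis=0)
    for v, m in zip(scores, ens):
        if not np.isfinite(m):
            raise ConsistencyError(f"{v.key}: no base score overlaps calibrators")
        out.append(
            ScoredVariant(key=v.key, base_scores=dict(v.base_scores),
                          popeve_score=float(m))
        )
    return out
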