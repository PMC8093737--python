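"""Power-function allometry fitted on the log-log scale.

Woody biomass is related to stem diameter by the power function
``M = a * D**b``, which becomes linear after a log transform::

    ln M = b * ln D + ln a + eps,    eps ~ N(0, sigma**2)

Ordinary least squares on the log scale controls the heteroscedastic
(multiplicative) residuals that are typical of biomass data, and the
back-transformed 95% prediction interval is positively skewed about the
point estimate ``a * D**b`` — the skew is the reason uncertainty for
large shrubs explodes faster than their mass.

This module provides the fitted-allometry estimator, back-transformed
prediction intervals and bands over a diameter grid, the overlap of two
bands (used to test the self-similarity of aerial tips and whole
shrubs), and the power-law model of prediction error versus diameter
used downstream by the sampling-design rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CalibSample",
    "LogLogAllometry",
    "LogLogFit",
    "PredictionBand",
    "PEModel",
    "fit_loglog",
    "predict_log",
    "prediction_interval",
    "prediction_band",
    "band_overlap",
    "fit_pe_model",
]


@dataclass(frozen=True)
class CalibSample:
    """One destructively sampled shrub or aerial tip.

    ``diameter_cm`` is DRC (diameter at root collar) for rooted shrubs
    and the basal diameter for aerial tips; ``mass_kg`` is wet field-mass.
    """

    diameter_cm: float
    mass_kg: float
    role: str = "whole_shrub"  # or "aerial_tip"
    taxon: str = ""

    def __post_init__(self) -> None:
        if not (self.diameter_cm > 0 and self.mass_kg > 0):
            raise ValueError(
                f"diameter and mass must be positive, got "
                f"({self.diameter_cm}, {self.mass_kg})"
            )


@dataclass
class PredictionBand:
    """Point estimate and back-transformed prediction bounds on a diameter grid."""

    grid_cm: np.ndarray
    point_kg: np.ndarray
    lwr_kg: np.ndarray
    upr_kg: np.ndarray
    level: float = 0.95

    @property
    def uncertainty_kg(self) -> np.ndarray:
        """Interval range upr - lwr at each grid diameter."""
        return self.upr_kg - self.lwr_kg


@dataclass(frozen=True)
class PEModel:
    """Prediction error as a power law of diameter, PE = k * D**p."""

    k: float
    p: float

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.p > 0):
            raise ValueError(f"k and p must be positive, got ({self.k}, {self.p})")

    def pe(self, diameter_cm):
        return self.k * np.asarray(diameter_cm, dtype=float) ** self.p


class LogLogAllometry(RegressorMixin, BaseEstimator):
    """OLS fit of ln(mass) on ln(diameter) with prediction standard errors.

    Fitted attributes
    -----------------
    intercept_ : float
        ln(a) on the log scale.
    slope_ : float
        Allometric exponent b.
    residual_scale_ : float
        sqrt(SSE / df), the standard deviation of the log residuals.
    n_, df_ : int
        Sample size and residual degrees of freedom (n - 2).
    mean_logx_, sxx_ : float
        Mean of ln(D) and its sum of squared deviations; together with
        ``residual_scale_`` these are sufficient for every standard error
        this class reports.
    r2_ : float
        Coefficient of determination of the log-log regression.
    slope_se_, intercept_se_ : float
    diameter_range_ : tuple of float
        (min, max) training diameter, used for extrapolation warnings.
    """

    def fit(self, X, y):
        d = np.asarray(X, dtype=float).reshape(-1)
        m = np.asarray(y, dtype=float).reshape(-1)
        if d.shape != m.shape:
            raise ValueError("X and y must have the same length")
        if d.size < 3:
            raise ValueError("at least 3 samples are required")
        if np.any(d <= 0) or np.any(m <= 0):
            raise ValueError("diameters and masses must all be positive")
        lx, ly = np.log(d), np.log(m)
        sxx = float(np.sum((lx - lx.mean()) ** 2))
        if sxx <= 0:
            raise ValueError("at least 2 distinct diameters are required")
        res = sm.OLS(ly, sm.add_constant(lx)).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.n_ = int(d.size)
        self.df_ = self.n_ - 2
        self.residual_scale_ = float(np.sqrt(res.ssr / self.df_))
        self.mean_logx_ = float(lx.mean())
        self.sxx_ = sxx
        self.r2_ = float(res.rsquared)
        self.intercept_se_ = float(res.bse[0])
        self.slope_se_ = float(res.bse[1])
        self.diameter_range_ = (float(d.min()), float(d.max()))
        return self

    # -- prediction -------------------------------------------------------

    def predict_log(self, diameter_cm):
        """Expected log-mass with estimation and prediction standard errors.

        Returns ``(mu, se_fit, se_pred)`` where ``se_fit`` is the standard
        error of the regression estimate at ln(D) and
        ``se_pred = sqrt(residual_scale**2 + se_fit**2)`` is the standard
        error for predicting a new observation.
        """
        self._check_fitted()
        d = np.asarray(diameter_cm, dtype=float)
        if np.any(d <= 0):
            raise ValueError("diameter must be positive")
        lx = np.log(d)
        mu = self.intercept_ + self.slope_ * lx
        se_fit = self.residual_scale_ * np.sqrt(
            1.0 / self.n_ + (lx - self.mean_logx_) ** 2 / self.sxx_
        )
        se_pred = np.sqrt(self.residual_scale_**2 + se_fit**2)
        return mu, se_fit, se_pred

    def predict(self, X):
        """Point estimate a * D**b (the exponentiated conditional mean)."""
        mu, _, _ = self.predict_log(np.asarray(X, dtype=float).reshape(-1))
        return np.exp(mu)

    def prediction_interval(self, diameter_cm, level: float = 0.95):
        """Back-transformed prediction interval ``(point, lwr, upr)``.

        The interval is symmetric on the log scale, mu +/- t_{df} * se_pred,
        hence multiplicatively symmetric after exponentiation:
        lwr * upr == point**2.
        """
        self._check_fitted()
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.df_ < 1:
            raise ValueError("fit has no residual degrees of freedom")
        mu, _, se_pred = self.predict_log(diameter_cm)
        tq = stats.t.ppf(1 - (1 - level) / 2, self.df_)
        half = tq * se_pred
        return np.exp(mu), np.exp(mu - half), np.exp(mu + half)

    def band(self, d_min: float, d_max: float, step: float = 0.01,
             level: float = 0.95) -> PredictionBand:
        """Prediction band over the inclusive grid [d_min, d_max]."""
        grid = _diameter_grid(d_min, d_max, step)
        point, lwr, upr = self.prediction_interval(grid, level=level)
        return PredictionBand(grid, point, lwr, upr, level)

    # -- persistence ------------------------------------------------------

    _FIELDS = ("intercept_", "slope_", "residual_scale_", "n_", "df_",
               "mean_logx_", "sxx_", "r2_", "intercept_se_", "slope_se_",
               "diameter_range_")

    def to_dict(self) -> dict:
        self._check_fitted()
        out = {k.rstrip("_"): getattr(self, k) for k in self._FIELDS}
        out["diameter_range"] = list(self.diameter_range_)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "LogLogAllometry":
        obj = cls()
        for k in cls._FIELDS:
            obj.__setattr__(k, d[k.rstrip("_")])
        obj.diameter_range_ = tuple(d["diameter_range"])
        obj.n_ = int(obj.n_)
        obj.df_ = int(obj.df_)
        return obj

    def _check_fitted(self) -> None:
        if not hasattr(self, "slope_"):
            raise ValueError("this LogLogAllometry instance is not fitted yet")


# Alias: the fitted estimator carries everything a stored
# log-log fit needs (intercept, slope, residual scale, n, df, mean_logx, sxx).
LogLogFit = LogLogAllometry


def _diameter_grid(d_min: float, d_max: float, step: float) -> np.ndarray:
    if not d_min < d_max:
        raise ValueError("d_min must be less than d_max")
    if step <= 0:
        raise ValueError("step must be positive")
    # round-half-even on the count so e.g. [2.5, 7.5] at 0.01 gives 501 points
    n = int(round((d_max - d_min) / step)) + 1
    if n < 1:
        raise ValueError("empty diameter grid")
    return d_min + step * np.arange(n)


def fit_loglog(samples: Iterable[CalibSample]) -> LogLogAllometry:
    """Fit the log-log allometry from calibration samples."""
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError("at least 3 calibration samples are required")
    d = np.array([s.diameter_cm for s in samples], dtype=float)
    m = np.array([s.mass_kg for s in samples], dtype=float)
    return LogLogAllometry().fit(d, m)


def predict_log(fit: LogLogAllometry, diameter_cm):
    return fit.predict_log(diameter_cm)


def prediction_interval(fit: LogLogAllometry, diameter_cm, level: float = 0.95):
    return fit.prediction_interval(diameter_cm, level=level)


def prediction_band(fit: LogLogAllometry, d_min: float, d_max: float,
                    step: float = 0.01, level: float = 0.95) -> PredictionBand:
    return fit.band(d_min, d_max, step=step, level=level)


def band_overlap(band_a: PredictionBand, band_b: PredictionBand) -> float:
    """Mean fractional overlap of band_a's intervals by band_b's.

    At each grid diameter the overlap is the length of the intersection
    of the two prediction intervals divided by the length of band_a's
    interval; the returned value is the mean over the grid. A degenerate
    (zero-width) band_a interval counts as fully overlapped when it lies
    inside band_b's interval.
    """
    if band_a.grid_cm.shape != band_b.grid_cm.shape or not np.allclose(
        band_a.grid_cm, band_b.grid_cm
    ):
        raise ValueError("bands must share an identical diameter grid")
    lo = np.maximum(band_a.lwr_kg, band_b.lwr_kg)
    hi = np.minimum(band_a.upr_kg, band_b.upr_kg)
    inter = np.clip(hi - lo, 0.0, None)
    width_a = band_a.upr_kg - band_a.lwr_kg
    frac = np.empty_like(width_a)
    deg = width_a <= 0
    frac[~deg] = inter[~deg] / width_a[~deg]
    frac[deg] = (
        (band_a.lwr_kg[deg] >= band_b.lwr_kg[deg])
        & (band_a.lwr_kg[deg] <= band_b.upr_kg[deg])
    ).astype(float)
    return float(frac.mean())


def fit_pe_model(band: PredictionBand) -> PEModel:
    """Power-law fit of prediction-error width to diameter.

    Regresses ln(upr - lwr) on ln(D) over the band grid; the fitted
    relation PE = k * D**p is the uncertainty allometry the D_max
    decision rule integrates against the stem-diameter density.
    """
    width = band.uncertainty_kg
    if band.grid_cm.size < 2:
        raise ValueError("band needs at least 2 grid points")
    if np.any(width <= 0):
        raise ValueError("band has zero-width intervals; log(width) undefined")
    lx, ly = np.log(band.grid_cm), np.log(width)
    slope, intercept = np.polyfit(lx, ly, 1)
    return PEModel(k=float(np.exp(intercept)), p=float(slope))
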