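"""Conic-frustrum internode geometry and wet-density calibration.

A stem internode between two nodes is modeled as a regular conic
frustrum with end diameters D1, D2 and length L, giving volume

    V = pi * L * (D1**2 + D1*D2 + D2**2) / 12.

Wet field-mass of an internode is then density * V. The density is
calibrated from destructively sampled internodes either by a linear
regression of mass on volume (the slope is the wet density, kg/L) or by
a log-log regression of ln(mass) on ln(volume); a log-log slope of one
indicates proportionality through the origin, and exponentiating the
intercept recovers the wet density with a confidence interval.

Units: diameters and lengths in cm, volumes in cm^3 internally and
litres at the interface, masses in kg, densities in kg/L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CM3_PER_L",
    "InternodeSample",
    "DensityRegressor",
    "DensityFit",
    "frustrum_volume",
    "wet_density",
    "fit_density_linear",
    "fit_density_loglog",
    "density_ci",
]

CM3_PER_L = 1000.0


@dataclass(frozen=True)
class InternodeSample:
    """One cut, measured and weighed stem internode."""

    d1_cm: float
    d2_cm: float
    length_cm: float
    mass_kg: float
    taxon: str = ""

    def __post_init__(self) -> None:
        if not (self.d1_cm > 0 and self.d2_cm > 0 and self.length_cm > 0
                and self.mass_kg > 0):
            raise ValueError("internode dimensions and mass must be positive")

    @property
    def volume_l(self) -> float:
        return frustrum_volume(self.d1_cm, self.d2_cm, self.length_cm) / CM3_PER_L


def frustrum_volume(d1_cm, d2_cm, length_cm):
    """Volume (cm^3) of a conic frustrum with end diameters d1, d2 and length L.

    V = pi * L * (D1^2 + D1 D2 + D2^2) / 12; symmetric in (d1, d2),
    reducing to a cylinder when d1 == d2 and to a cone when one end is 0.
    """
    d1 = np.asarray(d1_cm, dtype=float)
    d2 = np.asarray(d2_cm, dtype=float)
    ln = np.asarray(length_cm, dtype=float)
    if np.any(d1 < 0) or np.any(d2 < 0) or np.any(ln <= 0):
        raise ValueError("diameters must be >= 0 and length > 0")
    if np.any((d1 == 0) & (d2 == 0)):
        raise ValueError("d1 and d2 cannot both be zero")
    v = np.pi * ln * (d1**2 + d1 * d2 + d2**2) / 12.0
    scalars = all(np.isscalar(a) for a in (d1_cm, d2_cm, length_cm))
    return float(v) if scalars else v


def wet_density(mass_kg: float, volume_l: float) -> float:
    """Wet density (kg/L) from a directly measured mass and volume."""
    if mass_kg <= 0 or volume_l <= 0:
        raise ValueError("mass and volume must be positive")
    return mass_kg / volume_l


class DensityRegressor(RegressorMixin, BaseEstimator):
    """Regression of internode mass on frustrum volume.

    Parameters
    ----------
    form : {"loglog", "linear"}
        "linear" fits mass = intercept + slope * volume with a free
        intercept; the slope estimates wet density (kg/L). "loglog"
        fits ln(mass) = intercept + slope * ln(volume); a slope near one
        supports proportionality, and exp(intercept) is the density.

    Fitted attributes: ``slope_``, ``slope_se_``, ``intercept_``,
    ``intercept_se_``, ``n_``, ``df_``, ``r2_``, ``residual_scale_``;
    for the loglog form also ``mean_logx_`` and ``sxx_`` (sufficient for
    prediction standard errors).
    """

    def __init__(self, form: str = "loglog"):
        self.form = form

    def fit(self, X, y):
        if self.form not in ("loglog", "linear"):
            raise ValueError(f"unknown form {self.form!r}")
        v = np.asarray(X, dtype=float).reshape(-1)
        m = np.asarray(y, dtype=float).reshape(-1)
        if v.size < 3:
            raise ValueError("at least 3 internodes are required")
        if np.any(v <= 0) or np.any(m <= 0):
            raise ValueError("volumes and masses must be positive")
        x = np.log(v) if self.form == "loglog" else v
        yy = np.log(m) if self.form == "loglog" else m
        sxx = float(np.sum((x - x.mean()) ** 2))
        if sxx <= 0:
            raise ValueError("volumes are degenerate (zero spread)")
        res = sm.OLS(yy, sm.add_constant(x)).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.intercept_se_ = float(res.bse[0])
        self.slope_se_ = float(res.bse[1])
        self.n_ = int(v.size)
        self.df_ = self.n_ - 2
        self.r2_ = float(res.rsquared)
        self.residual_scale_ = float(np.sqrt(res.ssr / self.df_))
        if self.form == "loglog":
            self.mean_logx_ = float(x.mean())
            self.sxx_ = sxx
        return self

    def predict_log(self, volume_l):
        """(mu, se_fit, se_pred) for ln(mass) at a volume, loglog form only."""
        self._check_fitted()
        if self.form != "loglog":
            raise ValueError("predict_log requires the loglog form")
        v = np.asarray(volume_l, dtype=float)
        if np.any(v <= 0):
            raise ValueError("volume must be positive")
        lx = np.log(v)
        mu = self.intercept_ + self.slope_ * lx
        se_fit = self.residual_scale_ * np.sqrt(
            1.0 / self.n_ + (lx - self.mean_logx_) ** 2 / self.sxx_
        )
        se_pred = np.sqrt(self.residual_scale_**2 + se_fit**2)
        return mu, se_fit, se_pred

    def predict(self, X):
        self._check_fitted()
        v = np.asarray(X, dtype=float).reshape(-1)
        if self.form == "loglog":
            mu, _, _ = self.predict_log(v)
            return np.exp(mu)
        return self.intercept_ + self.slope_ * v

    def density_ci(self, level: float = 0.95):
        """Wet-density CI from the loglog intercept, exp(a -/+ t*se)."""
        self._check_fitted()
        if self.form != "loglog":
            raise ValueError("density_ci requires the loglog form")
        return density_ci(self.intercept_, self.intercept_se_, self.df_, level)

    def to_dict(self) -> dict:
        self._check_fitted()
        keys = ["form", "intercept", "slope", "intercept_se", "slope_se",
                "n", "df", "r2", "residual_scale"]
        out = {"form": self.form}
        for k in keys[1:]:
            out[k] = getattr(self, k + "_")
        if self.form == "loglog":
            out["mean_logx"] = self.mean_logx_
            out["sxx"] = self.sxx_
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "DensityRegressor":
        obj = cls(form=d["form"])
        for k, v in d.items():
            if k != "form":
                setattr(obj, k + "_", v)
        obj.n_ = int(obj.n_)
        obj.df_ = int(obj.df_)
        return obj

    def _check_fitted(self) -> None:
        if not hasattr(self, "slope_"):
            raise ValueError("this DensityRegressor instance is not fitted yet")


DensityFit = DensityRegressor


def _volumes_masses(internodes: Iterable[InternodeSample]):
    internodes = list(internodes)
    if len(internodes) < 3:
        raise ValueError("at least 3 internode samples are required")
    v = np.array([s.volume_l for s in internodes])
    m = np.array([s.mass_kg for s in internodes])
    return v, m


def fit_density_linear(internodes: Iterable[InternodeSample]) -> DensityRegressor:
    """Linear mass-on-volume regression; the slope is wet density (kg/L)."""
    v, m = _volumes_masses(internodes)
    return DensityRegressor(form="linear").fit(v, m)


def fit_density_loglog(internodes: Iterable[InternodeSample]) -> DensityRegressor:
    """Log-log mass-on-volume regression (the default internode mass model)."""
    v, m = _volumes_masses(internodes)
    return DensityRegressor(form="loglog").fit(v, m)


def density_ci(intercept: float, intercept_se: float, df: int,
               level: float = 0.95):
    """Wet-density confidence interval exp(intercept -/+ t_{df} * se), kg/L."""
    if intercept_se < 0:
        raise ValueError("intercept_se must be non-negative")
    if df < 1:
        raise ValueError("df must be at least 1")
    tq = stats.t.ppf(1 - (1 - level) / 2, df)
    return (float(np.exp(intercept - tq * intercept_se)),
            float(np.exp(intercept + tq * intercept_se)))
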