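"""Choosing D_max: precision benefit versus measurement-time cost.

Prediction error of diameter-based allometry grows as a power law
PE = k * D**p with p > 2, so the expected per-stem prediction error
depends on the stand's stem-diameter distribution pdf(D):

    E[PE1] = integral pdf(x) * k * x**p dx        (single-component, all D)
    E[PE2] = integral_{x <= D_max} pdf(x) * k * x**p dx
                                                  (two-component; the frustrum
                                                   error above D_max is
                                                   negligible by comparison)

Both integrals are approximated as Riemann sums over a 512-point kernel
density of pilot stem diameters with increment dx = range/512. On the
cost side, a per-plot timing regression total = t0 + t1*n1 + t2*n2 gives
the mean times of single- (t1) and two-component (t2) measures; every
stem is first measured once, and only the fraction P(D > D_max) incurs
the extra frustrum work, so an average measurement under the
two-component protocol costs t1 + t2 * P(D > D_max).

A candidate D_max is acceptable when the precision gain at least pays
for the extra time:

    E[PE1] / E[PE2]  >=  (t2 * P(D > D_max) + t1) / t1
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .allometry import PEModel

__all__ = [
    "DiameterDensity",
    "TimeCostRegressor",
    "TimeCostFit",
    "DmaxEvaluation",
    "kde_diameters",
    "expected_pe",
    "fit_time_cost",
    "evaluate_dmax",
    "scan_dmax",
]

_GRID_N = 512


@dataclass
class DiameterDensity:
    """Kernel density of stem diameters on an equispaced 512-point grid.

    ``dx`` is the Riemann increment (grid range / 512) used by
    :func:`expected_pe`; the Riemann sum of ``y * dx`` is ~1.
    """

    x: np.ndarray
    y: np.ndarray
    dx: float
    bandwidth: float = float("nan")


@dataclass
class DmaxEvaluation:
    """Benefit/cost verdict for one candidate D_max."""

    d_max_cm: Optional[float]
    epe1_kg: float
    epe2_kg: float
    pe_ratio: float
    p_exceed: float
    e_t2_s: float
    expected_two_time_s: float
    time_ratio: float
    acceptable: bool


def kde_diameters(diameters: Sequence[float],
                  clip_at_zero: bool = False) -> DiameterDensity:
    """Gaussian kernel density with the classical rule-of-thumb bandwidth.

    bandwidth = 0.9 * min(sd, IQR/1.34) * n**(-1/5), evaluated on a
    512-point equispaced grid spanning [min - 3*bw, max + 3*bw]
    (optionally clipped at zero, since diameters are positive).
    Deterministic: the same input always yields the same grid.
    """
    d = np.asarray(diameters, dtype=float).reshape(-1)
    if d.size < 2:
        raise ValueError("at least 2 diameters are required")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    sd = float(np.std(d, ddof=1))
    iqr = float(np.subtract(*np.percentile(d, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("diameters have zero spread")
    bw = 0.9 * spread * d.size ** (-0.2)
    lo = d.min() - 3.0 * bw
    hi = d.max() + 3.0 * bw
    if clip_at_zero:
        lo = max(lo, 0.0)
    x = np.linspace(lo, hi, _GRID_N)
    # column-wise Gaussian kernel sum; n and grid are small enough to broadcast
    z = (x[:, None] - d[None, :]) / bw
    y = np.exp(-0.5 * z**2).sum(axis=1) / (d.size * bw * np.sqrt(2 * np.pi))
    dx = (hi - lo) / _GRID_N
    return DiameterDensity(x=x, y=y, dx=dx, bandwidth=bw)


def expected_pe(density: DiameterDensity, pe: PEModel,
                upper_cm: Optional[float] = None) -> float:
    """Expected per-stem prediction error (kg) by Riemann sum.

    Sums ``y_i * k * x_i**p * dx`` over the whole grid, or over grid
    diameters <= ``upper_cm`` for the two-component variant. Grid points
    at non-positive diameters (possible when the kernel tail crosses
    zero) contribute nothing. An ``upper_cm`` below the grid minimum
    returns 0 with a warning.
    """
    x, y = density.x, density.y
    mask = x > 0
    if upper_cm is not None:
        if upper_cm > x.max() + 1e-12:
            raise ValueError("upper_cm lies above the density grid range")
        if upper_cm < x.min():
            warnings.warn("upper_cm is below the density grid; E[PE] = 0",
                          stacklevel=2)
            return 0.0
        mask &= x <= upper_cm
    return float(np.sum(y[mask] * pe.k * x[mask] ** pe.p) * density.dx)


class TimeCostRegressor(RegressorMixin, BaseEstimator):
    """Per-plot timing regression total = t0 + t1*n_single + t2*n_two.

    Fitted attributes: ``t0_s_`` (per-plot overhead), ``t1_s_`` (mean
    time of a single-component measure), ``t2_s_`` (mean time of a
    two-component measure), ``sigma_s_`` (residual sd), ``r2_``,
    ``n_plots_``, and ``cov_params_`` (3x3 coefficient covariance).
    """

    def fit(self, X, y):
        counts = np.asarray(X, dtype=float)
        t = np.asarray(y, dtype=float).reshape(-1)
        if counts.ndim != 2 or counts.shape[1] != 2:
            raise ValueError("X must be (n_plots, 2): [n_single, n_two]")
        if counts.shape[0] != t.size:
            raise ValueError("X and y must have the same number of plots")
        if t.size < 4:
            raise ValueError("at least 4 plots are required")
        design = sm.add_constant(counts, has_constant="add")
        if np.linalg.matrix_rank(design) < 3:
            raise ValueError("timing design matrix is rank deficient")
        res = sm.OLS(t, design).fit()
        self.t0_s_ = float(res.params[0])
        self.t1_s_ = float(res.params[1])
        self.t2_s_ = float(res.params[2])
        self.n_plots_ = int(t.size)
        self.df_ = int(res.df_resid)
        self.sigma_s_ = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid else 0.0
        self.r2_ = float(res.rsquared)
        self.cov_params_ = np.asarray(res.cov_params())
        return self

    def predict(self, X):
        counts = np.asarray(X, dtype=float)
        return self.t0_s_ + self.t1_s_ * counts[:, 0] + self.t2_s_ * counts[:, 1]


TimeCostFit = TimeCostRegressor


def fit_time_cost(records) -> TimeCostRegressor:
    """Fit the timing regression from (total_time_s, n_single, n_two) rows.

    ``records`` may be an iterable of 3-tuples or a DataFrame with
    columns total_time_s, n_single, n_two.
    """
    if hasattr(records, "columns"):
        t = np.asarray(records["total_time_s"], dtype=float)
        counts = np.column_stack([np.asarray(records["n_single"], dtype=float),
                                  np.asarray(records["n_two"], dtype=float)])
    else:
        rows = [tuple(r) for r in records]
        t = np.array([r[0] for r in rows], dtype=float)
        counts = np.array([[r[1], r[2]] for r in rows], dtype=float)
    return TimeCostRegressor().fit(counts, t)


def evaluate_dmax(pe_ratio_or_components, t1_s: float, t2_s: float,
                  p_exceed: float,
                  d_max_cm: Optional[float] = None) -> DmaxEvaluation:
    """Benefit/cost decision for a candidate D_max.

    ``pe_ratio_or_components`` is either the precision-gain ratio
    E[PE1]/E[PE2] itself or the pair ``(epe1, epe2)``. The expected time
    of a two-component measure is ``t1 + t2 * p_exceed`` (every stem is
    measured once; only stems thicker than D_max incur the frustrum
    measurements), and the candidate is acceptable when
    pe_ratio >= time_ratio.
    """
    if t1_s <= 0 or t2_s < 0:
        raise ValueError("t1 must be positive and t2 non-negative")
    if not 0 <= p_exceed <= 1:
        raise ValueError("p_exceed must lie in [0, 1]")
    if isinstance(pe_ratio_or_components, (tuple, list)):
        epe1, epe2 = (float(v) for v in pe_ratio_or_components)
        if epe2 <= 0:
            raise ValueError("E[PE2] must be positive")
        pe_ratio = epe1 / epe2
    else:
        pe_ratio = float(pe_ratio_or_components)
        epe1 = epe2 = float("nan")
    e_t2 = t2_s * p_exceed
    expected_two = e_t2 + t1_s
    time_ratio = expected_two / t1_s
    return DmaxEvaluation(
        d_max_cm=d_max_cm, epe1_kg=epe1, epe2_kg=epe2, pe_ratio=pe_ratio,
        p_exceed=float(p_exceed), e_t2_s=float(e_t2),
        expected_two_time_s=float(expected_two), time_ratio=float(time_ratio),
        acceptable=bool(pe_ratio >= time_ratio),
    )


def scan_dmax(diameters: Sequence[float], pe: PEModel,
              time: TimeCostRegressor,
              candidates: Sequence[float],
              clip_at_zero: bool = False) -> list[DmaxEvaluation]:
    """Evaluate the decision rule over candidate D_max values.

    For each candidate, ``p_exceed`` is the empirical fraction of pilot
    diameters strictly greater than the candidate and E[PE2] truncates
    the Riemann sum at the candidate. Results are returned in candidate
    order.
    """
    cand = np.asarray(candidates, dtype=float)
    if cand.size == 0:
        raise ValueError("no candidate D_max values supplied")
    d = np.asarray(diameters, dtype=float).reshape(-1)
    if np.any(cand < d.min()) or np.any(cand > d.max()):
        raise ValueError("candidates must lie within the observed diameter range")
    density = kde_diameters(d, clip_at_zero=clip_at_zero)
    epe1 = expected_pe(density, pe)
    out = []
    for c in cand:
        p_exceed = float(np.mean(d > c))
        # at the top of the range no stem exceeds the candidate, the two
        # protocols coincide and the truncated integral equals the full one
        epe2 = epe1 if c >= d.max() else expected_pe(density, pe, upper_cm=float(c))
        out.append(evaluate_dmax((epe1, epe2), time.t1_s_, time.t2_s_,
                                 p_exceed, d_max_cm=float(c)))
    return out
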