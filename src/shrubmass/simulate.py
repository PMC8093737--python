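"""Synthetic shrubs, calibration datasets, plot inventories and timing records.

The generator embodies the statistical structure the estimation method
assumes, so the whole pipeline is testable end to end without field
data:

* shrub architecture is self-similar: above every node the cross-
  sectional area is split among children (pipe-model flavour, with
  Dirichlet jitter), and stems taper along internodes, so aerial tips
  are small copies of whole shrubs;
* tip wet mass follows the power-law allometry ``a * D**b`` with
  multiplicative lognormal noise;
* internode wet mass is wood density times conic-frustrum volume, again
  with lognormal noise;
* root-collar diameters are lognormal (truncated below at D_min);
* plot timing is linear in the counts of single- and two-component
  measures with Gaussian noise.

Every generated quantity carries its ground-truth value so coverage and
parameter-recovery checks can be run against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .estimator import StemSegment, decompose
from .geometry import CM3_PER_L, frustrum_volume

__all__ = ["SimConfig", "gen_shrub", "gen_destructive",
           "gen_plot_inventory", "gen_timing"]


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic world.

    Tip allometry (a=0.07, b=2.437), the D_min/D_max thresholds
    (2.5/7.5 cm) and the timing coefficients (t1=26 s, t2=111 s,
    sigma=543 s) default to published field values for Alaskan
    alder/willow stands; the remaining knobs are documented choices of
    plausible magnitude (see docs/methods.md).
    """

    # tip (and whole-small-shrub) allometry, kg vs cm
    tip_a: float = 0.07
    tip_b: float = 2.437
    tip_sdlog: float = 0.45
    # internode mass model
    density_kg_l: float = 0.9
    internode_sdlog: float = 0.10
    # architecture
    taper_rate: float = 0.0025          # fractional diameter loss per cm of stem
    internode_length_range: tuple[float, float] = (30.0, 120.0)
    branch_counts: tuple[int, ...] = (2, 3)
    branch_probs: tuple[float, ...] = (0.7, 0.3)
    split_concentration: float = 4.0    # Dirichlet jitter of the area split
    min_child_diameter_cm: float = 0.05
    # population
    drc_meanlog: float = 1.6            # median DRC ~ 5 cm
    drc_sdlog: float = 0.55
    d_min: float = 2.5
    d_max: float = 7.5
    mean_shrubs_per_plot: float = 84.0  # ~1,430 shrubs over 17 plots
    # timing study
    t0_s: float = 300.0
    t1_s: float = 26.0
    t2_s: float = 111.0
    time_sigma_s: float = 543.0
    mean_singles_per_plot: float = 92.0
    mean_twos_per_plot: float = 6.0
    count_cv: float = 0.6               # between-plot spread of shrub density

    def validate(self) -> None:
        if not (self.tip_a > 0 and self.tip_b > 0 and self.tip_sdlog >= 0):
            raise ValueError("tip allometry parameters must be positive")
        if not (self.density_kg_l > 0 and self.internode_sdlog >= 0):
            raise ValueError("density parameters must be positive")
        if not 0 < self.taper_rate < 1:
            raise ValueError("taper_rate must be in (0, 1)")
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be below d_max")
        if len(self.branch_counts) != len(self.branch_probs) or not np.isclose(
                sum(self.branch_probs), 1.0):
            raise ValueError("branch_probs must match branch_counts and sum to 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _draw_drc(cfg: SimConfig, rng: np.random.Generator) -> float:
    # truncated lognormal: every generated shrub is a tall shrub (DRC >= D_min)
    while True:
        d = float(rng.lognormal(cfg.drc_meanlog, cfg.drc_sdlog))
        if d >= cfg.d_min:
            return d


def _grow(cfg: SimConfig, rng: np.random.Generator, base_d: float) -> StemSegment:
    if base_d <= cfg.d_max:
        mass = cfg.tip_a * base_d**cfg.tip_b * float(
            np.exp(rng.normal(0.0, cfg.tip_sdlog)))
        return StemSegment(base_diameter_cm=base_d, true_mass_kg=mass)
    length = float(rng.uniform(*cfg.internode_length_range))
    top_d = base_d * (1.0 - cfg.taper_rate) ** length
    vol_l = frustrum_volume(base_d, top_d, length) / CM3_PER_L
    mass = cfg.density_kg_l * vol_l * float(
        np.exp(rng.normal(0.0, cfg.internode_sdlog)))
    k = int(rng.choice(cfg.branch_counts, p=cfg.branch_probs))
    weights = rng.dirichlet([cfg.split_concentration] * k)
    child_d = top_d * np.sqrt(weights)  # area-preserving split with jitter
    children = [_grow(cfg, rng, float(d)) for d in child_d
                if d > cfg.min_child_diameter_cm]
    return StemSegment(base_diameter_cm=base_d, top_diameter_cm=top_d,
                       length_cm=length, children=children, true_mass_kg=mass)


def gen_shrub(config: SimConfig, seed=0,
              drc_cm: Optional[float] = None) -> StemSegment:
    """Generate one shrub structure with ground-truth component masses.

    ``seed`` may be an int or a Generator; ``drc_cm`` fixes the
    root-collar diameter instead of drawing it.
    """
    config.validate()
    rng = _rng(seed)
    if drc_cm is None:
        drc_cm = _draw_drc(config, rng)
    if drc_cm <= 0:
        raise ValueError("drc_cm must be positive")
    return _grow(config, rng, float(drc_cm))


def gen_destructive(config: SimConfig, n_shrubs: int, seed=0):
    """Destructive calibration tables: (calibration_df, internode_df).

    Every generated shrub contributes a whole-shrub row (DRC, total
    true mass); shrubs larger than D_max are additionally dissected into
    aerial-tip rows and internode rows, emulating a destructive
    calibration campaign.
    """
    config.validate()
    if n_shrubs < 3:
        raise ValueError("at least 3 shrubs are required for calibration")
    rng = _rng(seed)
    calib_rows, internode_rows = [], []
    for i in range(n_shrubs):
        sid = f"S{i:04d}"
        drc = _draw_drc(config, rng)
        shrub = _grow(config, rng, drc)
        calib_rows.append({"shrub_id": sid, "taxon": "synthetic",
                           "role": "whole_shrub", "diameter_cm": drc,
                           "mass_kg": shrub.total_true_mass()})
        if drc > config.d_max:
            for seg in shrub.iter_segments():
                if seg.is_terminal:
                    calib_rows.append({
                        "shrub_id": sid, "taxon": "synthetic",
                        "role": "aerial_tip",
                        "diameter_cm": seg.base_diameter_cm,
                        "mass_kg": seg.true_mass_kg})
                else:
                    internode_rows.append({
                        "shrub_id": sid, "taxon": "synthetic",
                        "d1_cm": seg.base_diameter_cm,
                        "d2_cm": seg.top_diameter_cm,
                        "length_cm": seg.length_cm,
                        "mass_kg": seg.true_mass_kg})
    return pd.DataFrame(calib_rows), pd.DataFrame(internode_rows)


def gen_plot_inventory(config: SimConfig, n_plots: int, seed=0):
    """Field inventories for ``n_plots`` plots: (inventory_df, shrub_df).

    ``inventory_df`` holds the two-component measurements (one row per
    tip or frustrum, in field order); ``shrub_df`` has one row per shrub
    with its DRC and TRUE total biomass, so plot truth is
    ``shrub_df.groupby("plot_id").true_mass_kg.sum()``.
    """
    config.validate()
    if n_plots < 1:
        raise ValueError("n_plots must be at least 1")
    rng = _rng(seed)
    inv_rows, shrub_rows = [], []
    for p in range(n_plots):
        pid = f"P{p:03d}"
        n_shrubs = int(rng.poisson(config.mean_shrubs_per_plot))
        for i in range(n_shrubs):
            sid = f"{pid}-S{i:03d}"
            drc = _draw_drc(config, rng)
            shrub = _grow(config, rng, drc)
            comps = decompose(shrub, d_min=config.d_min, d_max=config.d_max,
                              shrub_id=sid, plot_id=pid)
            for seq, comp in enumerate(comps):
                inv_rows.append({"plot_id": pid, "shrub_id": sid,
                                 "component_seq": seq, "kind": comp.kind,
                                 "d1_cm": comp.d1_cm, "d2_cm": comp.d2_cm,
                                 "length_cm": comp.length_cm})
            shrub_rows.append({"plot_id": pid, "shrub_id": sid, "drc_cm": drc,
                               "true_mass_kg": shrub.total_true_mass()})
    return pd.DataFrame(inv_rows), pd.DataFrame(shrub_rows)


def gen_timing(config: SimConfig, n_plots: int, seed=0) -> pd.DataFrame:
    """Per-plot timing records total = t0 + t1*n1 + t2*n2 + N(0, sigma^2).

    Times are redrawn until positive (a plot cannot take negative time).
    """
    config.validate()
    if n_plots < 1:
        raise ValueError("n_plots must be at least 1")
    rng = _rng(seed)
    rows = []
    # plots differ in shrub density, so counts are gamma-mixed Poisson
    # (overdispersed) rather than plain Poisson
    shape = 1.0 / config.count_cv**2 if config.count_cv > 0 else None
    for p in range(n_plots):
        if shape is None:
            lam1, lam2 = config.mean_singles_per_plot, config.mean_twos_per_plot
        else:
            lam1 = rng.gamma(shape, config.mean_singles_per_plot / shape)
            lam2 = rng.gamma(shape, config.mean_twos_per_plot / shape)
        n1 = int(rng.poisson(lam1))
        n2 = int(rng.poisson(lam2))
        while True:
            total = (config.t0_s + config.t1_s * n1 + config.t2_s * n2
                     + float(rng.normal(0.0, config.time_sigma_s)))
            if total > 0:
                break
        rows.append({"plot_id": f"P{p:03d}", "total_time_s": total,
                     "n_single": n1, "n_two": n2})
    return pd.DataFrame(rows)
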