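"""Two-component field algorithm: decomposing shrubs and estimating components.

A tall shrub is measured as a tree of stem segments. Walking up from the
root collar:

1. Record the stem diameter D1.
2. If D1 <= D_max the whole stem above is one aerial tip, predicted by
   tip allometry from that single diameter — stop.
3. Otherwise the internode up to the next node is a conic frustrum:
   record its length L and end diameters D1 and D2 (D2 just below the
   upper node swelling), and repeat for every stem above the node.

Shrubs whose root-collar diameter falls below D_min are not tall shrubs
and are excluded. Each measured component is converted to a predictive
distribution of log wet mass: tips through the tip allometry, frustra
through the internode log-log mass-volume model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .allometry import LogLogAllometry
from .geometry import CM3_PER_L, DensityRegressor, frustrum_volume

__all__ = [
    "StemSegment",
    "Component",
    "ComponentEstimate",
    "ExtrapolationWarning",
    "decompose",
    "estimate_components",
    "single_component_estimates",
    "segment_to_dict",
    "segment_from_dict",
]


class ExtrapolationWarning(UserWarning):
    """A prediction was requested outside the calibration diameter range."""


@dataclass
class StemSegment:
    """A stem segment between nodes, with the segments above the node.

    Terminal segments (aerial tips) carry only a base diameter; internal
    segments additionally have a top diameter, a length, and children.
    ``true_mass_kg``, when present, is the simulator's ground-truth wet
    mass of this segment's own component (the whole tip for terminal
    segments, the internode wood for internal ones).
    """

    base_diameter_cm: float
    top_diameter_cm: Optional[float] = None
    length_cm: Optional[float] = None
    children: list["StemSegment"] = field(default_factory=list)
    true_mass_kg: Optional[float] = None

    @property
    def is_terminal(self) -> bool:
        return self.top_diameter_cm is None

    def iter_segments(self) -> Iterator["StemSegment"]:
        yield self
        for child in self.children:
            yield from child.iter_segments()

    def total_true_mass(self) -> float:
        """Sum of attached ground-truth masses over the whole structure."""
        total = 0.0
        for seg in self.iter_segments():
            if seg.true_mass_kg is None:
                raise ValueError("segment without attached true mass")
            total += seg.true_mass_kg
        return total


@dataclass
class Component:
    """A field-measured piece of a shrub: an aerial tip or a frustrum."""

    kind: str  # "tip" or "frustrum"
    d1_cm: float
    d2_cm: Optional[float] = None
    length_cm: Optional[float] = None
    shrub_id: Optional[str] = None
    plot_id: Optional[str] = None


@dataclass
class ComponentEstimate:
    """Predictive log-mass distribution and point estimate for a component."""

    component: Component
    mu_log_kg: float
    se_log: float
    point_kg: float


def decompose(shrub: StemSegment, d_min: float = 2.5, d_max: float = 7.5,
              shrub_id: Optional[str] = None,
              plot_id: Optional[str] = None) -> list[Component]:
    """Apply the field algorithm to one rooted stem.

    Returns the components in depth-first order: a segment with base
    diameter <= d_max becomes a single tip (D1 = d_max counts as a tip);
    a larger segment contributes a frustrum and the walk continues into
    its children. A root-collar diameter below d_min returns no
    components (the plant is not a tall shrub).
    """
    if d_min > d_max:
        raise ValueError("d_min must not exceed d_max")
    if shrub.base_diameter_cm < d_min:
        return []
    out: list[Component] = []
    _walk(shrub, d_max, out, shrub_id, plot_id)
    return out


def _walk(seg: StemSegment, d_max: float, out: list[Component],
          shrub_id, plot_id) -> None:
    if seg.base_diameter_cm <= 0:
        raise ValueError("segment with non-positive base diameter")
    if seg.base_diameter_cm <= d_max:
        out.append(Component("tip", seg.base_diameter_cm,
                             shrub_id=shrub_id, plot_id=plot_id))
        return
    if seg.top_diameter_cm is None or seg.length_cm is None:
        raise ValueError(
            f"segment with base diameter {seg.base_diameter_cm} cm exceeds "
            f"D_max={d_max} but has no top diameter/length to measure as a frustrum"
        )
    out.append(Component("frustrum", seg.base_diameter_cm, seg.top_diameter_cm,
                         seg.length_cm, shrub_id=shrub_id, plot_id=plot_id))
    for child in seg.children:
        _walk(child, d_max, out, shrub_id, plot_id)


def estimate_components(components: Iterable[Component],
                        tip_fit: LogLogAllometry,
                        internode_fit: DensityRegressor
                        ) -> list[ComponentEstimate]:
    """Predictive log-mass for each component.

    Tips use the tip allometry at their basal diameter; frustra are
    converted to volume (litres) and passed through the internode
    log-log mass-volume model. The reported ``se_log`` is the full
    prediction standard error (residual scale plus estimation error in
    quadrature). Tip diameters outside the tip fit's calibration range
    trigger an ExtrapolationWarning, not an error.
    """
    out: list[ComponentEstimate] = []
    for comp in components:
        if comp.kind == "tip":
            if tip_fit is None:
                raise ValueError("tip components require a tip allometry fit")
            rng = getattr(tip_fit, "diameter_range_", None)
            if rng is not None and not (rng[0] <= comp.d1_cm <= rng[1]):
                warnings.warn(
                    f"tip diameter {comp.d1_cm:.2f} cm outside calibration "
                    f"range [{rng[0]:.2f}, {rng[1]:.2f}] cm",
                    ExtrapolationWarning, stacklevel=2,
                )
            mu, _, se_pred = tip_fit.predict_log(comp.d1_cm)
        elif comp.kind == "frustrum":
            if internode_fit is None:
                raise ValueError("frustrum components require an internode fit")
            vol_l = frustrum_volume(comp.d1_cm, comp.d2_cm, comp.length_cm) / CM3_PER_L
            mu, _, se_pred = internode_fit.predict_log(vol_l)
        else:
            raise ValueError(f"unknown component kind {comp.kind!r}")
        out.append(ComponentEstimate(comp, float(mu), float(se_pred),
                                     float(np.exp(mu))))
    return out


def single_component_estimates(drc_list: Sequence[float],
                               whole_fit: LogLogAllometry,
                               shrub_ids: Optional[Sequence[str]] = None,
                               plot_id: Optional[str] = None
                               ) -> list[ComponentEstimate]:
    """One whole-shrub estimate per DRC, regardless of shrub size."""
    drc = np.asarray(drc_list, dtype=float)
    if drc.size == 0:
        return []
    if np.any(drc <= 0):
        raise ValueError("DRC values must be positive")
    if shrub_ids is None:
        shrub_ids = [None] * drc.size
    out = []
    for d, sid in zip(drc, shrub_ids):
        comp = Component("tip", float(d), shrub_id=sid, plot_id=plot_id)
        mu, _, se_pred = whole_fit.predict_log(d)
        out.append(ComponentEstimate(comp, float(mu), float(se_pred),
                                     float(np.exp(mu))))
    return out


def segment_to_dict(seg: StemSegment) -> dict:
    """Nested-dict (JSON-ready) form of a stem structure."""
    d: dict = {"base_diameter_cm": seg.base_diameter_cm}
    if not seg.is_terminal:
        d["top_diameter_cm"] = seg.top_diameter_cm
        d["length_cm"] = seg.length_cm
        d["children"] = [segment_to_dict(c) for c in seg.children]
    if seg.true_mass_kg is not None:
        d["true_mass_kg"] = seg.true_mass_kg
    return d


def segment_from_dict(d: dict) -> StemSegment:
    return StemSegment(
        base_diameter_cm=d["base_diameter_cm"],
        top_diameter_cm=d.get("top_diameter_cm"),
        length_cm=d.get("length_cm"),
        children=[segment_from_dict(c) for c in d.get("children", [])],
        true_mass_kg=d.get("true_mass_kg"),
    )
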