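"""CSV and JSON round-tripping for calibration data, inventories and models.

All CSVs are comma-separated UTF-8 with a required header row and "."
decimals. Fitted models are stored as JSON (nested structure); rounding
happens only at presentation, never in stored values.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .allometry import CalibSample, LogLogAllometry
from .estimator import Component
from .geometry import DensityRegressor, InternodeSample
from .propagation import PlotBiomass

__all__ = [
    "read_calibration", "read_internodes", "read_inventory", "read_timing",
    "read_diameters", "write_plot_biomass", "save_models", "load_models",
]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_calibration(path) -> list[CalibSample]:
    """Read destructive calibration samples (tips and whole shrubs)."""
    df = pd.read_csv(path)
    _require_columns(df, ["shrub_id", "role", "diameter_cm", "mass_kg"], path)
    samples = []
    for idx, row in df.iterrows():
        try:
            samples.append(CalibSample(
                diameter_cm=float(row["diameter_cm"]),
                mass_kg=float(row["mass_kg"]),
                role=str(row["role"]),
                taxon=str(row.get("taxon", "")),
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad calibration row {idx}: {exc}") from exc
    return samples


def read_internodes(path) -> list[InternodeSample]:
    df = pd.read_csv(path)
    _require_columns(df, ["shrub_id", "d1_cm", "d2_cm", "length_cm", "mass_kg"],
                     path)
    samples = []
    for idx, row in df.iterrows():
        try:
            samples.append(InternodeSample(
                d1_cm=float(row["d1_cm"]), d2_cm=float(row["d2_cm"]),
                length_cm=float(row["length_cm"]), mass_kg=float(row["mass_kg"]),
                taxon=str(row.get("taxon", "")),
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad internode row {idx}: {exc}") from exc
    return samples


def read_inventory(path) -> dict[str, list[Component]]:
    """Plot inventory CSV -> {plot_id: [Component, ...]} in file order."""
    df = pd.read_csv(path)
    _require_columns(df, ["plot_id", "shrub_id", "kind", "d1_cm"], path)
    plots: dict[str, list[Component]] = {}
    for idx, row in df.iterrows():
        kind = str(row["kind"])
        if kind not in ("tip", "frustrum"):
            raise ValueError(f"{path}: row {idx}: unknown component kind {kind!r}")
        d2 = row.get("d2_cm")
        length = row.get("length_cm")
        comp = Component(
            kind=kind, d1_cm=float(row["d1_cm"]),
            d2_cm=None if pd.isna(d2) else float(d2),
            length_cm=None if pd.isna(length) else float(length),
            shrub_id=str(row["shrub_id"]), plot_id=str(row["plot_id"]),
        )
        if kind == "frustrum" and (comp.d2_cm is None or comp.length_cm is None):
            raise ValueError(f"{path}: row {idx}: frustrum needs d2_cm and length_cm")
        plots.setdefault(comp.plot_id, []).append(comp)
    return plots


def read_timing(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["plot_id", "total_time_s", "n_single", "n_two"], path)
    return df


def read_diameters(path) -> np.ndarray:
    df = pd.read_csv(path)
    _require_columns(df, ["diameter_cm"], path)
    d = df["diameter_cm"].to_numpy(dtype=float)
    if d.size == 0:
        raise ValueError(f"{path}: no diameters")
    return d


def write_plot_biomass(path, records: Iterable[PlotBiomass]) -> None:
    rows = [{"plot_id": r.plot_id, "method": r.method, "point_kg": r.point_kg,
             "ci_lwr_kg": r.ci_lwr_kg, "ci_upr_kg": r.ci_upr_kg,
             "uncertainty_kg": r.uncertainty_kg, "n_draws": r.n_draws,
             "seed": r.seed} for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_models(path, models: dict) -> None:
    """Serialise a dict of fitted models (LogLogAllometry / DensityRegressor)."""
    payload = {}
    for name, model in models.items():
        payload[name] = {"type": type(model).__name__, **model.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_models(path) -> dict:
    payload = json.loads(Path(path).read_text())
    out = {}
    for name, entry in payload.items():
        entry = dict(entry)
        kind = entry.pop("type")
        if kind == "LogLogAllometry":
            out[name] = LogLogAllometry.from_dict(entry)
        elif kind == "DensityRegressor":
            out[name] = DensityRegressor.from_dict(entry)
        else:
            raise ValueError(f"{path}: unknown model type {kind!r} for {name!r}")
    return out
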