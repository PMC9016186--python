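"""Daily dose-verification workflow: recalculate the fixed plan on serial
images, compute DVH metrics, compare to thresholds, and trend fractions."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids_io import ImageGrid, RigidTransform, StructureMask, resample_rigid
from .hu_density import (
    HUDensityTable,
    RSPTable,
    apply_density_overrides,
    density_from_hu,
    rsp_from_density,
)
from .proton_sim import BeamSpec, BraggModel, compute_beam_dose

__all__ = ["DVHCurve", "VerificationReport", "compute_dvh", "dvh_metric",
           "verify_daily", "batch_report"]


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram for one structure on one dose grid.

    ``cum_volume_pct[i]`` is the percent of the structure volume receiving at
    least ``edges_cgy[i]``; it starts at 100 at dose 0 and is monotone
    non-increasing, reaching 0 beyond the maximum dose.
    """

    structure: str
    edges_cgy: np.ndarray
    cum_volume_pct: np.ndarray
    total_volume_cm3: float
    bin_width_cgy: float

    def __post_init__(self) -> None:
        self.edges_cgy = np.asarray(self.edges_cgy, dtype=float)
        self.cum_volume_pct = np.asarray(self.cum_volume_pct, dtype=float)
        if self.cum_volume_pct[0] != 100.0:
            raise ValueError("cumulative volume must start at 100% at dose 0")
        if np.any(np.diff(self.cum_volume_pct) > 1e-9):
            raise ValueError("cumulative DVH must be monotone non-increasing")
        if self.cum_volume_pct[-1] != 0.0:
            raise ValueError("cumulative DVH must end at 0% beyond the max dose")

    def volume_at(self, dose_cgy: float) -> float:
        """Linear interpolation of the cumulative curve at a dose level."""
        return float(np.interp(dose_cgy, self.edges_cgy, self.cum_volume_pct))


def compute_dvh(dose: ImageGrid, mask: StructureMask,
                bin_width_cgy: float = 1.0) -> DVHCurve:
    """Cumulative DVH over the masked voxels (volume = voxel count × volume)."""
    if dose.quantity != "dose":
        raise ValueError("expected a dose grid")
    if mask.mask.shape != dose.shape or not mask.grid.same_geometry(dose):
        raise ValueError("mask geometry does not match the dose grid")
    if mask.voxel_count == 0:
        raise ValueError(f"structure {mask.name!r} mask is empty")
    doses = dose.values[mask.mask]
    n_bins = int(np.ceil((doses.max() + bin_width_cgy) / bin_width_cgy)) + 1
    edges = bin_width_cgy * np.arange(n_bins + 1)
    # fraction of voxels with dose >= edge
    cum = 100.0 * (1.0 - np.searchsorted(np.sort(doses), edges, side="left") / doses.size)
    cum[0] = 100.0
    voxel_cm3 = float(np.prod(dose.spacing)) / 1000.0
    return DVHCurve(structure=mask.name, edges_cgy=edges, cum_volume_pct=cum,
                    total_volume_cm3=doses.size * voxel_cm3,
                    bin_width_cgy=bin_width_cgy)


def dvh_metric(curve: DVHCurve, metric: str, prescription_cgy: float) -> float:
    """Evaluate ``Vx%`` (volume receiving ≥ x% of prescription, %), ``Dmean``
    or ``Dmax`` (cGy) from a DVH curve."""
    token = metric.strip()
    if token.lower().startswith("v") and token.endswith("%"):
        x = float(token[1:-1])
        return curve.volume_at(x / 100.0 * prescription_cgy)
    if token.lower() == "dmean":
        # integrate the differential histogram implied by the cumulative curve
        drop = -np.diff(curve.cum_volume_pct) / 100.0
        centers = 0.5 * (curve.edges_cgy[:-1] + curve.edges_cgy[1:])
        return float(np.sum(drop * centers))
    if token.lower() == "dmax":
        nonzero = np.nonzero(curve.cum_volume_pct > 0)[0]
        return float(curve.edges_cgy[nonzero[-1]])
    raise ValueError(f"unknown DVH metric token {metric!r}")


@dataclass
class VerificationReport:
    """Per-fraction verification outcome, losslessly (de)serializable."""

    fraction: str
    modality: str
    prescription_cgy: float
    metrics: dict = field(default_factory=dict)   # structure -> metric -> value
    flags: list = field(default_factory=list)     # dicts with metric/threshold/triggered
    provenance: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        doc = {
            "fraction": self.fraction,
            "modality": self.modality,
            "prescription_cgy": self.prescription_cgy,
            "metrics": self.metrics,
            "flags": self.flags,
            "provenance": self.provenance,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "VerificationReport":
        text = Path(source).read_text() if isinstance(source, (str, Path)) \
            and "\n" not in str(source) and Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(fraction=doc["fraction"], modality=doc["modality"],
                   prescription_cgy=doc["prescription_cgy"],
                   metrics=doc["metrics"], flags=doc["flags"],
                   provenance=doc["provenance"])


DEFAULT_THRESHOLDS = [("target", "V100%", ">=", 95.0)]


def _beam_footprint_corners(beam: BeamSpec, planning: ImageGrid) -> np.ndarray:
    """Corners (mm) of the box the beam must traverse in the planning frame:
    lateral spot extent ±2σ by the full depth extent of the grid."""
    ua, va = beam.in_plane_axes
    us = [s.lateral_mm[0] for s in beam.spots]
    vs = [s.lateral_mm[1] for s in beam.spots]
    pad = 2.0 * max(s.sigma_lat_mm for s in beam.spots)
    ulo, uhi = min(us) - pad, max(us) + pad
    vlo, vhi = min(vs) - pad, max(vs) + pad
    dlo, dhi = planning.extent(beam.axis)
    corners = []
    for u in (ulo, uhi):
        for v in (vlo, vhi):
            for d in (dlo, dhi):
                p = np.zeros(3)
                p[ua], p[va], p[beam.axis] = u, v, d
                corners.append(p)
    return np.array(corners)


def verify_daily(planning_geometry: ImageGrid, daily_image: ImageGrid,
                 transform: RigidTransform, table: HUDensityTable,
                 rsp_table: RSPTable, beam: BeamSpec,
                 structures: dict[str, StructureMask],
                 target_name: str = "target",
                 prescription_cgy: float = 200.0,
                 thresholds: list[tuple[str, str, str, float]] | None = None,
                 overrides: list[tuple[StructureMask, float]] | None = None,
                 model: BraggModel | None = None,
                 fraction: str = "fx", bin_width_cgy: float = 1.0) -> VerificationReport:
    """Recalculate the fixed plan on a rigidly aligned daily image and grade it.

    The daily image is resampled onto the planning geometry through
    ``transform`` (daily frame → planning frame), converted with the
    modality's HU-D table, and the unmodified beam is recomputed. The target
    structure reports V100%; all other structures report Dmean and Dmax.
    Default flag: target V100% < 95%.

    Raises if the beam's lateral footprint and depth extent do not map inside
    the daily image's field of view (the entire beam path must be imaged).
    """
    corners = _beam_footprint_corners(beam, planning_geometry)
    in_daily = transform.inverse().apply(corners)
    for ax in range(3):
        lo, hi = daily_image.extent(ax)
        if in_daily[:, ax].min() < lo - daily_image.spacing[ax] or \
                in_daily[:, ax].max() > hi + daily_image.spacing[ax]:
            raise ValueError(
                "beam path exits the daily image field of view on axis "
                f"{ax}: the entire beam path needs to be included in the FOV")

    aligned = resample_rigid(daily_image, transform, planning_geometry)
    density = density_from_hu(aligned, table)
    if overrides:
        density = apply_density_overrides(density, overrides)
    rsp = rsp_from_density(density, rsp_table)
    dose = compute_beam_dose(beam, rsp, model)

    metrics: dict[str, dict[str, float]] = {}
    for name, mask in structures.items():
        curve = compute_dvh(dose, mask, bin_width_cgy)
        if name == target_name:
            metrics[name] = {"V100%": dvh_metric(curve, "V100%", prescription_cgy)}
        else:
            metrics[name] = {
                "Dmean": dvh_metric(curve, "Dmean", prescription_cgy),
                "Dmax": dvh_metric(curve, "Dmax", prescription_cgy),
            }

    if thresholds is None:
        thresholds = [(target_name, "V100%", ">=", 95.0)]
    flags = []
    for struct, metric, op, limit in thresholds:
        value = metrics.get(struct, {}).get(metric)
        if value is None:
            continue
        ok = value >= limit if op == ">=" else value <= limit
        flags.append({"structure": struct, "metric": metric, "threshold": limit,
                      "comparison": op, "value": value, "triggered": not ok})

    return VerificationReport(
        fraction=fraction,
        modality=table.modality,
        prescription_cgy=float(prescription_cgy),
        metrics=metrics,
        flags=flags,
        provenance={
            "table_modality": table.modality,
            "transform": transform.matrix.tolist(),
            "n_spots": len(beam.spots),
            "bin_width_cgy": bin_width_cgy,
            "target": target_name,
        },
    )


def batch_report(reports: list[VerificationReport]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-fraction metric table plus a modality-stratified min/max/worst
    summary. Rejects mixed prescriptions."""
    if not reports:
        raise ValueError("need at least one report")
    rx = {r.prescription_cgy for r in reports}
    if len(rx) > 1:
        raise ValueError(f"mixed prescription values across reports: {sorted(rx)}")

    rows = []
    for r in reports:
        row = {"fraction": r.fraction, "modality": r.modality}
        for struct, md in r.metrics.items():
            for metric, value in md.items():
                row[f"{struct}:{metric}"] = value
        rows.append(row)
    table = pd.DataFrame(rows)

    metric_cols = [c for c in table.columns if c not in ("fraction", "modality")]
    summaries = []
    for modality, grp in table.groupby("modality"):
        for col in metric_cols:
            vals = grp[col].dropna()
            if vals.empty:
                continue
            worst_is_min = col.endswith("V100%") or ":V" in col
            worst_idx = vals.idxmin() if worst_is_min else vals.idxmax()
            summaries.append({
                "modality": modality, "metric": col, "n": len(vals),
                "min": vals.min(), "max": vals.max(),
                "worst_fraction": grp.loc[worst_idx, "fraction"],
            })
    return table, pd.DataFrame(summaries)
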