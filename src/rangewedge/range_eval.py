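"""Depth-sweep range-error estimation.

Candidate 2D planes are extracted from the 3D dose at 1-mm spacing around the
physical detector depth, gamma-compared against the measurement (always the
reference), and the best-matching depth — passing-rate maximum with parabolic
sub-step refinement — is converted to a percentage range error normalized by
the central-axis water-equivalent depth of the detector plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gamma import GammaParams, gamma_map
from .grids_io import ImageGrid, PlanarDose, StructureMask, sample_points
from .hu_density import (
    HUDensityTable,
    RSPTable,
    apply_density_overrides,
    density_from_hu,
    rsp_from_density,
)
from .proton_sim import BeamSpec, BraggModel, compute_beam_dose, wepl_profile

__all__ = ["RangeSweepResult", "extract_plane", "sweep_depths", "best_match",
           "percent_range_error", "evaluate_range_uncertainty"]


@dataclass
class RangeSweepResult:
    """Gamma passing rate vs candidate depth and the refined best estimate."""

    depths_mm: np.ndarray
    pass_rates_pct: np.ndarray
    physical_depth_mm: float
    wepl_to_detector_mm: float
    range_errors_pct: np.ndarray = field(default=None)  # per candidate depth
    best_depth_mm: float = float("nan")
    best_range_error_pct: float = float("nan")
    low_confidence: bool = False
    degenerate: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depths_mm = np.asarray(self.depths_mm, dtype=float)
        self.pass_rates_pct = np.asarray(self.pass_rates_pct, dtype=float)
        if np.any(np.diff(self.depths_mm) <= 0):
            raise ValueError("candidate depths must be strictly increasing")
        if np.any((self.pass_rates_pct < 0) | (self.pass_rates_pct > 100)):
            raise ValueError("passing rates must be in [0, 100]")
        if self.range_errors_pct is None:
            self.range_errors_pct = (100.0 * (self.depths_mm - self.physical_depth_mm)
                                     / self.wepl_to_detector_mm)


def extract_plane(dose: ImageGrid, axis: int, depth_mm: float,
                  lattice: PlanarDose | tuple | None = None) -> PlanarDose:
    """Trilinear extraction of a 2D dose plane at a given depth.

    ``lattice`` supplies the in-plane sampling geometry: a PlanarDose (its
    lattice is copied — the default for comparing against a measurement) or a
    ``(origin2, spacing2, shape2)`` tuple. In-plane points outside the grid
    are filled with 0 dose.
    """
    if dose.quantity != "dose":
        raise ValueError("expected a dose grid")
    lo, hi = dose.extent(axis)
    if not (lo <= depth_mm <= hi):
        raise ValueError(f"depth {depth_mm} mm outside grid extent [{lo}, {hi}] mm")
    ua, va = (a for a in (0, 1, 2) if a != axis)
    if lattice is None:
        origin2 = np.array([dose.origin[ua], dose.origin[va]])
        spacing2 = np.array([dose.spacing[ua], dose.spacing[va]])
        shape2 = (dose.shape[ua], dose.shape[va])
    elif isinstance(lattice, PlanarDose):
        origin2 = lattice.in_plane_origin.copy()
        spacing2 = lattice.in_plane_spacing.copy()
        shape2 = lattice.values.shape
    else:
        origin2, spacing2, shape2 = lattice
        origin2 = np.asarray(origin2, dtype=float)
        spacing2 = np.asarray(spacing2, dtype=float)
    u = origin2[0] + spacing2[0] * np.arange(shape2[0])
    v = origin2[1] + spacing2[1] * np.arange(shape2[1])
    uu, vv = np.meshgrid(u, v, indexing="ij")
    pts = np.zeros(uu.shape + (3,))
    pts[..., ua] = uu
    pts[..., va] = vv
    pts[..., axis] = depth_mm
    values = np.clip(sample_points(dose, pts), 0.0, None)
    return PlanarDose(plane_axis=axis, depth=float(depth_mm),
                      in_plane_origin=origin2, in_plane_spacing=spacing2,
                      values=values)


def _fine_lattice_for(measurement: PlanarDose, dose: ImageGrid, axis: int,
                      pad_mm: float) -> tuple:
    """In-plane lattice at the dose grid's resolution covering the
    measurement extent (padded by the gamma search radius)."""
    ua, va = (a for a in (0, 1, 2) if a != axis)
    sp = np.array([dose.spacing[ua], dose.spacing[va]])
    nu, nv = measurement.values.shape
    lo = measurement.in_plane_origin - pad_mm
    hi = measurement.in_plane_origin + measurement.in_plane_spacing * \
        np.array([nu - 1, nv - 1]) + pad_mm
    shape2 = tuple(int(np.floor((hi[k] - lo[k]) / sp[k])) + 1 for k in range(2))
    return (lo, sp, shape2)


def sweep_depths(measurement: PlanarDose, dose: ImageGrid,
                 window_mm: float = 10.0, step_mm: float = 1.0,
                 params: GammaParams | None = None,
                 wepl_to_detector_mm: float | None = None) -> RangeSweepResult:
    """Gamma passing rate of candidate planes vs depth around the detector.

    Candidate planes at ``measurement.depth ± window`` in ``step`` increments
    are extracted on a fine lattice at the dose grid's in-plane resolution
    (the calculated dose keeps its full resolution; the coarse-pitch
    measurement is always the gamma reference). Deterministic.
    """
    if params is None:
        params = GammaParams()
    axis = measurement.plane_axis
    lo, hi = dose.extent(axis)
    d0 = measurement.depth
    if not (lo <= d0 - window_mm and d0 + window_mm <= hi):
        raise ValueError(
            f"sweep window [{d0 - window_mm}, {d0 + window_mm}] mm outside "
            f"dose grid extent [{lo}, {hi}] mm")
    n = int(round(window_mm / step_mm))
    depths = d0 + step_mm * np.arange(-n, n + 1)
    lattice = _fine_lattice_for(measurement, dose, axis,
                                pad_mm=params.search_radius_factor * params.dta_mm)
    rates = np.empty(depths.size)
    for i, depth in enumerate(depths):
        plane = extract_plane(dose, axis, depth, lattice)
        rates[i] = gamma_map(measurement, plane, params).pass_rate_pct
    wepl = float("nan") if wepl_to_detector_mm is None else float(wepl_to_detector_mm)
    result = RangeSweepResult(
        depths_mm=depths, pass_rates_pct=rates,
        physical_depth_mm=d0,
        wepl_to_detector_mm=wepl if np.isfinite(wepl) else 1.0,
        degenerate=bool(np.ptp(rates) < 1e-12),
        provenance={"gamma_params": vars(params) if not hasattr(params, "__dataclass_fields__")
                    else {k: getattr(params, k) for k in params.__dataclass_fields__},
                    "step_mm": step_mm, "window_mm": window_mm},
    )
    if wepl_to_detector_mm is None:
        result.wepl_to_detector_mm = float("nan")
        result.range_errors_pct = np.full(depths.size, np.nan)
    return result


def best_match(sweep: RangeSweepResult) -> float:
    """Refined best-matching depth (mm) from a passing-rate sweep.

    The peak candidate is refined by a parabolic fit through it and its two
    neighbors when it is interior and strictly above them; a plateau of equal
    maxima returns the plateau midpoint with ``sweep.low_confidence`` set.
    Updates ``sweep.best_depth_mm`` / ``best_range_error_pct`` in place.
    """
    d = sweep.depths_mm
    r = sweep.pass_rates_pct
    if d.size < 3:
        raise ValueError("sweep needs at least 3 candidate depths")
    if np.ptp(r) < 1e-12:
        raise ValueError("all passing rates equal: gradient-free comparison "
                         "carries no range information")
    peak = float(r.max())
    ties = np.nonzero(np.abs(r - peak) < 1e-9)[0]
    if ties.size > 1:
        best = float(0.5 * (d[ties[0]] + d[ties[-1]]))
        sweep.low_confidence = True
    else:
        i = int(ties[0])
        if 0 < i < d.size - 1:
            denom = r[i - 1] - 2 * r[i] + r[i + 1]
            offset = 0.5 * (r[i - 1] - r[i + 1]) / denom if abs(denom) > 1e-12 else 0.0
            best = float(d[i] + np.clip(offset, -1.0, 1.0) * (d[i + 1] - d[i]))
        else:
            best = float(d[i])
            sweep.low_confidence = True
    sweep.best_depth_mm = best
    if np.isfinite(sweep.wepl_to_detector_mm):
        sweep.best_range_error_pct = percent_range_error(
            best, sweep.physical_depth_mm, sweep.wepl_to_detector_mm)
    return best


def percent_range_error(best_depth_mm: float, physical_depth_mm: float,
                        wepl_to_detector_mm: float) -> float:
    """ε = 100·(best − physical)/WEPL.

    Positive ε means the calculation overestimates range: the measured
    pattern is found at a deeper calculated plane than the physical one.
    """
    if not wepl_to_detector_mm > 0:
        raise ValueError("WEPL to detector must be positive")
    return 100.0 * (best_depth_mm - physical_depth_mm) / wepl_to_detector_mm


def central_axis_wepl(rsp: ImageGrid, axis: int, entry: str, depth_mm: float,
                      lateral_mm: tuple[float, float]) -> float:
    """WEPL from the entry surface to ``depth_mm`` along one beam ray.

    The entry surface is the first voxel along the ray with RSP > 0.05 (skips
    the air upstream of the phantom); air contributes its true, tiny RSP.
    """
    ua, va = (a for a in (0, 1, 2) if a != axis)
    w = wepl_profile(rsp, axis, entry)
    n = rsp.shape[axis]
    pts = np.zeros((n, 3))
    pts[:, ua] = lateral_mm[0]
    pts[:, va] = lateral_mm[1]
    pts[:, axis] = rsp.axis_coords(axis)
    ray_rsp = sample_points(rsp, pts)
    ray_w = sample_points(w, pts)
    inside = np.nonzero(ray_rsp > 0.05)[0]
    w_entry = float(ray_w[inside[0]]) if inside.size else 0.0
    det = np.zeros(3)
    det[ua], det[va], det[axis] = lateral_mm[0], lateral_mm[1], depth_mm
    w_det = float(sample_points(w, det[None, :])[0])
    return w_det - w_entry


def evaluate_range_uncertainty(image: ImageGrid, table: HUDensityTable,
                               rsp_table: RSPTable, beam: BeamSpec,
                               measurement: PlanarDose,
                               overrides: list[tuple[StructureMask, float]] | None = None,
                               params: GammaParams | None = None,
                               model: BraggModel | None = None,
                               window_mm: float = 10.0,
                               step_mm: float = 1.0) -> RangeSweepResult:
    """Full range-uncertainty evaluation on one image.

    Chains HU→density (modality table) → density overrides → density→RSP →
    forward beam dose → depth sweep → best match → percentage range error.
    Stage failures are re-raised with the stage name. The percentage
    denominator is the central-axis WEPL from the entry surface to the
    physical detector plane, computed on this image's RSP.
    """
    stages = []

    def stage(name, fn):
        stages.append(name)
        try:
            return fn()
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    density = stage("density_from_hu", lambda: density_from_hu(image, table))
    if overrides:
        density = stage("apply_overrides",
                        lambda: apply_density_overrides(density, overrides))
    rsp = stage("rsp_from_density", lambda: rsp_from_density(density, rsp_table))
    dose = stage("compute_beam_dose", lambda: compute_beam_dose(beam, rsp, model))

    wsum = sum(s.weight for s in beam.spots)
    cu = sum(s.lateral_mm[0] * s.weight for s in beam.spots) / wsum
    cv = sum(s.lateral_mm[1] * s.weight for s in beam.spots) / wsum
    wepl = stage("central_axis_wepl",
                 lambda: central_axis_wepl(rsp, beam.axis, beam.entry,
                                           measurement.depth, (cu, cv)))
    sweep = stage("sweep_depths",
                  lambda: sweep_depths(measurement, dose, window_mm, step_mm,
                                       params, wepl_to_detector_mm=wepl))
    stage("best_match", lambda: best_match(sweep))
    sweep.provenance.update({
        "table_modality": table.modality,
        "beam_axis": beam.axis,
        "beam_entry": beam.entry,
        "n_spots": len(beam.spots),
        "central_axis_mm": [cu, cv],
        "wepl_denominator": "central-axis entry surface to detector plane",
        "stages": stages,
    })
    return sweep
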