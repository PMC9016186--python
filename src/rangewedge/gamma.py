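"""2D gamma-index comparison of a measured reference plane against a
calculated evaluated plane.

Definition (shared by the fast path and the brute-force oracle): for each
reference point r above the low-dose threshold,

    γ(r) = min over candidate positions e of
           sqrt(‖e − r‖²/Δd² + (D_eval(e) − D_ref(r))²/(ΔD·D_norm/100)²)

where the candidates are the nodes of a dense lattice (step
``interp_step_mm``, anchored at the evaluated plane's origin) lying within
``search_radius_factor·Δd`` of r, plus the bilinearly interpolated evaluated
dose at r's exact position. Gamma is not symmetric; the reference is the
measurement by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .grids_io import PlanarDose

__all__ = ["GammaParams", "GammaResult", "gamma_map", "brute_force_gamma",
           "passing_rate"]

_ORACLE_GUARD = 50  # max reference points per side for brute_force_gamma


@dataclass(frozen=True)
class GammaParams:
    """Criteria and numerical settings for the 2D gamma comparison."""

    dose_pct: float = 3.0
    dta_mm: float = 3.0
    normalization: float | str = "global-max"  # or explicit dose in cGy
    threshold_pct: float = 10.0
    search_radius_factor: float = 3.0
    interp_step_mm: float = 0.3

    def __post_init__(self) -> None:
        if self.dose_pct <= 0 or self.dta_mm <= 0:
            raise ValueError("dose and distance criteria must be positive")
        if not 0 <= self.threshold_pct < 100:
            raise ValueError("threshold must be in [0, 100)")
        if self.search_radius_factor < 1:
            raise ValueError("search radius must be at least 1×DTA")
        if self.interp_step_mm <= 0:
            raise ValueError("interpolation step must be positive")


@dataclass
class GammaResult:
    """Per-reference-point γ values and the passing rate."""

    gamma: np.ndarray          # NaN at excluded (below-threshold) points
    included: np.ndarray       # bool, same shape as the reference values
    truncated: np.ndarray      # bool: search disk exited the evaluated plane
    pass_rate_pct: float
    norm_dose: float
    params: GammaParams = field(default_factory=GammaParams)

    def __post_init__(self) -> None:
        g = self.gamma[self.included]
        if g.size and (np.any(g < 0) or not np.all(np.isfinite(g))):
            raise ValueError("gamma values must be finite and non-negative")
        if not 0 <= self.pass_rate_pct <= 100:
            raise ValueError("passing rate must be in [0, 100]")


def passing_rate(result: GammaResult) -> float:
    """Percent of included reference points with γ ≤ 1."""
    g = result.gamma[result.included]
    if g.size == 0:
        raise ValueError("no included points")
    return 100.0 * float(np.count_nonzero(g <= 1.0)) / g.size


def _norm_dose(reference: PlanarDose, params: GammaParams) -> float:
    if params.normalization == "global-max":
        norm = float(reference.values.max())
    else:
        norm = float(params.normalization)
    if norm <= 0:
        raise ValueError("normalization dose must be positive")
    return norm


def _plane_coords(plane: PlanarDose) -> tuple[np.ndarray, np.ndarray]:
    nu, nv = plane.values.shape
    u = plane.in_plane_origin[0] + plane.in_plane_spacing[0] * np.arange(nu)
    v = plane.in_plane_origin[1] + plane.in_plane_spacing[1] * np.arange(nv)
    return u, v


def _dense_lattice(evaluated: PlanarDose, step: float):
    """Node coordinates of the dense candidate lattice over the evaluated
    plane's extent (anchored at its origin)."""
    u, v = _plane_coords(evaluated)
    nu = int(math.floor((u[-1] - u[0]) / step + 1e-9)) + 1
    nv = int(math.floor((v[-1] - v[0]) / step + 1e-9)) + 1
    du = u[0] + step * np.arange(nu)
    dv = v[0] + step * np.arange(nv)
    return du, dv


def _check_overlap(reference: PlanarDose, evaluated: PlanarDose,
                   slack_mm: float = 0.0) -> None:
    """Planes must overlap spatially (within the gamma search radius)."""
    ru, rv = _plane_coords(reference)
    eu, ev = _plane_coords(evaluated)
    if ru[0] > eu[-1] + slack_mm or ru[-1] < eu[0] - slack_mm \
            or rv[0] > ev[-1] + slack_mm or rv[-1] < ev[0] - slack_mm:
        raise ValueError("reference and evaluated planes do not overlap spatially")


def _bilinear(evaluated: PlanarDose, pu: np.ndarray, pv: np.ndarray) -> np.ndarray:
    """Vectorized bilinear interpolation on the evaluated lattice (clamped)."""
    u, v = _plane_coords(evaluated)
    fi = np.clip((pu - u[0]) / evaluated.in_plane_spacing[0], 0, u.size - 1)
    fj = np.clip((pv - v[0]) / evaluated.in_plane_spacing[1], 0, v.size - 1)
    i0 = np.minimum(fi.astype(int), u.size - 2) if u.size > 1 else np.zeros_like(fi, int)
    j0 = np.minimum(fj.astype(int), v.size - 2) if v.size > 1 else np.zeros_like(fj, int)
    ti = fi - i0
    tj = fj - j0
    vals = evaluated.values
    if u.size == 1 and v.size == 1:
        return np.broadcast_to(vals[0, 0], fi.shape).copy()
    if u.size == 1:
        return vals[0, j0] * (1 - tj) + vals[0, j0 + 1] * tj
    if v.size == 1:
        return vals[i0, 0] * (1 - ti) + vals[i0 + 1, 0] * ti
    return (vals[i0, j0] * (1 - ti) * (1 - tj)
            + vals[i0 + 1, j0] * ti * (1 - tj)
            + vals[i0, j0 + 1] * (1 - ti) * tj
            + vals[i0 + 1, j0 + 1] * ti * tj)


def gamma_map(reference: PlanarDose, evaluated: PlanarDose,
              params: GammaParams | None = None) -> GammaResult:
    """Vectorized 2D gamma of ``evaluated`` against the ``reference`` plane."""
    if params is None:
        params = GammaParams()
    radius = params.search_radius_factor * params.dta_mm
    _check_overlap(reference, evaluated, slack_mm=radius)
    norm = _norm_dose(reference, params)
    delta_d = params.dose_pct * norm / 100.0
    step = params.interp_step_mm

    du, dv = _dense_lattice(evaluated, step)
    uu, vv = np.meshgrid(du, dv, indexing="ij")
    dense = _bilinear(evaluated, uu, vv)
    eu, ev_ = _plane_coords(evaluated)

    ru, rv = _plane_coords(reference)
    included = reference.values >= params.threshold_pct * norm / 100.0
    if not included.any():
        raise ValueError("all reference points are below the low-dose threshold")

    eu0, ev0 = du[0], dv[0]
    gamma = np.full(reference.values.shape, np.nan)
    truncated = np.zeros(reference.values.shape, dtype=bool)
    r2 = radius * radius
    dta2 = params.dta_mm**2
    dd2 = delta_d**2

    for i, j in zip(*np.nonzero(included)):
        pu, pv = ru[i], rv[j]
        i0 = max(int(math.ceil((pu - radius - eu0) / step - 1e-12)), 0)
        i1 = min(int(math.floor((pu + radius - eu0) / step + 1e-12)), du.size - 1)
        j0 = max(int(math.ceil((pv - radius - ev0) / step - 1e-12)), 0)
        j1 = min(int(math.floor((pv + radius - ev0) / step + 1e-12)), dv.size - 1)
        best = np.inf
        if i0 <= i1 and j0 <= j1:
            su = du[i0:i1 + 1] - pu
            sv = dv[j0:j1 + 1] - pv
            dist2 = su[:, None] ** 2 + sv[None, :] ** 2
            disk = dist2 <= r2 + 1e-12
            if disk.any():
                diff = dense[i0:i1 + 1, j0:j1 + 1] - reference.values[i, j]
                g2 = dist2 / dta2 + (diff * diff) / dd2
                best = float(np.min(np.where(disk, g2, np.inf)))
        # candidate at the reference point itself (zero distance); valid
        # anywhere inside the evaluated plane's true extent
        if eu[0] - 1e-9 <= pu <= eu[-1] + 1e-9 and ev_[0] - 1e-9 <= pv <= ev_[-1] + 1e-9:
            d_at = float(_bilinear(evaluated, np.array([pu]), np.array([pv]))[0])
            best = min(best, (d_at - reference.values[i, j]) ** 2 / dd2)
        if not np.isfinite(best):
            raise ValueError("reference point has no candidate inside the "
                             "evaluated plane; planes barely overlap")
        gamma[i, j] = math.sqrt(best)
        truncated[i, j] = (pu - radius < du[0] - 1e-9 or pu + radius > du[-1] + 1e-9
                           or pv - radius < dv[0] - 1e-9 or pv + radius > dv[-1] + 1e-9)

    result = GammaResult(gamma=gamma, included=included, truncated=truncated,
                         pass_rate_pct=0.0, norm_dose=norm, params=params)
    result.pass_rate_pct = passing_rate(result)
    return result


def brute_force_gamma(reference: PlanarDose, evaluated: PlanarDose,
                      params: GammaParams | None = None) -> GammaResult:
    """Exhaustive oracle: identical definition to :func:`gamma_map`, computed
    with plain loops over the full dense lattice and an independent
    interpolator. Guarded to small reference planes."""
    if params is None:
        params = GammaParams()
    nu, nv = reference.values.shape
    if nu > _ORACLE_GUARD or nv > _ORACLE_GUARD:
        raise ValueError(f"brute-force oracle limited to {_ORACLE_GUARD}x"
                         f"{_ORACLE_GUARD} reference points")
    radius = params.search_radius_factor * params.dta_mm
    _check_overlap(reference, evaluated, slack_mm=radius)
    norm = _norm_dose(reference, params)
    delta_d = params.dose_pct * norm / 100.0

    eu, ev = _plane_coords(evaluated)
    interp = RegularGridInterpolator((eu, ev), evaluated.values,
                                     bounds_error=False, fill_value=None)
    du, dv = _dense_lattice(evaluated, params.interp_step_mm)
    dense = interp(np.stack(np.meshgrid(du, dv, indexing="ij"), axis=-1))

    ru, rv = _plane_coords(reference)
    included = reference.values >= params.threshold_pct * norm / 100.0
    if not included.any():
        raise ValueError("all reference points are below the low-dose threshold")

    gamma = np.full(reference.values.shape, np.nan)
    truncated = np.zeros(reference.values.shape, dtype=bool)
    for i in range(nu):
        for j in range(nv):
            if not included[i, j]:
                continue
            pu, pv, dref = ru[i], rv[j], reference.values[i, j]
            best = math.inf
            for a in range(du.size):
                su = du[a] - pu
                if abs(su) > radius + 1e-9:
                    continue
                for b in range(dv.size):
                    sv = dv[b] - pv
                    dist2 = su * su + sv * sv
                    if dist2 > radius * radius + 1e-12:
                        continue
                    diff = dense[a, b] - dref
                    g2 = dist2 / params.dta_mm**2 + diff * diff / delta_d**2
                    if g2 < best:
                        best = g2
            if eu[0] - 1e-9 <= pu <= eu[-1] + 1e-9 and ev[0] - 1e-9 <= pv <= ev[-1] + 1e-9:
                d_at = float(interp([[pu, pv]])[0])
                best = min(best, (d_at - dref) ** 2 / delta_d**2)
            if not math.isfinite(best):
                raise ValueError("reference point has no candidate inside the "
                                 "evaluated plane; planes barely overlap")
            gamma[i, j] = math.sqrt(best)
            truncated[i, j] = (pu - radius < du[0] - 1e-9 or pu + radius > du[-1] + 1e-9
                               or pv - radius < dv[0] - 1e-9 or pv + radius > dv[-1] + 1e-9)

    result = GammaResult(gamma=gamma, included=included, truncated=truncated,
                         pass_rate_pct=0.0, norm_dose=norm, params=params)
    result.pass_rate_pct = passing_rate(result)
    return result
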