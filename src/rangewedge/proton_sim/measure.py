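"""Simulated 2D ion-chamber-array measurement of a dose plane."""

from __future__ import annotations

import numpy as np

from ..grids_io import ImageGrid, PlanarDose, sample_points

__all__ = ["simulate_measurement"]


def simulate_measurement(dose: ImageGrid, depth_mm: float,
                         pitch_mm: float = 10.0,
                         noise_pct: float = 0.0,
                         seed: int = 0,
                         axis: int = 1,
                         detector_shape: tuple[int, int] = (27, 27),
                         center_mm: tuple[float, float] | None = None) -> PlanarDose:
    """Sample a dose grid on a detector lattice at one physical depth.

    Trilinear sampling at the chamber positions, then multiplicative Gaussian
    noise ``D·(1 + N(0, noise_pct/100))``, seeded. The lattice is centered on
    the grid's in-plane center unless ``center_mm`` is given.
    """
    if dose.quantity != "dose":
        raise ValueError("expected a dose grid")
    lo, hi = dose.extent(axis)
    if not (lo <= depth_mm <= hi):
        raise ValueError(f"detector depth {depth_mm} mm outside grid extent "
                         f"[{lo}, {hi}] mm along axis {axis}")
    ua, va = (a for a in (0, 1, 2) if a != axis)
    if center_mm is None:
        center_mm = (0.5 * sum(dose.extent(ua)), 0.5 * sum(dose.extent(va)))
    nu, nv = detector_shape
    u = center_mm[0] + pitch_mm * (np.arange(nu) - (nu - 1) / 2.0)
    v = center_mm[1] + pitch_mm * (np.arange(nv) - (nv - 1) / 2.0)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    pts = np.zeros(uu.shape + (3,))
    pts[..., ua] = uu
    pts[..., va] = vv
    pts[..., axis] = depth_mm
    values = sample_points(dose, pts)
    if noise_pct > 0:
        rng = np.random.default_rng(seed)
        values = values * (1.0 + rng.normal(0.0, noise_pct / 100.0, size=values.shape))
    return PlanarDose(
        plane_axis=axis,
        depth=float(depth_mm),
        in_plane_origin=np.array([u[0], v[0]]),
        in_plane_spacing=np.array([pitch_mm, pitch_mm]),
        values=np.clip(values, 0.0, None),
    )
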