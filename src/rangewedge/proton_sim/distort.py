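"""Image-domain CBCT emulation: per-tissue-class affine HU distortion, a
radial cupping term, and seeded Gaussian noise."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..grids_io import ImageGrid

__all__ = ["CBCTDistortion", "classify_density", "distort_to_cbct", "CLASS_NAMES"]

CLASS_NAMES = ("air", "lung", "soft", "bone")

# density thresholds separating air / lung / soft tissue / bone (g/cm3)
_CLASS_EDGES = (0.05, 0.6, 1.2)


@dataclass
class CBCTDistortion:
    """HU_cbct = a_c·HU_ct + b_c + cupping·(r/r0)² + N(0, σ²), per class c."""

    class_affine: dict = field(default_factory=lambda: {
        "air": (1.0, 0.0),
        "lung": (1.0, 30.0),
        "soft": (1.0, 40.0),
        "bone": (0.95, 20.0),
    })
    cupping_amplitude_hu: float = 0.0
    cupping_radius_mm: float = 100.0
    noise_sigma_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma_hu < 0:
            raise ValueError("noise sigma must be >= 0")
        missing = [c for c in CLASS_NAMES if c not in self.class_affine]
        if missing:
            raise ValueError(f"class_affine missing classes: {missing}")


def classify_density(density: ImageGrid) -> np.ndarray:
    """Assign every voxel to one of air/lung/soft/bone by density threshold."""
    if density.quantity != "density":
        raise ValueError("expected a density grid")
    return np.digitize(density.values, _CLASS_EDGES)


def distort_to_cbct(ct_hu: ImageGrid, class_ids: np.ndarray,
                    distortion: CBCTDistortion) -> ImageGrid:
    """Apply a CBCT distortion model to a CT HU grid.

    ``class_ids`` holds one integer per voxel indexing ``CLASS_NAMES``
    (use :func:`classify_density` on the truth density). Deterministic for a
    fixed seed.
    """
    if ct_hu.quantity != "HU":
        raise ValueError("expected an HU grid")
    class_ids = np.asarray(class_ids)
    if class_ids.shape != ct_hu.shape:
        raise ValueError("class assignment shape does not match the grid")
    if class_ids.min() < 0 or class_ids.max() >= len(CLASS_NAMES):
        raise ValueError("unassigned voxels: class ids must index air/lung/soft/bone")

    a = np.array([distortion.class_affine[c][0] for c in CLASS_NAMES])
    b = np.array([distortion.class_affine[c][1] for c in CLASS_NAMES])
    out = a[class_ids] * ct_hu.values + b[class_ids]

    if distortion.cupping_amplitude_hu != 0.0:
        # radial in the axial (x, y) plane about the grid center
        x = ct_hu.axis_coords(0)
        y = ct_hu.axis_coords(1)
        cx = 0.5 * (x[0] + x[-1])
        cy = 0.5 * (y[0] + y[-1])
        r2 = ((x - cx) ** 2)[:, None] + ((y - cy) ** 2)[None, :]
        out = out + (distortion.cupping_amplitude_hu
                     * (r2 / distortion.cupping_radius_mm**2))[:, :, None]

    if distortion.noise_sigma_hu > 0:
        rng = np.random.default_rng(distortion.seed)
        out = out + rng.normal(0.0, distortion.noise_sigma_hu, size=out.shape)
    return ct_hu.with_values(out)
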