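"""Digital head/thorax phantoms: ellipsoidal body with bone shell, optional
lungs, a posterior solid-water base slab, and a wedge-shaped target whose
distal depth varies linearly with lateral position so its gradient crosses
the detector plane."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..grids_io import ImageGrid, StructureMask
from ..hu_density import HUDensityTable, default_ct_table

__all__ = ["PhantomSpec", "head_phantom_spec", "thorax_phantom_spec", "make_phantom",
           "AIR_DENSITY", "LUNG_DENSITY", "SOFT_DENSITY", "BONE_DENSITY"]

AIR_DENSITY = 0.00121
LUNG_DENSITY = 0.26
SOFT_DENSITY = 1.0
BONE_DENSITY = 1.55


@dataclass
class PhantomSpec:
    """Geometry of a synthetic phantom (all lengths mm, axis 1 = AP depth)."""

    site: str
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    body_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    body_semiaxes: tuple[float, float, float] = (45.0, 55.0, 45.0)
    shell_thickness_mm: float = 5.0
    lungs: list[tuple[tuple[float, float, float], tuple[float, float, float]]] = \
        field(default_factory=list)
    base_y_range: tuple[float, float] = (0.0, 0.0)
    wedge_u_range: tuple[float, float] = (0.0, 0.0)   # lateral axis 0 (x)
    wedge_v_range: tuple[float, float] = (0.0, 0.0)   # lateral axis 2 (z)
    wedge_proximal_y: float = 0.0
    wedge_distal_y_range: tuple[float, float] = (0.0, 0.0)  # linear in u
    #: secondary tilt of the distal surface along the v (axis-2) direction,
    #: mm depth per mm lateral; staggers where each detector row crosses the
    #: gradient so the pass-rate-vs-depth curve degrades smoothly
    wedge_v_slope: float = 0.0
    detector_depth_mm: float = 0.0
    detector_pitch_mm: float = 10.0
    detector_shape: tuple[int, int] = (27, 27)
    noise_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        d0, d1 = sorted(self.wedge_distal_y_range)
        if not (d0 <= self.detector_depth_mm <= d1):
            raise ValueError(
                f"wedge gradient [{d0}, {d1}] mm must span the detector depth "
                f"{self.detector_depth_mm} mm")
        for ax in range(3):
            top = self.origin[ax] + self.spacing[ax] * (self.shape[ax] - 1)
            lo = self.body_center[ax] - self.body_semiaxes[ax]
            hi = self.body_center[ax] + self.body_semiaxes[ax]
            if lo < self.origin[ax] - 1e-9 or hi > top + 1e-9:
                raise ValueError(f"body ellipsoid exceeds grid extent on axis {ax}")
        if self.base_y_range[1] > self.origin[1] + self.spacing[1] * (self.shape[1] - 1) + 1e-9:
            raise ValueError("base slab exceeds grid extent")
        if max(self.wedge_distal_y_range) > self.base_y_range[1]:
            raise ValueError("wedge distal surface exceeds the base slab")


def head_phantom_spec(noise_hu: float = 0.0, seed: int = 0) -> PhantomSpec:
    """Default head phantom: soft-tissue ellipsoid with bone shell on a
    solid-water base; wedge target inside the base with slope 0.25."""
    return PhantomSpec(
        site="head",
        shape=(170, 170, 150),
        body_center=(85.0, 63.0, 75.0),
        # wide in x/z so the tissue chord (hence the WEPL to the wedge's
        # distal surface) is nearly uniform across the wedge footprint and
        # the distal-margin offset stays constant over the field
        body_semiaxes=(75.0, 55.0, 65.0),
        shell_thickness_mm=5.0,
        base_y_range=(118.0, 168.0),
        wedge_u_range=(45.0, 125.0),
        wedge_v_range=(50.0, 100.0),
        wedge_proximal_y=121.0,
        wedge_distal_y_range=(132.0, 152.0),
        wedge_v_slope=0.08,
        detector_depth_mm=149.0,
        noise_hu=noise_hu,
        seed=seed,
    )


def thorax_phantom_spec(noise_hu: float = 0.0, seed: int = 0) -> PhantomSpec:
    """Default thorax phantom: body ellipsoid, two lungs, bone shell, base."""
    return PhantomSpec(
        site="thorax",
        shape=(180, 150, 140),
        body_center=(90.0, 62.0, 70.0),
        body_semiaxes=(85.0, 60.0, 65.0),
        shell_thickness_mm=4.0,
        lungs=[((48.0, 62.0, 70.0), (30.0, 38.0, 48.0)),
               ((132.0, 62.0, 70.0), (30.0, 38.0, 48.0))],
        base_y_range=(123.0, 148.0),
        wedge_u_range=(62.0, 118.0),
        wedge_v_range=(44.0, 96.0),
        wedge_proximal_y=126.0,
        wedge_distal_y_range=(132.0, 144.0),
        wedge_v_slope=0.06,
        detector_depth_mm=141.0,
        noise_hu=noise_hu,
        seed=seed,
    )


def _ellipsoid(coords, center, semi) -> np.ndarray:
    xx, yy, zz = coords
    return (((xx - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((zz - center[2]) / semi[2]) ** 2) <= 1.0


_AA_OFFSETS = np.array([-1.0 / 3.0, 0.0, 1.0 / 3.0])


def _ellipsoid_fraction(axes, spacing, center, semi) -> np.ndarray:
    """Partial-volume occupancy of an ellipsoid on the voxel lattice
    (3x3x3 supersampling). A hard voxelized surface aliases ray chord
    lengths by a full voxel between neighboring columns, which imprints
    ~0.5-mm WEPL jitter on every distal dose surface."""
    frac = np.zeros(tuple(a.size for a in axes), dtype=np.float64)
    for dx in _AA_OFFSETS * spacing[0]:
        for dy in _AA_OFFSETS * spacing[1]:
            for dz in _AA_OFFSETS * spacing[2]:
                sub = ((axes[0] + dx)[:, None, None],
                       (axes[1] + dy)[None, :, None],
                       (axes[2] + dz)[None, None, :])
                frac += _ellipsoid(sub, center, semi)
    return frac / 27.0


def make_phantom(spec: PhantomSpec,
                 ct_table: HUDensityTable | None = None
                 ) -> tuple[ImageGrid, ImageGrid, StructureMask, StructureMask]:
    """Build a phantom from its spec.

    Returns ``(ct_hu, density_truth, wedge_mask, base_mask)``. CT HU are the
    inverse of the CT HU-D table applied to the true density, plus optional
    seeded Gaussian noise; generation is deterministic for a fixed seed.
    """
    if ct_table is None:
        ct_table = default_ct_table()
    origin = np.asarray(spec.origin, dtype=float)
    spacing = np.asarray(spec.spacing, dtype=float)
    axes = [origin[a] + spacing[a] * np.arange(spec.shape[a]) for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij", sparse=True)
    coords = (xx, yy, zz)

    inner_semi = np.maximum(np.asarray(spec.body_semiaxes) - spec.shell_thickness_mm, 1.0)
    f_body = _ellipsoid_fraction(axes, spacing, spec.body_center, spec.body_semiaxes)
    f_inner = _ellipsoid_fraction(axes, spacing, spec.body_center, inner_semi)
    # nested composition: air -> bone shell -> soft interior -> lungs
    density = (AIR_DENSITY
               + f_body * (BONE_DENSITY - AIR_DENSITY)
               + f_inner * (SOFT_DENSITY - BONE_DENSITY))
    for center, semi in spec.lungs:
        density += _ellipsoid_fraction(axes, spacing, center, semi) \
            * (LUNG_DENSITY - SOFT_DENSITY)

    base = (yy >= spec.base_y_range[0]) & (yy < spec.base_y_range[1])
    base = np.broadcast_to(base, spec.shape).copy()
    density[base] = SOFT_DENSITY  # solid water

    u0, u1 = spec.wedge_u_range
    v0, v1 = spec.wedge_v_range
    d0, d1 = spec.wedge_distal_y_range
    frac = np.clip((xx - u0) / max(u1 - u0, 1e-9), 0.0, 1.0)
    distal = d0 + (d1 - d0) * frac + spec.wedge_v_slope * (zz - 0.5 * (v0 + v1))
    wedge = ((xx >= u0) & (xx <= u1) & (zz >= v0) & (zz <= v1)
             & (yy >= spec.wedge_proximal_y) & (yy <= distal))
    wedge = np.broadcast_to(wedge, spec.shape).copy()

    hu = np.asarray(ct_table.inverse_lookup(density), dtype=float)
    if spec.noise_hu > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_hu, size=hu.shape)

    geom = dict(origin=origin, spacing=spacing, frame="planning")
    ct = ImageGrid(values=hu, quantity="HU", **geom)
    rho = ImageGrid(values=density, quantity="density", **geom)
    wedge_mask = StructureMask("wedge_ctv", rho, wedge)
    base_mask = StructureMask("base", rho, base)
    if wedge_mask.voxel_count == 0:
        raise ValueError("wedge target mask is empty; check phantom spec")
    return ct, rho, wedge_mask, base_mask
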