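"""Geometry-aware volume and plane containers plus resampling and rasterization.

Conventions
-----------
* Right-handed frame, units mm, voxel-center convention, 0-based indices.
* ``ImageGrid.values`` is indexed ``[i, j, k]`` along axes (0, 1, 2); the world
  position of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``.
* Axis 1 is the anterior-posterior beam axis by default.
* All interpolation is trilinear (bilinear in 2D); no higher-order kernels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "Quantity",
    "ImageGrid",
    "RigidTransform",
    "PlanarDose",
    "StructureMask",
    "FILL_VALUES",
    "resample_rigid",
    "rasterize_contours",
    "sample_points",
]

#: Recognised voxel quantities and their out-of-volume fill values.
FILL_VALUES = {
    "HU": -1000.0,
    "density": 0.00121,  # air, g/cm3
    "RSP": 0.0,
    "dose": 0.0,
    "WEPL": 0.0,
}

Quantity = str


@dataclass
class ImageGrid:
    """A 3D scalar volume on a regular axis-aligned lattice.

    Parameters
    ----------
    origin : (3,) array-like
        World position (mm) of the center of voxel (0, 0, 0).
    spacing : (3,) array-like
        Voxel pitch (mm) per axis; strictly positive.
    values : (n0, n1, n2) ndarray
        One scalar per voxel.
    quantity : {"HU", "density", "RSP", "dose"}
    frame : str
        Label of the coordinate frame the grid lives in.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    quantity: Quantity = "HU"
    frame: str = "patient"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise ValueError("origin and spacing must be 3-vectors")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if min(self.values.shape) < 1:
            raise ValueError("shape must be >= 1 on every axis")
        if self.quantity not in FILL_VALUES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.quantity in ("density", "dose") and np.any(self.values < 0):
            raise ValueError(f"{self.quantity} values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def extent(self, axis: int) -> tuple[float, float]:
        """World coordinates of the first and last voxel center along ``axis``."""
        c = self.axis_coords(axis)
        return float(c[0]), float(c[-1])

    def index_of(self, point_mm) -> np.ndarray:
        """Continuous index of a world point (no rounding)."""
        return (np.asarray(point_mm, dtype=float) - self.origin) / self.spacing

    def with_values(self, values: np.ndarray, quantity: Quantity | None = None) -> "ImageGrid":
        """Same geometry, new values (and optionally a new quantity label)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       quantity=quantity or self.quantity)

    def same_geometry(self, other: "ImageGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


@dataclass
class RigidTransform:
    """4x4 homogeneous rigid transform (rotation + mm translation)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        r = m[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation block is not orthonormal (R^T R != I)")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-9):
            raise ValueError("rotation block must have determinant +1")
        if not np.allclose(m[3], [0, 0, 0, 1]):
            raise ValueError("last row must be [0, 0, 0, 1]")
        self.matrix = m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def translation(cls, t) -> "RigidTransform":
        m = np.eye(4)
        m[:3, 3] = np.asarray(t, dtype=float)
        return cls(m)

    def inverse(self) -> "RigidTransform":
        r = self.matrix[:3, :3]
        t = self.matrix[:3, 3]
        m = np.eye(4)
        m[:3, :3] = r.T
        m[:3, 3] = -r.T @ t
        return RigidTransform(m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of points (mm)."""
        p = np.asarray(points, dtype=float)
        return p @ self.matrix[:3, :3].T + self.matrix[:3, 3]


@dataclass
class PlanarDose:
    """2D dose samples on a regular in-plane lattice at one depth.

    The two in-plane axes are the volume axes other than ``plane_axis`` in
    increasing order; ``values[i, j]`` sits at
    ``in_plane_origin + (i, j) * in_plane_spacing``.
    """

    plane_axis: int
    depth: float
    in_plane_origin: np.ndarray
    in_plane_spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.in_plane_origin = np.asarray(self.in_plane_origin, dtype=float)
        self.in_plane_spacing = np.asarray(self.in_plane_spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.plane_axis not in (0, 1, 2):
            raise ValueError("plane_axis must be 0, 1 or 2")
        if self.values.ndim != 2:
            raise ValueError("values must be 2D")
        if np.any(self.in_plane_spacing <= 0):
            raise ValueError("in-plane spacing must be strictly positive")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        if not np.isfinite(self.depth):
            raise ValueError("depth must be finite")

    @property
    def in_plane_axes(self) -> tuple[int, int]:
        return tuple(a for a in (0, 1, 2) if a != self.plane_axis)  # type: ignore

    def point_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid ('ij') of in-plane world coordinates of every sample."""
        u = self.in_plane_origin[0] + self.in_plane_spacing[0] * np.arange(self.values.shape[0])
        v = self.in_plane_origin[1] + self.in_plane_spacing[1] * np.arange(self.values.shape[1])
        return np.meshgrid(u, v, indexing="ij")


@dataclass
class StructureMask:
    """Boolean voxel mask tied to an ImageGrid geometry."""

    name: str
    grid: ImageGrid
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match grid shape {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * float(np.prod(self.grid.spacing)) / 1000.0


def sample_points(grid: ImageGrid, points_mm: np.ndarray, fill: float | None = None) -> np.ndarray:
    """Trilinear sample of ``grid`` at world points (..., 3); out-of-volume
    points get the quantity's fill value."""
    if fill is None:
        fill = FILL_VALUES[grid.quantity]
    pts = np.asarray(points_mm, dtype=float)
    idx = (pts - grid.origin) / grid.spacing
    coords = np.moveaxis(idx, -1, 0)
    return map_coordinates(grid.values, coords, order=1, mode="constant", cval=fill)


def resample_rigid(moving: ImageGrid, transform: RigidTransform,
                   target_geometry: ImageGrid) -> ImageGrid:
    """Resample ``moving`` onto the geometry of ``target_geometry``.

    ``transform`` maps moving-frame coordinates to target-frame coordinates;
    each target voxel center is pulled back through the inverse and sampled
    trilinearly. Out-of-volume points use the quantity-dependent fill value.
    """
    if abs(np.linalg.det(transform.matrix)) < 1e-12:
        raise ValueError("singular transform matrix")
    inv = transform.inverse()
    i, j, k = np.meshgrid(*(np.arange(n) for n in target_geometry.shape), indexing="ij")
    pts = np.stack([i, j, k], axis=-1) * target_geometry.spacing + target_geometry.origin
    sampled = sample_points(moving, inv.apply(pts))
    if moving.quantity in ("density", "dose"):
        sampled = np.clip(sampled, 0.0, None)
    return ImageGrid(
        origin=target_geometry.origin.copy(),
        spacing=target_geometry.spacing.copy(),
        values=sampled,
        quantity=moving.quantity,
        frame=target_geometry.frame,
    )


def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray,
                       edge_eps: float = 1e-9) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test; points on an edge
    count as inside. ``poly`` is (n, 2), implicitly closed."""
    x1 = poly[:, 0]
    y1 = poly[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)

    px = px[:, None]
    py = py[:, None]

    crosses = (y1 > py) != (y2 > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_int = x1 + (py - y1) * (x2 - x1) / np.where(y2 == y1, np.inf, y2 - y1)
    inside = np.sum(crosses & (px < x_int), axis=1) % 2 == 1

    # on-edge test: point within eps of the segment
    dx = x2 - x1
    dy = y2 - y1
    seg2 = dx * dx + dy * dy
    t = np.clip(((px - x1) * dx + (py - y1) * dy) / np.where(seg2 == 0, 1, seg2), 0, 1)
    d2 = (x1 + t * dx - px) ** 2 + (y1 + t * dy - py) ** 2
    on_edge = np.any(d2 <= edge_eps**2, axis=1)
    return inside | on_edge


def rasterize_contours(planar_polygons, grid_geometry: ImageGrid,
                       name: str = "structure", plane_axis: int = 2) -> StructureMask:
    """Rasterize per-slice closed polygons into a voxel mask.

    Parameters
    ----------
    planar_polygons : iterable of (slice_position_mm, vertices)
        ``vertices`` is an (n, 2) array of in-plane mm coordinates on the two
        axes other than ``plane_axis`` (increasing axis order). Polygons are
        closed implicitly. Each slice position must lie within half the slice
        spacing of a grid slice.
    grid_geometry : ImageGrid
        Supplies the lattice; its values are ignored.

    Voxel centers are classified with the even-odd rule; centers exactly on a
    polygon edge count as inside.
    """
    mask = np.zeros(grid_geometry.shape, dtype=bool)
    ua, va = (a for a in (0, 1, 2) if a != plane_axis)
    u = grid_geometry.axis_coords(ua)
    v = grid_geometry.axis_coords(va)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    slice_pos = grid_geometry.axis_coords(plane_axis)
    half = grid_geometry.spacing[plane_axis] / 2.0

    any_hit = False
    for z, verts in planar_polygons:
        verts = np.asarray(verts, dtype=float)
        if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
            raise ValueError("each polygon needs at least 3 (u, v) vertices")
        k = int(np.argmin(np.abs(slice_pos - z)))
        if abs(slice_pos[k] - z) > half + 1e-9:
            raise ValueError(
                f"polygon slice at {z} mm is farther than half the slice "
                f"spacing from any grid slice"
            )
        inside = _points_in_polygon(uu.ravel(), vv.ravel(), verts).reshape(uu.shape)
        if inside.any():
            any_hit = True
        sl: list = [slice(None)] * 3
        sl[plane_axis] = k
        plane = mask[tuple(sl)]
        # XOR per polygon implements even-odd across overlapping polygons on
        # the same slice; disjoint polygons simply add up.
        mask[tuple(sl)] = plane ^ inside
    if not any_hit:
        warnings.warn(f"structure {name!r}: no voxel centers inside any polygon",
                      stacklevel=2)
    return StructureMask(name=name, grid=grid_geometry, mask=mask)
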