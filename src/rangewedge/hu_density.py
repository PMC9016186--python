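"""HU -> mass-density tables, group-based CBCT calibration, density -> RSP.

Dose calculation on either modality uses a piecewise-linear HU-D table; the
CBCT table is fit from volume-of-interest samples of near-homogeneous
materials (air, lung, soft tissue, bone, plus optional inserts) against the
CT table. The full stoichiometric composition / mean-ionization chain is
collapsed to a single configurable density -> relative-stopping-power table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .grids_io import ImageGrid, StructureMask

__all__ = [
    "HUDensityTable",
    "VOISample",
    "RSPTable",
    "default_ct_table",
    "default_rsp_table",
    "density_from_hu",
    "fit_group_table",
    "rsp_from_density",
    "apply_density_overrides",
]

_HU_COVER = (-1000.0, 3000.0)
_AIR_DENSITY = 0.00121


@dataclass
class HUDensityTable:
    """Piecewise-linear HU -> mass density (g/cm3) anchors for one modality."""

    modality: str  # "CT" or "CBCT"
    anchors: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.modality not in ("CT", "CBCT"):
            raise ValueError("modality must be 'CT' or 'CBCT'")
        if not self.anchors:
            raise ValueError("empty HU-D table")
        self.anchors = [(float(h), float(d)) for h, d in self.anchors]
        hu = np.array([a[0] for a in self.anchors])
        rho = np.array([a[1] for a in self.anchors])
        if np.any(np.diff(hu) <= 0):
            raise ValueError("HU anchors must be strictly increasing")
        if np.any(np.diff(rho) < 0):
            raise ValueError("density anchors must be non-decreasing")
        if hu[0] > _HU_COVER[0] or hu[-1] < _HU_COVER[1]:
            raise ValueError(f"HU coverage must include {_HU_COVER}, got [{hu[0]}, {hu[-1]}]")
        if rho[0] > 0.0013:
            raise ValueError("first anchor density must be <= 0.0013 (air)")

    @property
    def hu(self) -> np.ndarray:
        return np.array([a[0] for a in self.anchors])

    @property
    def density(self) -> np.ndarray:
        return np.array([a[1] for a in self.anchors])

    def lookup(self, hu) -> np.ndarray:
        """Interpolate densities for HU values (clamped at both ends)."""
        return np.interp(np.asarray(hu, dtype=float), self.hu, self.density)

    def inverse_lookup(self, density) -> np.ndarray:
        """HU producing a given density (clamped; flat segments -> first HU)."""
        return np.interp(np.asarray(density, dtype=float), self.density, self.hu)

    def to_yaml(self, path) -> str:
        path = Path(path)
        path.write_text(yaml.safe_dump(
            {"modality": self.modality,
             "anchors": [[h, d] for h, d in self.anchors]},
            sort_keys=False))
        return str(path)

    @classmethod
    def from_yaml(cls, path) -> "HUDensityTable":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(modality=doc["modality"], anchors=[tuple(a) for a in doc["anchors"]])


@dataclass
class VOISample:
    """Mean HU of one near-homogeneous material class on CT and CBCT."""

    material_class: str
    mean_hu_cbct: float
    mean_hu_ct: float | None = None
    known_density: float | None = None

    def __post_init__(self) -> None:
        if self.mean_hu_ct is None and self.known_density is None:
            raise ValueError(
                f"sample {self.material_class!r}: need known_density or mean_hu_ct")


@dataclass
class RSPTable:
    """Piecewise-linear mass density -> relative stopping power anchors."""

    anchors: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("empty RSP table")
        self.anchors = [(float(d), float(r)) for d, r in self.anchors]
        rho = np.array([a[0] for a in self.anchors])
        rsp = np.array([a[1] for a in self.anchors])
        if np.any(np.diff(rho) <= 0):
            raise ValueError("density anchors must be strictly increasing")
        if np.any(np.diff(rsp) < 0):
            raise ValueError("RSP anchors must be non-decreasing")
        if abs(self.lookup(1.0) - 1.0) > 1e-6:
            raise ValueError("RSP at density 1.0 g/cm3 must equal 1.0 (water)")

    def lookup(self, density) -> np.ndarray:
        rho = np.array([a[0] for a in self.anchors])
        rsp = np.array([a[1] for a in self.anchors])
        return np.interp(np.asarray(density, dtype=float), rho, rsp)

    def scaled(self, factor: float) -> "RSPTable":
        """Table with all RSP values multiplied by ``factor`` (for injecting a
        controlled stopping-power perturbation). Skips re-validation of the
        water normalization on purpose."""
        t = object.__new__(RSPTable)
        t.anchors = [(d, r * factor) for d, r in self.anchors]
        return t

    def to_yaml(self, path) -> str:
        path = Path(path)
        path.write_text(yaml.safe_dump(
            {"anchors": [[d, r] for d, r in self.anchors]}, sort_keys=False))
        return str(path)

    @classmethod
    def from_yaml(cls, path) -> "RSPTable":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(anchors=[tuple(a) for a in doc["anchors"]])


def default_ct_table() -> HUDensityTable:
    """Default CT calibration: air / lung / adipose / water / muscle / bone."""
    return HUDensityTable("CT", [
        (-1000.0, _AIR_DENSITY),
        (-740.0, 0.26),
        (-98.0, 0.93),
        (0.0, 1.0),
        (40.0, 1.04),
        (1100.0, 1.55),
        (3000.0, 2.4),
    ])


def default_rsp_table() -> RSPTable:
    """Default density -> RSP anchors (air, lung, adipose, water, muscle, bone)."""
    return RSPTable([
        (0.0, 0.0),
        (0.26, 0.265),
        (0.93, 0.95),
        (1.0, 1.0),
        (1.04, 1.035),
        (1.55, 1.45),
        (2.4, 2.1),
    ])


def density_from_hu(grid: ImageGrid, table: HUDensityTable) -> ImageGrid:
    """Convert an HU grid to mass density via piecewise-linear interpolation.

    HU outside the table's coverage are clamped to the end densities.
    """
    if grid.quantity != "HU":
        raise ValueError(f"expected an HU grid, got quantity={grid.quantity!r}")
    return grid.with_values(table.lookup(grid.values), quantity="density")


def _pool_adjacent_violators(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted isotonic (non-decreasing) regression, L2, PAV algorithm."""
    blocks = [[y[i], w[i], 1] for i in range(len(y))]  # mean, weight, count
    out: list[list[float]] = []
    for b in blocks:
        out.append(b)
        while len(out) > 1 and out[-2][0] > out[-1][0] + 1e-15:
            m2, w2, c2 = out.pop()
            m1, w1, c1 = out.pop()
            wt = w1 + w2
            out.append([(m1 * w1 + m2 * w2) / wt, wt, c1 + c2])
    fitted = np.empty_like(y)
    i = 0
    for mean, _, count in out:
        fitted[i:i + count] = mean
        i += count
    return fitted


def fit_group_table(samples: list[VOISample], reference: HUDensityTable,
                    weights: list[float] | None = None) -> HUDensityTable:
    """Fit a CBCT HU-D table from VOI samples against a CT reference table.

    Each sample's density is its ``known_density`` when present, otherwise the
    reference table applied to its CT mean HU. Anchors are (CBCT mean HU,
    density) sorted by HU; density inversions are repaired by weighted
    pool-adjacent-violators (with a warning); coverage is extended to
    [-1000, 3000] HU by clamping the end densities.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 material classes (air, soft tissue, bone)")
    names = [s.material_class for s in samples]
    if len(set(names)) != len(names):
        raise ValueError("material_class labels must be unique per calibration set")
    if weights is None:
        weights = [1.0] * len(samples)

    pairs = []
    for s, w in zip(samples, weights):
        rho = s.known_density if s.known_density is not None \
            else float(reference.lookup(s.mean_hu_ct))
        pairs.append((float(s.mean_hu_cbct), rho, float(w)))
    pairs.sort(key=lambda p: p[0])

    hu = np.array([p[0] for p in pairs])
    if np.any(np.diff(hu) < 1.0):
        raise ValueError("duplicate CBCT HU anchors (closer than 1 HU)")

    rho = np.array([p[1] for p in pairs])
    w = np.array([p[2] for p in pairs])
    if np.any(np.diff(rho) < 0):
        fitted = _pool_adjacent_violators(rho, w)
        warnings.warn(
            "CBCT HU-D samples contain a density inversion; applied "
            "pool-adjacent-violators isotonic repair", stacklevel=2)
        rho = fitted

    anchors = list(zip(hu.tolist(), rho.tolist()))
    if hu[0] > _HU_COVER[0]:
        anchors.insert(0, (_HU_COVER[0], min(rho[0], _AIR_DENSITY)))
    if hu[-1] < _HU_COVER[1]:
        anchors.append((_HU_COVER[1], rho[-1]))
    return HUDensityTable("CBCT", anchors)


def rsp_from_density(grid: ImageGrid, table: RSPTable) -> ImageGrid:
    """Convert a density grid to relative stopping power (clamped linear)."""
    if grid.quantity != "density":
        raise ValueError(f"expected a density grid, got quantity={grid.quantity!r}")
    return grid.with_values(table.lookup(grid.values), quantity="RSP")


def apply_density_overrides(density: ImageGrid,
                            overrides: list[tuple[StructureMask, float]]) -> ImageGrid:
    """Force density inside override masks (e.g. solid-water base = 1.00)."""
    values = density.values.copy()
    for mask, rho in overrides:
        if mask.mask.shape != density.shape:
            raise ValueError(f"override {mask.name!r} geometry mismatch")
        values[mask.mask] = rho
    return density.with_values(values)
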