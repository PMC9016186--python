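"""Plain-text exchange formats: detector-plane ASCII and rigid transforms.

Detector ASCII dialect::

    # optional comments
    nx=27
    ny=27
    pitch_mm=10
    origin_mm=-130,-130
    depth_mm=122
    axis=1
    <ny rows of nx dose values (cGy), whitespace or comma delimited>
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .core import PlanarDose, RigidTransform

__all__ = [
    "read_measurement",
    "write_measurement",
    "read_transform",
    "write_transform",
]

_REQUIRED_KEYS = ("nx", "ny", "pitch_mm", "origin_mm", "depth_mm", "axis")


def write_measurement(plane: PlanarDose, path) -> str:
    """Serialize a planar dose in the detector ASCII dialect.

    Requires isotropic in-plane spacing (single ``pitch_mm`` header field).
    """
    sp = plane.in_plane_spacing
    if abs(sp[0] - sp[1]) > 1e-9:
        raise ValueError("detector ASCII format requires isotropic in-plane pitch")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nu, nv = plane.values.shape
    lines = [
        "# rangewedge detector plane",
        f"nx={nu}",
        f"ny={nv}",
        f"pitch_mm={sp[0]:.6g}",
        f"origin_mm={plane.in_plane_origin[0]:.6g},{plane.in_plane_origin[1]:.6g}",
        f"depth_mm={plane.depth:.6g}",
        f"axis={plane.plane_axis}",
    ]
    for j in range(nv):
        lines.append(" ".join(f"{v:.8g}" for v in plane.values[:, j]))
    path.write_text("\n".join(lines) + "\n")
    return str(path)


def read_measurement(path) -> PlanarDose:
    """Parse the detector ASCII dialect; delimiter may be whitespace or comma."""
    raw_lines = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    for lineno, line in enumerate(raw_lines, 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        m = re.match(r"^([A-Za-z_][A-Za-z0-9_]*)\s*=\s*(.*)$", line)
        if m and not rows:
            header[m.group(1)] = m.group(2).strip()
            continue
        try:
            rows.append([float(tok) for tok in re.split(r"[,\s]+", line) if tok])
        except ValueError as exc:
            raise ValueError(f"{path}: unparseable data row at line {lineno}") from exc

    for key in _REQUIRED_KEYS:
        if key not in header:
            raise ValueError(f"{path}: missing header key {key!r}")
    nx = int(header["nx"])
    ny = int(header["ny"])
    pitch = [float(t) for t in re.split(r"[,\s]+", header["pitch_mm"]) if t]
    if len(pitch) == 1:
        pitch = pitch * 2
    origin = [float(t) for t in re.split(r"[,\s]+", header["origin_mm"]) if t]
    if len(origin) != 2:
        raise ValueError(f"{path}: origin_mm must have exactly 2 values")

    if not rows:
        raise ValueError(f"{path}: header only, no data rows")
    if len(rows) != ny:
        raise ValueError(f"{path}: expected ny={ny} data rows, found {len(rows)}")
    for j, r in enumerate(rows):
        if len(r) != nx:
            raise ValueError(f"{path}: ragged row {j}: expected nx={nx} values, found {len(r)}")
    values = np.asarray(rows, dtype=float).T  # file rows are the v axis
    return PlanarDose(
        plane_axis=int(header["axis"]),
        depth=float(header["depth_mm"]),
        in_plane_origin=np.asarray(origin),
        in_plane_spacing=np.asarray(pitch),
        values=values,
    )


def write_transform(transform: RigidTransform, path) -> str:
    """Write a 4x4 transform as 4 lines x 4 numbers, row-major, mm."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [" ".join(f"{v:.12g}" for v in row) for row in transform.matrix]
    path.write_text("\n".join(lines) + "\n")
    return str(path)


def read_transform(path) -> RigidTransform:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            rows.append([float(t) for t in re.split(r"[,\s]+", line) if t])
    if len(rows) != 4 or any(len(r) != 4 for r in rows):
        raise ValueError(f"{path}: expected 4 lines of 4 numbers")
    return RigidTransform(np.asarray(rows, dtype=float))
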