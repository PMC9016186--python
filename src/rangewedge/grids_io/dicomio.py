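"""DICOM I/O: CT image series (read/write) and RT Dose (read/write).

Implements a deliberately small explicit-VR little-endian codec covering the
uncompressed tag set this package emits. It is not a general DICOM library:
sequences, compressed transfer syntaxes and undefined lengths are rejected.
"""

from __future__ import annotations

import os
import struct
import uuid
from pathlib import Path

import numpy as np

from .core import ImageGrid

__all__ = ["read_image_series", "write_image_series", "read_dose", "write_dose"]

_TRANSFER_SYNTAX_LE_EXPLICIT = "1.2.840.10008.1.2.1"
_SOP_CT = "1.2.840.10008.5.1.4.1.1.2"
_SOP_RTDOSE = "1.2.840.10008.5.1.4.1.1.481.2"
_UID_ROOT = "2.25"  # UUID-derived UIDs

# tags (group, element)
T_SOP_CLASS = (0x0008, 0x0016)
T_SOP_INSTANCE = (0x0008, 0x0018)
T_MODALITY = (0x0008, 0x0060)
T_SERIES_UID = (0x0020, 0x000E)
T_INSTANCE_NUMBER = (0x0020, 0x0013)
T_IMAGE_POSITION = (0x0020, 0x0032)
T_IMAGE_ORIENTATION = (0x0020, 0x0037)
T_SLICE_THICKNESS = (0x0018, 0x0050)
T_SAMPLES_PER_PIXEL = (0x0028, 0x0002)
T_PHOTOMETRIC = (0x0028, 0x0004)
T_NUM_FRAMES = (0x0028, 0x0008)
T_ROWS = (0x0028, 0x0010)
T_COLS = (0x0028, 0x0011)
T_PIXEL_SPACING = (0x0028, 0x0030)
T_BITS_ALLOCATED = (0x0028, 0x0100)
T_BITS_STORED = (0x0028, 0x0101)
T_HIGH_BIT = (0x0028, 0x0102)
T_PIXEL_REP = (0x0028, 0x0103)
T_RESCALE_INTERCEPT = (0x0028, 0x1052)
T_RESCALE_SLOPE = (0x0028, 0x1053)
T_DOSE_UNITS = (0x3004, 0x0002)
T_GRID_FRAME_OFFSETS = (0x3004, 0x000C)
T_DOSE_GRID_SCALING = (0x3004, 0x000E)
T_PIXEL_DATA = (0x7FE0, 0x0010)

_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}


def _new_uid() -> str:
    return f"{_UID_ROOT}.{uuid.uuid4().int}"


def _encode_element(tag: tuple[int, int], vr: bytes, payload: bytes) -> bytes:
    if len(payload) % 2:
        payload += b"\x00" if vr not in (b"UI",) else b"\x00"
    head = struct.pack("<HH", *tag) + vr
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(payload)) + payload
    return head + struct.pack("<H", len(payload)) + payload


def _txt(tag, vr: bytes, value) -> bytes:
    if isinstance(value, (list, tuple, np.ndarray)):
        s = "\\".join(_fmt(v) for v in value)
    else:
        s = _fmt(value)
    return _encode_element(tag, vr, s.encode("ascii"))


def _fmt(v) -> str:
    if isinstance(v, float):
        s = repr(v)
        if len(s) > 16:  # DS values are capped at 16 bytes
            s = f"{v:.9e}"
        return s
    return str(v)


def _us(tag, value: int) -> bytes:
    return _encode_element(tag, b"US", struct.pack("<H", value))


def _write_file(path: Path, sop_class: str, sop_instance: str, elements: bytes) -> None:
    meta_body = b"".join([
        _txt((0x0002, 0x0002), b"UI", sop_class),
        _txt((0x0002, 0x0003), b"UI", sop_instance),
        _txt((0x0002, 0x0010), b"UI", _TRANSFER_SYNTAX_LE_EXPLICIT),
        _txt((0x0002, 0x0012), b"UI", f"{_UID_ROOT}.0.1"),
    ])
    meta = _encode_element((0x0002, 0x0000), b"UL", struct.pack("<I", len(meta_body)))
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM")
        fh.write(meta + meta_body)
        fh.write(elements)


class _Reader:
    def __init__(self, data: bytes, path: str):
        self.data = data
        self.path = path
        self.pos = 0

    def read_dataset(self) -> dict:
        if self.data[128:132] != b"DICM":
            raise ValueError(f"{self.path}: missing DICM magic; not a DICOM part-10 file")
        self.pos = 132
        out: dict = {}
        n = len(self.data)
        while self.pos + 8 <= n:
            group, elem = struct.unpack_from("<HH", self.data, self.pos)
            vr = self.data[self.pos + 4:self.pos + 6]
            if vr in _LONG_VRS:
                (length,) = struct.unpack_from("<I", self.data, self.pos + 8)
                body_at = self.pos + 12
            else:
                (length,) = struct.unpack_from("<H", self.data, self.pos + 6)
                body_at = self.pos + 8
            if length == 0xFFFFFFFF:
                raise ValueError(f"{self.path}: undefined-length element "
                                 f"({group:04X},{elem:04X}) not supported")
            body = self.data[body_at:body_at + length]
            self.pos = body_at + length
            out[(group, elem)] = self._decode(vr, body)
        return out

    @staticmethod
    def _decode(vr: bytes, body: bytes):
        if vr in (b"UI", b"CS", b"LO", b"SH", b"PN", b"DA", b"TM", b"AS"):
            return body.decode("ascii", "replace").rstrip("\x00 ").strip()
        if vr == b"DS":
            s = body.decode("ascii", "replace").strip("\x00 ")
            vals = [float(x) for x in s.split("\\")] if s else []
            return vals[0] if len(vals) == 1 else vals
        if vr == b"IS":
            s = body.decode("ascii", "replace").strip("\x00 ")
            vals = [int(x) for x in s.split("\\")] if s else []
            return vals[0] if len(vals) == 1 else vals
        if vr == b"US":
            vals = list(struct.unpack(f"<{len(body)//2}H", body))
            return vals[0] if len(vals) == 1 else vals
        if vr == b"UL":
            vals = list(struct.unpack(f"<{len(body)//4}I", body))
            return vals[0] if len(vals) == 1 else vals
        return body  # raw bytes (pixel data etc.)


def _read_file(path) -> dict:
    with open(path, "rb") as fh:
        return _Reader(fh.read(), str(path)).read_dataset()


# ---------------------------------------------------------------------------
# CT image series
# ---------------------------------------------------------------------------

def write_image_series(grid: ImageGrid, directory) -> list[str]:
    """Write an HU grid as a DICOM CT series, one file per axis-2 slice.

    Values are stored as signed 16-bit integers with rescale slope 1 and
    intercept 0, so HU must fit in int16.
    """
    if grid.quantity != "HU":
        raise ValueError("write_image_series expects an HU grid")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = _new_uid()
    nx, ny, nz = grid.shape
    paths = []
    for k in range(nz):
        sop = _new_uid()
        pixels = np.round(grid.values[:, :, k]).astype(np.int16)
        # DICOM rows run along axis 1 (y), columns along axis 0 (x)
        raw = np.ascontiguousarray(pixels.T).tobytes()
        pos = [grid.origin[0], grid.origin[1], grid.origin[2] + k * grid.spacing[2]]
        body = b"".join([
            _txt(T_SOP_CLASS, b"UI", _SOP_CT),
            _txt(T_SOP_INSTANCE, b"UI", sop),
            _txt(T_MODALITY, b"CS", "CT"),
            _txt(T_SLICE_THICKNESS, b"DS", float(grid.spacing[2])),
            _txt(T_SERIES_UID, b"UI", series_uid),
            _txt(T_INSTANCE_NUMBER, b"IS", k + 1),
            _txt(T_IMAGE_POSITION, b"DS", [float(p) for p in pos]),
            _txt(T_IMAGE_ORIENTATION, b"DS", [1, 0, 0, 0, 1, 0]),
            _us(T_SAMPLES_PER_PIXEL, 1),
            _txt(T_PHOTOMETRIC, b"CS", "MONOCHROME2"),
            _us(T_ROWS, ny),
            _us(T_COLS, nx),
            _txt(T_PIXEL_SPACING, b"DS", [float(grid.spacing[1]), float(grid.spacing[0])]),
            _us(T_BITS_ALLOCATED, 16),
            _us(T_BITS_STORED, 16),
            _us(T_HIGH_BIT, 15),
            _us(T_PIXEL_REP, 1),
            _txt(T_RESCALE_INTERCEPT, b"DS", 0.0),
            _txt(T_RESCALE_SLOPE, b"DS", 1.0),
            _encode_element(T_PIXEL_DATA, b"OW", raw),
        ])
        path = directory / f"ct_{k:04d}.dcm"
        _write_file(path, _SOP_CT, sop, body)
        paths.append(str(path))
    return paths


def read_image_series(directory, frame: str = "patient",
                      spacing_tol: float = 0.01) -> ImageGrid:
    """Read a directory of single-frame DICOM CT slices into an HU grid.

    Slices must share orientation (axis-aligned identity) and in-plane
    geometry, and be uniformly spaced along the slice normal within
    ``spacing_tol`` mm.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir()
                   if p.is_file() and p.suffix.lower() in (".dcm", ".ima", ""))
    if not files:
        raise ValueError(f"no DICOM slices found in {directory}")
    slices = []
    ref_orient = None
    ref_file = None
    for p in files:
        ds = _read_file(p)
        orient = np.asarray(ds[T_IMAGE_ORIENTATION], dtype=float)
        if ref_orient is None:
            ref_orient, ref_file = orient, p
            if not np.allclose(orient, [1, 0, 0, 0, 1, 0], atol=1e-6):
                raise ValueError(f"{p.name}: non-axis-aligned orientation "
                                 f"{orient.tolist()} not supported")
        elif not np.allclose(orient, ref_orient, atol=1e-6):
            raise ValueError(
                f"mixed-orientation series: slice {p.name} orientation differs "
                f"from {ref_file.name}"
            )
        rows = ds[T_ROWS]
        cols = ds[T_COLS]
        pix_spacing = ds[T_PIXEL_SPACING]  # [row (y), col (x)]
        pos = np.asarray(ds[T_IMAGE_POSITION], dtype=float)
        slope = float(ds.get(T_RESCALE_SLOPE, 1.0))
        intercept = float(ds.get(T_RESCALE_INTERCEPT, 0.0))
        raw = np.frombuffer(ds[T_PIXEL_DATA], dtype="<i2", count=rows * cols)
        hu = raw.reshape(rows, cols).astype(float) * slope + intercept
        slices.append((pos, pix_spacing, hu, p.name))

    slices.sort(key=lambda s: s[0][2])
    pos0, pix_spacing0, _, name0 = slices[0]
    for pos, pix_spacing, _, name in slices[1:]:
        if not np.allclose(pix_spacing, pix_spacing0, atol=1e-6) or \
                not np.allclose(pos[:2], pos0[:2], atol=1e-6):
            raise ValueError(f"slice {name}: in-plane geometry differs from {name0}")

    zs = np.array([s[0][2] for s in slices])
    if len(zs) > 1:
        gaps = np.diff(zs)
        if np.any(gaps <= 0):
            raise ValueError("duplicate or non-increasing slice positions")
        if gaps.max() - gaps.min() > spacing_tol:
            raise ValueError(
                f"non-uniform slice spacing: gaps range "
                f"{gaps.min():.4f}..{gaps.max():.4f} mm exceeds {spacing_tol} mm tolerance"
            )
        dz = float(gaps.mean())
    else:
        dz = 1.0
    values = np.stack([s[2].T for s in slices], axis=2)  # (x, y, z)
    return ImageGrid(
        origin=np.array([pos0[0], pos0[1], zs[0]]),
        spacing=np.array([pix_spacing0[1], pix_spacing0[0], dz]),
        values=values,
        quantity="HU",
        frame=frame,
    )


# ---------------------------------------------------------------------------
# RT Dose
# ---------------------------------------------------------------------------

def write_dose(grid: ImageGrid, path) -> str:
    """Write a dose grid as a multiframe DICOM RT Dose file (uint32 pixels,
    DoseGridScaling chosen so the stored integers span the dose range)."""
    if grid.quantity != "dose":
        raise ValueError("write_dose expects a dose grid")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    max_dose = float(grid.values.max())
    scaling = max_dose / (2**32 - 1) if max_dose > 0 else 1.0
    scaling = float(_fmt(scaling))  # quantize to the stored DS representation
    pixels = np.round(grid.values / scaling).astype(np.uint32)
    nx, ny, nz = grid.shape
    # frame f is slice z=f; within a frame rows run along y, columns along x
    raw = np.ascontiguousarray(np.transpose(pixels, (2, 1, 0))).tobytes()
    offsets = [float(k * grid.spacing[2]) for k in range(nz)]
    sop = _new_uid()
    body = b"".join([
        _txt(T_SOP_CLASS, b"UI", _SOP_RTDOSE),
        _txt(T_SOP_INSTANCE, b"UI", sop),
        _txt(T_MODALITY, b"CS", "RTDOSE"),
        _txt(T_SERIES_UID, b"UI", _new_uid()),
        _txt(T_IMAGE_POSITION, b"DS", [float(v) for v in grid.origin]),
        _txt(T_IMAGE_ORIENTATION, b"DS", [1, 0, 0, 0, 1, 0]),
        _us(T_SAMPLES_PER_PIXEL, 1),
        _txt(T_PHOTOMETRIC, b"CS", "MONOCHROME2"),
        _txt(T_NUM_FRAMES, b"IS", nz),
        _us(T_ROWS, ny),
        _us(T_COLS, nx),
        _txt(T_PIXEL_SPACING, b"DS", [float(grid.spacing[1]), float(grid.spacing[0])]),
        _us(T_BITS_ALLOCATED, 32),
        _us(T_BITS_STORED, 32),
        _us(T_HIGH_BIT, 31),
        _us(T_PIXEL_REP, 0),
        _txt(T_DOSE_UNITS, b"CS", "CGY"),
        _txt(T_GRID_FRAME_OFFSETS, b"DS", offsets),
        _txt(T_DOSE_GRID_SCALING, b"DS", scaling),
        _encode_element(T_PIXEL_DATA, b"OW", raw),
    ])
    _write_file(path, _SOP_RTDOSE, sop, body)
    return str(path)


def read_dose(path, frame: str = "patient") -> ImageGrid:
    """Read a multiframe DICOM RT Dose file into a dose grid (cGy)."""
    ds = _read_file(path)
    if ds.get(T_MODALITY) != "RTDOSE":
        raise ValueError(f"{path}: not an RT Dose object")
    rows = ds[T_ROWS]
    cols = ds[T_COLS]
    nframes = int(ds[T_NUM_FRAMES])
    scaling = float(ds[T_DOSE_GRID_SCALING])
    offsets = np.atleast_1d(np.asarray(ds[T_GRID_FRAME_OFFSETS], dtype=float))
    pos = np.asarray(ds[T_IMAGE_POSITION], dtype=float)
    pix_spacing = ds[T_PIXEL_SPACING]
    raw = np.frombuffer(ds[T_PIXEL_DATA], dtype="<u4", count=nframes * rows * cols)
    values = raw.reshape(nframes, rows, cols).astype(float) * scaling
    if nframes > 1:
        steps = np.diff(offsets)
        if steps.max() - steps.min() > 1e-6:
            raise ValueError(f"{path}: non-uniform grid frame offsets")
        dz = float(steps.mean())
    else:
        dz = 1.0
    return ImageGrid(
        origin=pos,
        spacing=np.array([pix_spacing[1], pix_spacing[0], dz]),
        values=np.transpose(values, (2, 1, 0)),
        quantity="dose",
        frame=frame,
    )
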