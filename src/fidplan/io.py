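"""Reading and writing anatomy geometry.

Supported sources: DICOM RT-STRUCT structure sets (contour vertices via
pydicom), plain ``x,y,z`` CSV lists, and ascii PLY point clouds.  All
coordinates are millimetres in the file's patient coordinate system.

The PLY writer emits double-precision ascii so that a write/read
round-trip is lossless well below the 1e-6 mm contract.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pydicom

from .geometry import PointCloud3D

__all__ = [
    "read_structure_points",
    "write_points",
    "StructureNotFoundError",
    "PointFileParseError",
]

_FLOAT_FMT = "%.17g"  # exact double round-trip


class StructureNotFoundError(KeyError):
    """The requested structure name is absent from the structure set."""


class PointFileParseError(ValueError):
    """A point file contains rows that cannot be parsed as x,y,z."""


def read_structure_points(path: str | os.PathLike, structure_name: str | None = None) -> PointCloud3D:
    """Read a point cloud from an RT-STRUCT, CSV, or ascii PLY file.

    For DICOM structure sets, ``structure_name`` selects the ROI whose
    contour vertices are returned (slice order preserved as stored).
    For CSV/PLY the argument is ignored.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    suffix = p.suffix.lower()
    if suffix == ".csv":
        return _read_csv(p)
    if suffix == ".ply":
        return _read_ply(p)
    return _read_rtstruct(p, structure_name)


def write_points(cloud: PointCloud3D, path: str | os.PathLike, format: str | None = None) -> Path:
    """Write a cloud as CSV or ascii PLY; round-trips to < 1e-6 mm."""
    p = Path(path)
    fmt = (format or p.suffix.lstrip(".")).lower()
    if fmt == "csv":
        header = "x,y,z"
        np.savetxt(p, cloud.points, fmt=_FLOAT_FMT, delimiter=",",
                   header=header, comments="")
    elif fmt == "ply":
        _write_ply(cloud.points, p)
    else:
        raise ValueError(f"unsupported point format: {fmt!r} (use csv or ply)")
    return p


def _read_csv(path: Path) -> PointCloud3D:
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if lineno == 1 and any(_not_numeric(f) for f in fields):
                continue  # optional header
            try:
                vals = [float(f) for f in fields]
            except ValueError as exc:
                raise PointFileParseError(
                    f"{path}: non-numeric row at line {lineno}: {line!r}") from exc
            if len(vals) != 3:
                raise PointFileParseError(
                    f"{path}: expected 3 columns at line {lineno}, got {len(vals)}")
            rows.append(vals)
    if not rows:
        raise PointFileParseError(f"{path}: no data rows")
    return PointCloud3D(np.asarray(rows))


def _not_numeric(s: str) -> bool:
    try:
        float(s)
        return False
    except ValueError:
        return True


def _write_ply(points: np.ndarray, path: Path) -> None:
    n = points.shape[0]
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {n}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("end_header\n")
        for x, y, z in points:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")


def _read_ply(path: Path) -> PointCloud3D:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise PointFileParseError(f"{path}: not a PLY file")
        n_vertex = None
        while True:
            line = fh.readline()
            if not line:
                raise PointFileParseError(f"{path}: unterminated PLY header")
            line = line.strip()
            if line.startswith("format") and "ascii" not in line:
                raise PointFileParseError(f"{path}: only ascii PLY is supported")
            if line.startswith("element vertex"):
                n_vertex = int(line.split()[-1])
            if line == "end_header":
                break
        if n_vertex is None:
            raise PointFileParseError(f"{path}: missing vertex element")
        rows = []
        for k in range(n_vertex):
            line = fh.readline()
            try:
                vals = [float(f) for f in line.split()[:3]]
            except (ValueError, IndexError) as exc:
                raise PointFileParseError(
                    f"{path}: bad vertex row {k}: {line!r}") from exc
            rows.append(vals)
    return PointCloud3D(np.asarray(rows))


def _read_rtstruct(path: Path, structure_name: str | None) -> PointCloud3D:
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:
        raise PointFileParseError(f"{path}: not a readable DICOM file ({exc})") from exc
    if not hasattr(ds, "StructureSetROISequence"):
        raise PointFileParseError(f"{path}: DICOM file has no structure set")
    names = {int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence}
    if structure_name is None:
        if len(names) != 1:
            raise StructureNotFoundError(
                f"structure_name required; available: {sorted(names.values())}")
        structure_name = next(iter(names.values()))
    number = next((num for num, name in names.items() if name == structure_name), None)
    if number is None:
        raise StructureNotFoundError(
            f"structure {structure_name!r} not found; available: {sorted(names.values())}")
    contours = []
    for rc in getattr(ds, "ROIContourSequence", []):
        if int(rc.ReferencedROINumber) != number:
            continue
        for contour in getattr(rc, "ContourSequence", []):
            data = np.asarray([float(v) for v in contour.ContourData])
            contours.append(data.reshape(-1, 3))
    if not contours:
        raise StructureNotFoundError(
            f"structure {structure_name!r} has no contour data")
    return PointCloud3D(np.vstack(contours), label="tumor-surface")
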