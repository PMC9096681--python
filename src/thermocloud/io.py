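"""Readers and writers for point clouds, radiometric images and calibration files.

The on-disk contracts every other module consumes:

* PLY (``ascii`` and ``binary_little_endian``) point clouds whose vertex
  element carries ``x, y, z`` and, optionally, ``reflectance`` (laser
  return intensity, sensor units) and ``temperature`` (°C, 32-bit float).
  The out-of-view sentinel temperature is stored verbatim, never dropped.
* XYZ whitespace-separated text with 3 (coordinates), 4 (+reflectance) or
  5 (+temperature) columns.
* Radiometric thermal images as float32 TIFF or CSV grids, already in °C;
  no rescaling is ever applied on read.
* Calibration JSON/YAML with keys
  ``fx, fy, cx, cy, k1, k2, k3, p1, p2, R`` (row-major 9), ``t`` (3), ``units``.

Coordinates are metres throughout; unit conversion happens only at
configuration boundaries.  Image pixel origin is top-left, x rightward,
y downward, with pixel centres at integer coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

__all__ = [
    "FormatError",
    "CorruptFileError",
    "ThermalImage",
    "PointCloud",
    "read_point_cloud",
    "write_point_cloud",
    "read_thermal_image",
    "write_thermal_image",
    "read_calibration",
    "write_calibration",
]


class FormatError(ValueError):
    """The file does not conform to the expected dialect."""


class CorruptFileError(FormatError):
    """The file parses but its internal lengths/structure are inconsistent."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ThermalImage:
    """Radiometric image: a °C value per pixel, row-major, origin top-left."""

    values: np.ndarray
    timestamp: Optional[float] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] <= 0 or v.shape[1] <= 0:
            raise ValueError("image values must be a non-empty 2D grid")
        if not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite temperatures")
        self.values = v

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class PointCloud:
    """3D points (metres, sensor/rig frame) with per-point attributes.

    ``reflectance`` is the laser's backscattered return intensity (sensor
    units); ``temperature`` (°C) is present after fusion, where the
    out-of-view sentinel is a legal value.  Unknown file properties are
    preserved in ``extra``.
    """

    points: np.ndarray
    reflectance: Optional[np.ndarray] = None
    temperature: Optional[np.ndarray] = None
    frame_label: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        self.points = pts
        n = len(pts)
        for name in ("reflectance", "temperature"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float).reshape(-1)
                if len(arr) != n:
                    raise CorruptFileError(
                        f"{name} has {len(arr)} values for {n} points"
                    )
                setattr(self, name, arr)
        for key, arr in list(self.extra.items()):
            arr = np.asarray(arr)
            if len(arr) != n:
                raise CorruptFileError(f"extra property {key!r} length mismatch")
            self.extra[key] = arr

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask_or_index) -> "PointCloud":
        """Sub-cloud by boolean mask or index array; attributes follow."""
        idx = np.asarray(mask_or_index)
        return PointCloud(
            self.points[idx],
            None if self.reflectance is None else self.reflectance[idx],
            None if self.temperature is None else self.temperature[idx],
            self.frame_label,
            {k: v[idx] for k, v in self.extra.items()},
        )

    def with_temperature(self, temperature: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.points, self.reflectance, temperature, self.frame_label, dict(self.extra)
        )


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

_PLY_DTYPES = {
    "float": "<f4", "float32": "<f4",
    "double": "<f8", "float64": "<f8",
    "char": "<i1", "int8": "<i1",
    "uchar": "<u1", "uint8": "<u1",
    "short": "<i2", "int16": "<i2",
    "ushort": "<u2", "uint16": "<u2",
    "int": "<i4", "int32": "<i4",
    "uint": "<u4", "uint32": "<u4",
}


def _parse_ply_header(fh) -> tuple:
    magic = fh.readline().strip()
    if magic != b"ply":
        raise FormatError("not a PLY file")
    fmt = None
    elements = []  # list of (name, count, [(prop_name, dtype_str)])
    while True:
        line = fh.readline()
        if not line:
            raise CorruptFileError("PLY header ends without end_header")
        tokens = line.decode("ascii", errors="replace").split()
        if not tokens or tokens[0] == "comment":
            continue
        if tokens[0] == "format":
            fmt = tokens[1]
        elif tokens[0] == "element":
            elements.append((tokens[1], int(tokens[2]), []))
        elif tokens[0] == "property":
            if not elements:
                raise FormatError("property before any element")
            if tokens[1] == "list":
                elements[-1][2].append((tokens[-1], "list"))
            else:
                if tokens[1] not in _PLY_DTYPES:
                    raise FormatError(f"unsupported PLY type {tokens[1]!r}")
                elements[-1][2].append((tokens[-1], _PLY_DTYPES[tokens[1]]))
        elif tokens[0] == "end_header":
            break
    if fmt not in ("ascii", "binary_little_endian"):
        raise FormatError(f"unsupported PLY format {fmt!r}")
    return fmt, elements


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        fmt, elements = _parse_ply_header(fh)
        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None:
            raise FormatError("PLY has no vertex element")
        _, count, props = vertex
        if any(dt == "list" for _, dt in props):
            raise FormatError("list properties on the vertex element are unsupported")
        names = [p for p, _ in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise FormatError(f"vertex element lacks {axis!r} coordinate")
        dtype = np.dtype([(p, dt) for p, dt in props])
        if fmt == "binary_little_endian":
            if elements.index(vertex) != 0:
                raise FormatError("binary PLY must lead with the vertex element")
            raw = fh.read(dtype.itemsize * count)
            if len(raw) < dtype.itemsize * count:
                raise CorruptFileError(
                    f"vertex data truncated: expected {count} records"
                )
            table = np.frombuffer(raw, dtype=dtype, count=count)
        else:
            rows = []
            for _ in range(count):
                line = fh.readline()
                if not line.strip():
                    raise CorruptFileError(
                        f"vertex data truncated: expected {count} records"
                    )
                vals = line.split()
                if len(vals) != len(props):
                    raise CorruptFileError("vertex row has wrong field count")
                rows.append(tuple(float(v) for v in vals))
            table = np.array(rows, dtype=dtype)
    pts = np.column_stack([table["x"], table["y"], table["z"]]).astype(float)
    refl = table["reflectance"].astype(float) if "reflectance" in names else None
    temp = table["temperature"].astype(float) if "temperature" in names else None
    extra = {
        p: np.array(table[p])
        for p in names
        if p not in ("x", "y", "z", "reflectance", "temperature")
    }
    return PointCloud(pts, refl, temp, frame_label=str(path), extra=extra)


def _ply_columns(cloud: PointCloud) -> list:
    """(name, ply_type, numpy dtype, values) per vertex property."""
    cols = [
        ("x", "double", "<f8", cloud.points[:, 0]),
        ("y", "double", "<f8", cloud.points[:, 1]),
        ("z", "double", "<f8", cloud.points[:, 2]),
    ]
    if cloud.reflectance is not None:
        cols.append(("reflectance", "float", "<f4", cloud.reflectance))
    if cloud.temperature is not None:
        cols.append(("temperature", "float", "<f4", cloud.temperature))
    for key, arr in cloud.extra.items():
        if np.issubdtype(np.asarray(arr).dtype, np.integer):
            cols.append((key, "int", "<i4", np.asarray(arr)))
        else:
            cols.append((key, "float", "<f4", np.asarray(arr)))
    return cols


def _write_ply(cloud: PointCloud, path: Path, binary: bool) -> None:
    cols = _ply_columns(cloud)
    header = ["ply"]
    header.append(
        "format binary_little_endian 1.0" if binary else "format ascii 1.0"
    )
    header.append(f"element vertex {len(cloud)}")
    header += [f"property {ply_t} {name}" for name, ply_t, _, _ in cols]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            table = np.empty(len(cloud), dtype=[(n, dt) for n, _, dt, _ in cols])
            for name, _, _, vals in cols:
                table[name] = vals
            fh.write(table.tobytes())
        else:
            arrays = [np.asarray(vals) for _, _, _, vals in cols]
            f32 = [dt == "<f4" for _, _, dt, _ in cols]
            for i in range(len(cloud)):
                fields = []
                for arr, narrow in zip(arrays, f32):
                    v = np.float32(arr[i]) if narrow else arr[i]
                    fields.append(f"{v:.9g}" if narrow else f"{v:.17g}")
                fh.write((" ".join(fields) + "\n").encode("ascii"))


def read_point_cloud(path, format: Optional[str] = None) -> PointCloud:
    """Read a PLY or XYZ point cloud.

    ``format`` is inferred from the suffix when omitted (``.ply`` / anything
    else is treated as XYZ text).
    """
    path = Path(path)
    if format is None:
        format = "ply" if path.suffix.lower() == ".ply" else "xyz"
    if format == "ply":
        return _read_ply(path)
    if format == "xyz":
        try:
            data = np.loadtxt(path, dtype=float, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"malformed XYZ text: {exc}") from exc
        if data.size == 0:
            return PointCloud(np.zeros((0, 3)))
        if data.shape[1] < 3:
            raise FormatError("XYZ text needs at least 3 columns")
        refl = data[:, 3] if data.shape[1] > 3 else None
        temp = data[:, 4] if data.shape[1] > 4 else None
        return PointCloud(data[:, :3], refl, temp, frame_label=str(path))
    raise ValueError(f"unknown point-cloud format {format!r}")


def write_point_cloud(cloud: PointCloud, path, format: str = "ply_binary") -> None:
    """Write ``cloud`` as ``ply_ascii``, ``ply_binary`` or ``xyz``."""
    path = Path(path)
    if format == "ply_ascii":
        _write_ply(cloud, path, binary=False)
    elif format in ("ply_binary", "ply"):
        _write_ply(cloud, path, binary=True)
    elif format == "xyz":
        cols = [cloud.points]
        if cloud.reflectance is not None:
            cols.append(cloud.reflectance[:, None])
            if cloud.temperature is not None:
                cols.append(cloud.temperature[:, None])
        elif cloud.temperature is not None:
            raise ValueError("XYZ dialect cannot store temperature without reflectance")
        np.savetxt(path, np.hstack(cols), fmt="%.17g")
    else:
        raise ValueError(f"unknown point-cloud format {format!r}")


# ---------------------------------------------------------------------------
# thermal images
# ---------------------------------------------------------------------------


def read_thermal_image(path, format: Optional[str] = None) -> ThermalImage:
    """Read a radiometric image (values already °C; no rescaling)."""
    path = Path(path)
    if format is None:
        format = "tiff32" if path.suffix.lower() in (".tif", ".tiff") else "csv"
    if format == "tiff32":
        return ThermalImage(tifffile.imread(path).astype(float))
    if format == "csv":
        try:
            grid = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"non-rectangular or malformed CSV grid: {exc}") from exc
        return ThermalImage(grid)
    raise ValueError(f"unknown image format {format!r}")


def write_thermal_image(image: ThermalImage, path, format: Optional[str] = None) -> None:
    path = Path(path)
    if format is None:
        format = "tiff32" if path.suffix.lower() in (".tif", ".tiff") else "csv"
    if format == "tiff32":
        tifffile.imwrite(path, image.values.astype(np.float32))
    elif format == "csv":
        np.savetxt(path, image.values, delimiter=",", fmt="%.9g")
    else:
        raise ValueError(f"unknown image format {format!r}")


# ---------------------------------------------------------------------------
# calibration files
# ---------------------------------------------------------------------------


def write_calibration(path, intrinsics=None, extrinsics=None, metadata: Optional[dict] = None) -> None:
    """Serialise intrinsics and/or extrinsics to JSON or YAML (by suffix).

    The schema is flat: ``fx, fy, cx, cy, k1, k2, k3, p1, p2`` for the
    camera, ``R`` (row-major 9) and ``t`` (3) for the rigid transform, and a
    ``units`` tag (always metres/pixels here).  Round-trips are lossless to
    full float precision.
    """
    doc: dict = {"units": "m"}
    if intrinsics is not None:
        for k in ("fx", "fy", "cx", "cy", "k1", "k2", "k3", "p1", "p2"):
            doc[k] = float(getattr(intrinsics, k))
    if extrinsics is not None:
        doc["R"] = [float(v) for v in np.asarray(extrinsics.R).reshape(9)]
        doc["t"] = [float(v) for v in np.asarray(extrinsics.t).reshape(3)]
    if metadata:
        doc["metadata"] = metadata
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            yaml.safe_dump(doc, fh)
        else:
            json.dump(doc, fh, indent=2)


def read_calibration(path) -> dict:
    """Read a calibration file; returns ``{"intrinsics":, "extrinsics":, "metadata":}``.

    Missing halves come back as ``None``.
    """
    from .geometry import RigidTransform
    from .intrinsics import CameraIntrinsics

    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) if path.suffix.lower() in (".yaml", ".yml") else json.load(fh)
    intr = None
    if "fx" in doc:
        intr = CameraIntrinsics(
            fx=doc["fx"], fy=doc["fy"], cx=doc["cx"], cy=doc["cy"],
            k1=doc.get("k1", 0.0), k2=doc.get("k2", 0.0), k3=doc.get("k3", 0.0),
            p1=doc.get("p1", 0.0), p2=doc.get("p2", 0.0),
        )
    extr = None
    if "R" in doc:
        extr = RigidTransform(np.asarray(doc["R"], dtype=float).reshape(3, 3), doc["t"])
    return {"intrinsics": intr, "extrinsics": extr, "metadata": doc.get("metadata", {})}
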