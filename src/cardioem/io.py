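"""File I/O: multi-page TIFF stacks, NRRD label masks, CSV/JSON tables.

TIFF intensity stacks store one page per z-slice (page rows/columns map to the
y/x image axes).  Label volumes go to NRRD (a plain text header followed by
raw or gzip-compressed voxel data) or to uint8 TIFF.  Tabular outputs — angle
tables, fraction reports, summaries — are CSV/JSON with locale-independent
formatting.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import math
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import VolumeGeometry
from .volumes import LabelVolume, VoxelVolume

ANGLE_TABLE_COLUMNS = ["object_id", "theta_deg", "phi_deg", "n_voxels"]
TRUTH_ANGLE_COLUMNS = ["fibril_id", "theta_true_deg", "phi_true_deg"]


# ---------------------------------------------------------------------------
# TIFF stacks


def read_stack(path: str | Path, geometry: VolumeGeometry | None = None) -> VoxelVolume:
    """Read a multi-page TIFF into a :class:`VoxelVolume`.

    The z dimension equals the page count.  Default geometry is the SBF-SEM
    acquisition grid (10, 10, 40) nm unless overridden.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack not found: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        pages = [p.asarray() for p in tif.pages]
    if not pages:
        raise ValueError(f"no pages in {path}")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"ragged pages in {path}: shapes {sorted(shapes)}")
    first = pages[0]
    if first.ndim != 2:
        raise ValueError(f"unsupported page dimensionality {first.ndim} in {path}")
    if first.dtype not in (np.uint8, np.uint16, np.int16, np.float32, np.float64):
        raise ValueError(f"unsupported bit depth {first.dtype} in {path}")
    data = np.stack(pages, axis=-1)
    return VoxelVolume(data, geometry or VolumeGeometry())


def write_stack(volume: VoxelVolume | np.ndarray, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF, one page per z-slice."""
    path = Path(path)
    data = volume.data if isinstance(volume, VoxelVolume) else np.asarray(volume)
    pages = np.moveaxis(data, -1, 0)  # (z, rows, cols)
    tifffile.imwrite(str(path), pages, photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# NRRD (minimal reader/writer: raw or gzip encoding, fixed little-endian)

_NRRD_DTYPES = {
    "uint8": np.uint8,
    "uchar": np.uint8,
    "uint16": np.uint16,
    "unsigned short": np.uint16,
    "int16": np.int16,
    "short": np.int16,
    "int32": np.int32,
    "int": np.int32,
    "float": np.float32,
    "double": np.float64,
}
_NRRD_NAMES = {np.uint8: "uint8", np.uint16: "uint16", np.int16: "int16",
               np.int32: "int32", np.float32: "float", np.float64: "double"}


def write_nrrd(data: np.ndarray, path: str | Path, *,
               spacings: tuple[float, float, float] | None = None,
               encoding: str = "gzip") -> Path:
    """Write a 3D array as an attached-header NRRD file.

    Axis order on disk is the in-memory order (row, column, slice); the
    ``spacings`` field records physical voxel sizes per on-disk axis.
    """
    path = Path(path)
    data = np.ascontiguousarray(data)
    if data.ndim != 3:
        raise ValueError("only 3D volumes are supported")
    if encoding not in ("raw", "gzip"):
        raise ValueError(f"unsupported encoding {encoding!r}")
    dtype_name = _NRRD_NAMES.get(data.dtype.type)
    if dtype_name is None:
        raise ValueError(f"unsupported dtype {data.dtype}")
    lines = [
        "NRRD0004",
        "# generated by cardioem",
        f"type: {dtype_name}",
        "dimension: 3",
        f"sizes: {data.shape[0]} {data.shape[1]} {data.shape[2]}",
        f"encoding: {encoding}",
        "endian: little",
    ]
    if spacings is not None:
        lines.append("spacings: " + " ".join(repr(float(s)) for s in spacings))
    header = "\n".join(lines) + "\n\n"
    # NRRD sizes are listed fastest-varying first, so write Fortran-order bytes.
    payload = data.astype(data.dtype.newbyteorder("<"), copy=False).tobytes(order="F")
    if encoding == "gzip":
        payload = gzip.compress(payload)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(payload)
    return path


def read_nrrd(path: str | Path) -> tuple[np.ndarray, dict[str, str]]:
    """Read an attached-header NRRD file written by :func:`write_nrrd`
    (or any raw/gzip little-endian 3D NRRD)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NRRD file not found: {path}")
    with open(path, "rb") as fh:
        blob = fh.read()
    sep = blob.find(b"\n\n")
    if sep < 0 or not blob.startswith(b"NRRD"):
        raise ValueError(f"not a valid NRRD file: {path}")
    header_lines = blob[:sep].decode("ascii", errors="replace").splitlines()[1:]
    fields: dict[str, str] = {}
    for line in header_lines:
        if line.startswith("#") or ":" not in line:
            continue
        key, val = line.split(":", 1)
        fields[key.strip().lower()] = val.strip()
    dtype = _NRRD_DTYPES.get(fields.get("type", ""))
    if dtype is None:
        raise ValueError(f"unsupported NRRD type {fields.get('type')!r}")
    if int(fields.get("dimension", "0")) != 3:
        raise ValueError("only 3-dimensional NRRD volumes are supported")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    endian = fields.get("endian", "little")
    if endian != "little" and np.dtype(dtype).itemsize > 1:
        raise ValueError(f"unsupported endian {endian!r}")
    encoding = fields.get("encoding", "raw")
    payload = blob[sep + 2:]
    if encoding in ("gzip", "gz"):
        payload = gzip.decompress(payload)
    elif encoding != "raw":
        raise ValueError(f"unsupported NRRD encoding {encoding!r}")
    arr = np.frombuffer(payload, dtype=np.dtype(dtype).newbyteorder("<"))
    expected = int(np.prod(sizes))
    if arr.size != expected:
        raise ValueError(f"NRRD payload has {arr.size} values, expected {expected}")
    # sizes are fastest-first: reshape in Fortran order back to (row, col, slice)
    return arr.reshape(sizes, order="F").astype(dtype), fields


def write_label_volume(labels: LabelVolume, path: str | Path) -> Path:
    """Write a label volume as uint8 NRRD (``.nrrd``) or TIFF (``.tif``)."""
    path = Path(path)
    data = labels.data.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), np.moveaxis(data, -1, 0),
                         photometric="minisblack")
    else:
        write_nrrd(data, path, spacings=_disk_spacings(labels.geometry))
    return path


def read_label_volume(path: str | Path, class_map: Mapping[int, str],
                      geometry: VolumeGeometry | None = None) -> LabelVolume:
    """Read a label mask (NRRD or TIFF) and validate it against a class map.

    Raises ``ValueError`` listing any voxel values missing from the class map.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        vol = read_stack(path)
        data, geo = vol.data, (geometry or vol.geometry)
    else:
        data, fields = read_nrrd(path)
        if geometry is None and "spacings" in fields:
            sy, sx, sz = (float(v) for v in fields["spacings"].split())
            geometry = VolumeGeometry(spacing=(sx, sy, sz))
        geo = geometry or VolumeGeometry()
    if not np.issubdtype(data.dtype, np.integer):
        raise TypeError(f"label file {path} holds non-integer data ({data.dtype})")
    return LabelVolume(data.astype(np.int64), dict(class_map), geo)


def _disk_spacings(geometry: VolumeGeometry) -> tuple[float, float, float]:
    sx, sy, sz = geometry.spacing
    return (sy, sx, sz)  # on-disk axes are (row, col, slice)


# ---------------------------------------------------------------------------
# Tables and reports


def write_angle_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-object angle table (object_id, theta_deg, phi_deg, n_voxels)."""
    path = Path(path)
    missing = [c for c in ANGLE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"angle table missing columns {missing}")
    df.loc[:, ANGLE_TABLE_COLUMNS].to_csv(path, index=False, float_format="%.10g")
    return path


def read_angle_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("object_id", "theta_deg") if c not in df.columns]
    if missing:
        raise ValueError(f"angle table {path} missing columns {missing}")
    return df


def write_report(report: Any, path: str | Path) -> Path:
    """Serialize a report object (anything with ``to_dict``) to JSON or CSV.

    Mandatory numeric fields must be finite; fields whose value is ``None``
    (explicitly undefined quantities) are preserved as nulls.
    """
    path = Path(path)
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    _check_finite(payload)
    if path.suffix.lower() == ".csv":
        pd.DataFrame([_flatten(payload)]).to_csv(path, index=False, float_format="%.12g")
    else:
        with open(path, "w", encoding="ascii") as fh:
            json.dump(payload, fh, indent=2, allow_nan=False)
            fh.write("\n")
    return path


def read_report(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        row = df.iloc[0].to_dict()
        return {k: (None if isinstance(v, float) and math.isnan(v) else v)
                for k, v in row.items()}
    with open(path, encoding="ascii") as fh:
        return json.load(fh)


def _check_finite(obj: Any, key: str = "") -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_finite(v, k)
    elif isinstance(obj, (list, tuple)):
        for v in obj:
            _check_finite(v, key)
    elif isinstance(obj, float) and not math.isfinite(obj):
        raise ValueError(f"non-finite value in mandatory report field {key!r}")


def _flatten(d: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, Mapping):
            out.update(_flatten(v, key + "."))
        elif isinstance(v, (list, tuple)):
            out[key] = ";".join(str(x) for x in v)
        else:
            out[key] = v
    return out


# ---------------------------------------------------------------------------
# Configuration and provenance


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML/JSON configuration file; a ``seed`` key is mandatory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    if "seed" not in cfg:
        raise ValueError(f"config {path} must declare a 'seed'")
    return cfg


def config_hash(cfg: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
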