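"""Point-cloud container and PLY/PCD file I/O.

The pipeline's universal currency is a set of N metric 3D points with an
optional per-point integer label channel (stem / leaf instance ids). PLY is
supported in both ascii and binary little-endian flavours; PCD as ascii.
Coordinates are stored and written as float64 so fixtures round-trip
losslessly.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PointCloud", "read_cloud", "write_cloud"]

_PLY_TYPES = {
    "float": ("f", np.float32),
    "float32": ("f", np.float32),
    "double": ("d", np.float64),
    "float64": ("d", np.float64),
    "int": ("i", np.int32),
    "int32": ("i", np.int32),
    "uint": ("I", np.uint32),
    "uchar": ("B", np.uint8),
    "uint8": ("B", np.uint8),
    "short": ("h", np.int16),
    "ushort": ("H", np.uint16),
    "char": ("b", np.int8),
}


@dataclass
class PointCloud:
    """N x 3 metric points, gravity along +Y, with optional integer labels."""

    points: np.ndarray
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {self.points.shape}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self.points),):
                raise ValueError(
                    f"labels length {self.labels.shape} does not match "
                    f"{len(self.points)} points"
                )

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask_or_index: np.ndarray) -> "PointCloud":
        """Sub-cloud by boolean mask or integer index array (order preserved)."""
        labels = None if self.labels is None else self.labels[mask_or_index]
        return PointCloud(self.points[mask_or_index], labels)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points.min(axis=0), self.points.max(axis=0)


def write_cloud(cloud: PointCloud, path: str | Path, binary: bool = False) -> None:
    """Write a cloud to PLY (``.ply``, ascii or binary_little_endian) or ascii PCD."""
    path = Path(path)
    if path.suffix.lower() == ".pcd":
        _write_pcd(cloud, path)
    else:
        _write_ply(cloud, path, binary=binary)


def read_cloud(path: str | Path) -> PointCloud:
    """Read a PLY or PCD file into a :class:`PointCloud`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such point-cloud file: {path}")
    if path.suffix.lower() == ".pcd":
        return _read_pcd(path)
    return _read_ply(path)


# ---------------------------------------------------------------- PLY


def _write_ply(cloud: PointCloud, path: Path, binary: bool) -> None:
    n = len(cloud)
    has_labels = cloud.labels is not None
    fmt = "binary_little_endian" if binary else "ascii"
    header = [
        "ply",
        f"format {fmt} 1.0",
        f"element vertex {n}",
        "property double x",
        "property double y",
        "property double z",
    ]
    if has_labels:
        header.append("property int label")
    header.append("end_header")
    try:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            if binary:
                dtype = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
                if has_labels:
                    dtype.append(("label", "<i4"))
                rec = np.empty(n, dtype=dtype)
                rec["x"], rec["y"], rec["z"] = cloud.points.T
                if has_labels:
                    rec["label"] = cloud.labels
                fh.write(rec.tobytes())
            else:
                for i in range(n):
                    x, y, z = cloud.points[i]
                    line = f"{x:.17g} {y:.17g} {z:.17g}"
                    if has_labels:
                        line += f" {int(cloud.labels[i])}"
                    fh.write((line + "\n").encode("ascii"))
    except OSError as exc:
        raise OSError(f"failed writing PLY to {path}: {exc}") from exc


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        data = fh.read()
    end = data.find(b"end_header")
    if end < 0:
        raise ValueError(f"{path}: not a PLY file (no end_header)")
    header = data[:end].decode("ascii", errors="replace").splitlines()
    body = data[end:]
    body = body[body.find(b"\n") + 1 :]

    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    for line in header:
        tok = line.strip().split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertex = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            if tok[1] == "list":
                raise ValueError(f"{path}: list properties on vertices unsupported")
            props.append((tok[2], tok[1]))
    if fmt is None or n_vertex is None:
        raise ValueError(f"{path}: malformed PLY header")
    names = [p[0] for p in props]
    for ax in "xyz":
        if ax not in names:
            raise ValueError(f"{path}: vertex element missing property '{ax}'")

    if fmt == "ascii":
        rows = np.loadtxt(
            [ln for ln in body.decode("ascii").splitlines() if ln.strip()],
            dtype=np.float64,
            ndmin=2,
        ) if n_vertex else np.empty((0, len(props)))
        rows = rows[:n_vertex]
        cols = {name: rows[:, i] for i, (name, _t) in enumerate(props)}
    elif fmt == "binary_little_endian":
        dtype = np.dtype([(name, "<" + np.dtype(_PLY_TYPES[t][1]).char) for name, t in props])
        rec = np.frombuffer(body[: dtype.itemsize * n_vertex], dtype=dtype, count=n_vertex)
        cols = {name: rec[name].astype(np.float64) for name, _t in props}
    else:
        raise ValueError(f"{path}: unsupported PLY format '{fmt}'")

    pts = np.column_stack([cols["x"], cols["y"], cols["z"]])
    labels = cols["label"].astype(np.int64) if "label" in cols else None
    return PointCloud(pts, labels)


# ---------------------------------------------------------------- PCD (ascii)


def _write_pcd(cloud: PointCloud, path: Path) -> None:
    has_labels = cloud.labels is not None
    fields = "x y z" + (" label" if has_labels else "")
    n = len(cloud)
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\n"
        f"FIELDS {fields}\n"
        f"SIZE {'8 8 8 4' if has_labels else '8 8 8'}\n"
        f"TYPE {'F F F I' if has_labels else 'F F F'}\n"
        f"COUNT {'1 1 1 1' if has_labels else '1 1 1'}\n"
        f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i in range(n):
            x, y, z = cloud.points[i]
            line = f"{x:.17g} {y:.17g} {z:.17g}"
            if has_labels:
                line += f" {int(cloud.labels[i])}"
            fh.write(line + "\n")


def _read_pcd(path: Path) -> PointCloud:
    fields: list[str] = []
    n = 0
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        tok = line.strip().split()
        if not tok or tok[0] == "#":
            continue
        if tok[0] == "FIELDS":
            fields = tok[1:]
        elif tok[0] == "POINTS":
            n = int(tok[1])
        elif tok[0] == "DATA":
            if tok[1] != "ascii":
                raise ValueError(f"{path}: only ascii PCD supported")
            data_start = i + 1
            break
    rows = np.loadtxt(lines[data_start : data_start + n], dtype=np.float64, ndmin=2)
    idx = {f: j for j, f in enumerate(fields)}
    pts = np.column_stack([rows[:, idx["x"]], rows[:, idx["y"]], rows[:, idx["z"]]])
    labels = rows[:, idx["label"]].astype(np.int64) if "label" in idx else None
    return PointCloud(pts, labels)
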