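"""Core geometry types and I/O: point clouds, triangle meshes, k-NN queries.

File formats: XYZ (whitespace text, 3 or 6 columns), PLY (ASCII and
binary little-endian) and OBJ (``v``/``f`` records, quads fan-split).
Face indices are 0-based internally; OBJ's 1-based indexing is converted
at the I/O boundary.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ParseError",
    "PointCloud",
    "TriangleMesh",
    "NeighborIndex",
    "read_point_cloud",
    "write_point_cloud",
    "read_mesh",
    "write_mesh",
    "knn",
]

_NORMAL_TOL = 1e-6


class ParseError(ValueError):
    """Raised when a geometry file is syntactically or semantically malformed."""


@dataclass
class PointCloud:
    """A 3D point set with optional unit normals and per-point confidence.

    Parameters
    ----------
    points : (n, 3) float array
        Sample positions. Must be non-empty and finite.
    normals : (n, 3) float array, optional
        Unit normals (each within 1e-6 of unit length).
    confidence : (n,) float array, optional
        Per-point weights in [0, 1].
    """

    points: np.ndarray
    normals: np.ndarray | None = None
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {self.points.shape}")
        if len(self.points) == 0:
            raise ValueError("point cloud must be non-empty")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points contain non-finite coordinates")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64)
            if self.normals.shape != self.points.shape:
                raise ValueError("normals must match points in shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if np.any(np.abs(norms - 1.0) > _NORMAL_TOL):
                raise ValueError("normals must be unit length (within 1e-6)")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=np.float64)
            if self.confidence.shape != (len(self.points),):
                raise ValueError("confidence must be (n,)")
            if np.any(self.confidence < 0) or np.any(self.confidence > 1):
                raise ValueError("confidence values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_normals(self) -> bool:
        return self.normals is not None

    def copy(self) -> "PointCloud":
        return PointCloud(
            self.points.copy(),
            None if self.normals is None else self.normals.copy(),
            None if self.confidence is None else self.confidence.copy(),
        )


@dataclass
class TriangleMesh:
    """An orientation-bearing triangle mesh (0-based face indices)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError(f"faces must be (m, 3), got {self.faces.shape}")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face indices out of range")
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValueError("faces with repeated vertex indices are not allowed")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """All directed edges, one triple per face unrolled to (3m, 2)."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def is_watertight(self) -> bool:
        """True iff every undirected edge is shared by exactly two faces."""
        if len(self.faces) == 0:
            return False
        e = np.sort(self.edges(), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())


@dataclass
class NeighborIndex:
    """Exact k-nearest-neighbor table (self excluded, ties by lower index)."""

    k: int
    indices: np.ndarray  # (n, k) int
    distances: np.ndarray  # (n, k) float, ascending per row

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if self.indices.shape != self.distances.shape:
            raise ValueError("indices and distances must have the same shape")
        if self.indices.shape[1] != self.k:
            raise ValueError("neighbor lists must have exactly k entries")


def knn(cloud: PointCloud, k: int) -> NeighborIndex:
    """Exact Euclidean k-nearest neighbors for every point in *cloud*.

    A point never lists itself; equidistant ties are broken toward the
    lower point index so results are deterministic.
    """
    n = len(cloud)
    if k < 1:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the point count n={n}")
    pts = cloud.points
    tree = cKDTree(pts)
    # query k+2 so a tie straddling the cut can be detected and repaired
    m = min(n, k + 2)
    dist, idx = tree.query(pts, k=m)
    dist, idx = _drop_self(dist, idx, k)
    # repair rows where the kept/dropped boundary is a tie (rare)
    if dist.shape[1] > k:
        boundary_tie = np.isclose(dist[:, k - 1], dist[:, k], rtol=1e-12, atol=0.0)
        dist, idx = dist[:, :k].copy(), idx[:, :k].copy()
        for row in np.nonzero(boundary_tie)[0]:
            d_row = np.linalg.norm(pts - pts[row], axis=1)
            order = np.lexsort((np.arange(n), d_row))
            order = order[order != row][:k]
            idx[row] = order
            dist[row] = d_row[order]
    else:
        dist, idx = dist[:, :k], idx[:, :k]
    # enforce lower-index tie-break inside each row
    order = np.lexsort((idx, dist), axis=1)
    rows = np.arange(n)[:, None]
    return NeighborIndex(k=k, indices=idx[rows, order], distances=dist[rows, order])


def _drop_self(dist: np.ndarray, idx: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    n, m = idx.shape
    rows = np.arange(n)
    self_pos = np.argmax(idx == rows[:, None], axis=1)
    # when duplicated points exist, self may not be listed first; mask it out
    keep = np.ones((n, m), dtype=bool)
    keep[rows, self_pos] = False
    out_m = m - 1
    return (
        dist[keep].reshape(n, out_m),
        idx[keep].reshape(n, out_m),
    )


# ---------------------------------------------------------------------------
# point cloud I/O


def read_point_cloud(path: str | Path, format: str | None = None) -> PointCloud:
    """Read a point cloud from an XYZ or PLY file.

    Normals are renormalized on read; a zero-norm normal is a parse error.
    """
    path = Path(path)
    fmt = _infer_format(path, format, {"xyz", "ply"})
    if fmt == "xyz":
        return _read_xyz(path)
    return _read_ply_cloud(path)


def write_point_cloud(
    cloud: PointCloud, path: str | Path, format: str | None = None, binary: bool = False
) -> None:
    """Write a point cloud as XYZ text or PLY (ASCII, or binary LE if asked)."""
    path = Path(path)
    fmt = _infer_format(path, format, {"xyz", "ply"})
    if fmt == "xyz":
        cols = [cloud.points]
        if cloud.normals is not None:
            cols.append(cloud.normals)
        np.savetxt(path, np.hstack(cols), fmt="%.9g")
        return
    _write_ply(path, cloud.points, normals=cloud.normals, faces=None, binary=binary)


def _read_xyz(path: Path) -> PointCloud:
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) not in (3, 6):
                raise ParseError(f"{path}:{lineno}: expected 3 or 6 columns, got {len(parts)}")
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise ParseError(f"{path}:{lineno}: inconsistent column count")
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise ParseError(f"{path}: no data records")
    arr = np.asarray(rows, dtype=np.float64)
    normals = _renormalize(arr[:, 3:6], path) if arr.shape[1] == 6 else None
    return PointCloud(arr[:, :3], normals)


def _renormalize(normals: np.ndarray, path: Path) -> np.ndarray:
    norms = np.linalg.norm(normals, axis=1)
    bad = np.nonzero(norms < 1e-12)[0]
    if len(bad):
        raise ParseError(f"{path}: zero-norm normal at element {bad[0]}")
    return normals / norms[:, None]


# ---------------------------------------------------------------------------
# mesh I/O


def read_mesh(path: str | Path, format: str | None = None) -> TriangleMesh:
    """Read a triangle mesh from PLY or OBJ, preserving face orientation."""
    path = Path(path)
    fmt = _infer_format(path, format, {"ply", "obj"})
    if fmt == "obj":
        return _read_obj(path)
    verts, normals, faces = _read_ply(path)
    if faces is None:
        raise ParseError(f"{path}: PLY file has no face element")
    return TriangleMesh(verts, faces)


def write_mesh(
    mesh: TriangleMesh, path: str | Path, format: str | None = None, binary: bool = False
) -> None:
    path = Path(path)
    fmt = _infer_format(path, format, {"ply", "obj"})
    if fmt == "obj":
        with open(path, "w") as fh:
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in mesh.faces + 1:  # OBJ is 1-based
                fh.write(f"f {f[0]} {f[1]} {f[2]}\n")
        return
    _write_ply(path, mesh.vertices, normals=None, faces=mesh.faces, binary=binary)


def _read_obj(path: Path) -> TriangleMesh:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise ParseError(f"{path}:{lineno}: vertex needs 3 coordinates")
                verts.append([float(v) for v in parts[1:4]])
            elif tag == "f":
                idx = []
                for token in parts[1:]:
                    head = token.split("/")[0]
                    try:
                        i = int(head)
                    except ValueError:
                        raise ParseError(f"{path}:{lineno}: bad face index {token!r}") from None
                    if i < 0:
                        raise ParseError(f"{path}:{lineno}: negative OBJ indices unsupported")
                    idx.append(i - 1)
                if len(idx) == 3:
                    faces.append(idx)
                elif len(idx) == 4:  # fan split preserving winding
                    faces.append([idx[0], idx[1], idx[2]])
                    faces.append([idx[0], idx[2], idx[3]])
                else:
                    raise ParseError(
                        f"{path}:{lineno}: only triangles and quads supported "
                        f"(face has {len(idx)} vertices)"
                    )
    if not verts:
        raise ParseError(f"{path}: no vertices")
    return TriangleMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64).reshape(-1, 3))


# ---------------------------------------------------------------------------
# PLY reader/writer (ASCII + binary little-endian)

_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _read_ply(path: Path):
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ParseError(f"{path}: not a PLY file")
        fmt = None
        elements: list[tuple[str, int, list]] = []  # (name, count, [props])
        while True:
            line = fh.readline()
            if not line:
                raise ParseError(f"{path}: unexpected EOF in header")
            parts = line.decode("ascii", "replace").split()
            if not parts or parts[0] == "comment":
                continue
            if parts[0] == "format":
                fmt = parts[1]
                if fmt not in ("ascii", "binary_little_endian"):
                    raise ParseError(f"{path}: unsupported PLY format {fmt!r}")
            elif parts[0] == "element":
                elements.append((parts[1], int(parts[2]), []))
            elif parts[0] == "property":
                if not elements:
                    raise ParseError(f"{path}: property before any element")
                if parts[1] == "list":
                    elements[-1][2].append(("list", parts[2], parts[3], parts[4]))
                else:
                    elements[-1][2].append(("scalar", parts[1], parts[2]))
            elif parts[0] == "end_header":
                break
            else:
                raise ParseError(f"{path}: unknown header record {parts[0]!r}")
        if fmt is None:
            raise ParseError(f"{path}: missing format line")
        data = {}
        for name, count, props in elements:
            if fmt == "ascii":
                data[name] = _read_ply_element_ascii(fh, path, name, count, props)
            else:
                data[name] = _read_ply_element_binary(fh, path, name, count, props)
    verts = normals = faces = None
    if "vertex" in data:
        vd = data["vertex"]
        try:
            verts = np.column_stack([vd["x"], vd["y"], vd["z"]]).astype(np.float64)
        except KeyError:
            raise ParseError(f"{path}: vertex element lacks x/y/z") from None
        if all(k in vd for k in ("nx", "ny", "nz")):
            normals = np.column_stack([vd["nx"], vd["ny"], vd["nz"]]).astype(np.float64)
    if "face" in data:
        fl = data["face"].get("__lists__")
        if fl:
            lens = {len(f) for f in fl}
            if lens - {3}:
                raise ParseError(f"{path}: non-triangular PLY faces unsupported")
            faces = np.asarray(fl, dtype=np.int64)
    return verts, normals, faces


def _read_ply_element_ascii(fh, path, name, count, props):
    out: dict = {p[1] if p[0] == "list" else p[2]: [] for p in props}
    lists = []
    for i in range(count):
        line = fh.readline()
        if not line:
            raise ParseError(f"{path}: {name} element truncated at record {i}")
        vals = line.split()
        pos = 0
        for p in props:
            if p[0] == "list":
                n = int(vals[pos]); pos += 1
                lists.append([int(v) for v in vals[pos:pos + n]]); pos += n
            else:
                out[p[2]].append(float(vals[pos])); pos += 1
    res = {k: np.asarray(v) for k, v in out.items() if v}
    if lists:
        res["__lists__"] = lists
    return res


def _read_ply_element_binary(fh, path, name, count, props):
    if all(p[0] == "scalar" for p in props):
        dt = np.dtype([(p[2], "<" + _PLY_TYPES[p[1]]) for p in props])
        raw = fh.read(dt.itemsize * count)
        if len(raw) != dt.itemsize * count:
            raise ParseError(f"{path}: {name} element truncated")
        arr = np.frombuffer(raw, dtype=dt)
        return {p[2]: arr[p[2]].astype(np.float64) for p in props}
    lists = []
    scalars: dict = {}
    for i in range(count):
        for p in props:
            if p[0] == "list":
                cnt_dt = np.dtype("<" + _PLY_TYPES[p[1]])
                val_dt = np.dtype("<" + _PLY_TYPES[p[2]])
                n = int(np.frombuffer(fh.read(cnt_dt.itemsize), dtype=cnt_dt)[0])
                lists.append(
                    np.frombuffer(fh.read(val_dt.itemsize * n), dtype=val_dt).tolist()
                )
            else:
                dt = np.dtype("<" + _PLY_TYPES[p[1]])
                scalars.setdefault(p[2], []).append(
                    float(np.frombuffer(fh.read(dt.itemsize), dtype=dt)[0])
                )
    res = {k: np.asarray(v) for k, v in scalars.items()}
    if lists:
        res["__lists__"] = lists
    return res


def _read_ply_cloud(path: Path) -> PointCloud:
    verts, normals, _faces = _read_ply(path)
    if verts is None:
        raise ParseError(f"{path}: PLY file has no vertex element")
    if normals is not None:
        normals = _renormalize(normals, path)
    return PointCloud(verts, normals)


def _write_ply(path, vertices, normals=None, faces=None, binary=False):
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append(f"element vertex {len(vertices)}")
    header += ["property float x", "property float y", "property float z"]
    if normals is not None:
        header += ["property float nx", "property float ny", "property float nz"]
    if faces is not None:
        header.append(f"element face {len(faces)}")
        header.append("property list uchar int vertex_indices")
    header.append("end_header")
    vdata = vertices if normals is None else np.hstack([vertices, normals])
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(vdata.astype("<f4").tobytes())
            if faces is not None:
                for f in faces:
                    fh.write(struct.pack("<Biii", 3, *map(int, f)))
        else:
            for row in vdata:
                fh.write((" ".join(f"{v:.9g}" for v in row) + "\n").encode("ascii"))
            if faces is not None:
                for f in faces:
                    fh.write(f"3 {f[0]} {f[1]} {f[2]}\n".encode("ascii"))


def _infer_format(path: Path, format: str | None, allowed: set[str]) -> str:
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in allowed:
        raise ValueError(f"unsupported format {fmt!r} (expected one of {sorted(allowed)})")
    return fmt
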