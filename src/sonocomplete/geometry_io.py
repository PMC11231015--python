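"""Mesh and point-cloud containers, file I/O, and labelmap-to-mesh extraction.

All coordinates are world millimeters. NIfTI label volumes are converted to
world space through their affine immediately at load, so every downstream
threshold (e.g. the 5 mm facet tolerance) is metric.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
from skimage import measure

__all__ = [
    "TriangleMesh",
    "PointCloud",
    "LabeledSpine",
    "FormatError",
    "MissingLabelError",
    "DegenerateScaleError",
    "read_mesh",
    "write_mesh",
    "read_pointcloud",
    "write_pointcloud",
    "labelvolume_to_spine",
    "normalize_cloud",
    "denormalize_cloud",
    "point_mesh_distance",
    "farthest_point_indices",
]

LUMBAR_LEVELS = ("L1", "L2", "L3", "L4", "L5")


class FormatError(ValueError):
    """A file did not parse as the expected format."""


class MissingLabelError(KeyError):
    """A requested integer label is absent from a label volume."""


class DegenerateScaleError(ValueError):
    """A point cloud has zero spatial extent and cannot be normalized."""


@dataclass
class TriangleMesh:
    """Triangle surface in world millimeters.

    vertices : (V, 3) float array
    faces    : (F, 3) int array of vertex indices
    vertex_normals : optional (V, 3) unit vectors
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise FormatError(
                f"face index {int(self.faces.max())} out of range for "
                f"{len(self.vertices)} vertices"
            )
        if self.faces.size:
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise FormatError("mesh contains a face with a repeated vertex")
        if self.vertex_normals is not None:
            self.vertex_normals = np.asarray(self.vertex_normals, dtype=np.float64).reshape(-1, 3)
            norms = np.linalg.norm(self.vertex_normals, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise FormatError("vertex normals are not unit length")

    @property
    def triangles(self) -> np.ndarray:
        """(F, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self) -> np.ndarray:
        tri = self.triangles
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        length = np.linalg.norm(n, axis=1, keepdims=True)
        length[length == 0] = 1.0
        return n / length

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def bounds(self) -> np.ndarray:
        """(2, 3) min/max corner."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "TriangleMesh":
        return cls(vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces))


@dataclass
class PointCloud:
    """Point set in world millimeters with optional normals and level labels."""

    points: np.ndarray
    normals: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
            if len(self.normals) != len(self.points):
                raise ValueError("normals cardinality differs from points")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.points):
                raise ValueError("labels cardinality differs from points")

    def __len__(self) -> int:
        return len(self.points)

    def take(self, idx: np.ndarray) -> "PointCloud":
        return PointCloud(
            points=self.points[idx],
            normals=None if self.normals is None else self.normals[idx],
            labels=None if self.labels is None else self.labels[idx],
        )


@dataclass
class LabeledSpine:
    """Cranio-caudally ordered sequence of (level label, mesh), L1 first.

    ``joint_pivots`` is optional provenance set by the deformation module:
    the world position of each intervertebral joint pivot, kept consistent
    with the meshes so a subsequent deformation (e.g. the negated sample)
    bends about the same anatomical points.
    """

    levels: list[tuple[str, TriangleMesh]] = field(default_factory=list)
    joint_pivots: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.levels]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate level labels: {labels}")

    def __len__(self) -> int:
        return len(self.levels)

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.levels]

    @property
    def meshes(self) -> list[TriangleMesh]:
        return [m for _, m in self.levels]

    def centroids(self) -> np.ndarray:
        return np.array([m.centroid() for _, m in self.levels])

    def mesh(self, label: str) -> TriangleMesh:
        for lab, m in self.levels:
            if lab == label:
                return m
        raise KeyError(label)


# ---------------------------------------------------------------------------
# Mesh I/O (PLY / OBJ / STL via trimesh)
# ---------------------------------------------------------------------------

_MESH_FORMATS = {".ply", ".obj", ".stl"}


def read_mesh(path: str | Path) -> TriangleMesh:
    """Read a PLY/OBJ/STL triangle mesh; format inferred from the suffix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in _MESH_FORMATS:
        raise FormatError(f"unsupported mesh format: {path.suffix}")
    try:
        mesh = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:  # trimesh raises various types on malformed input
        raise FormatError(f"{path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0 and len(mesh.vertices) == 0:
        raise FormatError(f"{path}: no triangle geometry found")
    return TriangleMesh.from_trimesh(mesh)


def write_mesh(mesh: TriangleMesh, path: str | Path, *, ascii_ply: bool = False) -> None:
    """Write a mesh; format from suffix (.ply binary by default, .obj, .stl)."""
    path = Path(path)
    if path.suffix.lower() not in _MESH_FORMATS:
        raise FormatError(f"unsupported mesh format: {path.suffix}")
    tm = mesh.to_trimesh()
    if path.suffix.lower() == ".ply" and ascii_ply:
        path.write_bytes(tm.export(file_type="ply", encoding="ascii"))
    else:
        tm.export(str(path))


# ---------------------------------------------------------------------------
# Point-cloud I/O (PLY with per-point labels; XYZ lossy)
# ---------------------------------------------------------------------------


def write_pointcloud(
    pc: PointCloud, path: str | Path, *, binary: bool = True
) -> None:
    """Write a point cloud as PLY (canonical, carries labels) or XYZ (lossy).

    PLY stores labels as an extra per-vertex ``int32 label`` property and
    normals as ``nx ny nz`` when present. XYZ stores coordinates only.
    """
    if len(pc) == 0:
        raise ValueError("cannot write an empty point cloud")
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        np.savetxt(path, pc.points, fmt="%.8f")
        return
    if suffix != ".ply":
        raise FormatError(f"unsupported point-cloud format: {suffix}")

    n = len(pc)
    props = [("x", "float"), ("y", "float"), ("z", "float")]
    columns: list[np.ndarray] = [pc.points[:, i].astype(np.float32) for i in range(3)]
    if pc.normals is not None:
        props += [("nx", "float"), ("ny", "float"), ("nz", "float")]
        columns += [pc.normals[:, i].astype(np.float32) for i in range(3)]
    labels_int = None
    if pc.labels is not None:
        labels_int = _labels_to_int(pc.labels)
        props += [("label", "int")]
        columns += [labels_int.astype(np.int32)]

    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0", f"element vertex {n}"]
    header += [f"property {typ} {name}" for name, typ in props]
    header += ["end_header"]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            rec = np.zeros(
                n,
                dtype=[(name, "<f4" if typ == "float" else "<i4") for name, typ in props],
            )
            for (name, _), col in zip(props, columns):
                rec[name] = col
            fh.write(rec.tobytes())
        else:
            arr = np.column_stack([c.astype(np.float64) for c in columns])
            for row, _ in zip(arr, range(n)):
                parts = []
                for (name, typ), val in zip(props, row):
                    parts.append(str(int(val)) if typ == "int" else f"{val:.8g}")
                fh.write((" ".join(parts) + "\n").encode("ascii"))


def read_pointcloud(path: str | Path) -> PointCloud:
    """Read a PLY or XYZ point cloud written by :func:`write_pointcloud`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        pts = np.loadtxt(path, dtype=np.float64).reshape(-1, 3)
        return PointCloud(points=pts)
    if suffix != ".ply":
        raise FormatError(f"unsupported point-cloud format: {suffix}")
    return _read_ply_cloud(path)


_PLY_TYPES = {
    "float": ("<f4", 4), "float32": ("<f4", 4), "double": ("<f8", 8),
    "float64": ("<f8", 8), "int": ("<i4", 4), "int32": ("<i4", 4),
    "uint": ("<u4", 4), "uint32": ("<u4", 4), "uchar": ("u1", 1),
    "uint8": ("u1", 1), "char": ("i1", 1), "int8": ("i1", 1),
    "short": ("<i2", 2), "ushort": ("<u2", 2),
}


def _read_ply_cloud(path: Path) -> PointCloud:
    raw = path.read_bytes()
    end = raw.find(b"end_header\n")
    if not raw.startswith(b"ply") or end < 0:
        raise FormatError(f"{path}: not a PLY file (missing header at byte 0)")
    header = raw[:end].decode("ascii", errors="replace").splitlines()
    body = raw[end + len(b"end_header\n"):]

    fmt = None
    n_vertex = 0
    props: list[tuple[str, str]] = []
    in_vertex = False
    for lineno, line in enumerate(header):
        tok = line.split()
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
                raise FormatError(f"{path}: list property in vertex element (line {lineno})")
            props.append((tok[2], tok[1]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise FormatError(f"{path}: unsupported PLY format {fmt!r}")
    names = [n for n, _ in props]
    if not {"x", "y", "z"} <= set(names):
        raise FormatError(f"{path}: vertex element lacks x/y/z")

    if fmt == "ascii":
        rows = body.decode("ascii").split()
        arr = np.array(rows, dtype=np.float64).reshape(n_vertex, len(props))
        data = {name: arr[:, i] for i, (name, _) in enumerate(props)}
    else:
        dtype = np.dtype([(n, _PLY_TYPES[t][0]) for n, t in props])
        if len(body) < n_vertex * dtype.itemsize:
            raise FormatError(
                f"{path}: truncated binary body at byte {end + 11 + len(body)}"
            )
        rec = np.frombuffer(body[: n_vertex * dtype.itemsize], dtype=dtype)
        data = {n: rec[n].astype(np.float64) for n in names}

    pts = np.column_stack([data["x"], data["y"], data["z"]])
    normals = None
    if {"nx", "ny", "nz"} <= set(names):
        normals = np.column_stack([data["nx"], data["ny"], data["nz"]])
    labels = None
    if "label" in names:
        labels = _labels_from_int(data["label"].astype(np.int64))
    return PointCloud(points=pts, normals=normals, labels=labels)


def _labels_to_int(labels: np.ndarray) -> np.ndarray:
    """Map level strings like 'L3' to integers; pass integers through."""
    if labels.dtype.kind in "iu":
        return labels.astype(np.int64)
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        s = str(lab)
        out[i] = int(s[1:]) if s.startswith("L") else int(s)
    return out


def _labels_from_int(vals: np.ndarray) -> np.ndarray:
    return np.array([f"L{int(v)}" for v in vals])


# ---------------------------------------------------------------------------
# Label volume → per-vertebra meshes
# ---------------------------------------------------------------------------


def labelvolume_to_spine(
    volume_path: str | Path,
    label_map: dict[str, int],
    *,
    smooth: bool = False,
) -> LabeledSpine:
    """Extract one surface mesh per labeled vertebra from a NIfTI labelmap.

    Iso-surfaces each label's binary mask at 0.5 (marching cubes) and maps
    vertices through the NIfTI affine into world mm. Levels are returned in
    cranio-caudal order of their centroids. ``smooth`` applies one pass of
    Laplacian vertex averaging (off by default so the geometry stays auditable).
    """
    img = nib.load(str(volume_path))
    vol = np.asarray(img.dataobj)
    if not np.issubdtype(vol.dtype, np.integer):
        vol = np.rint(vol).astype(np.int64)
    affine = img.affine
    present = set(np.unique(vol).tolist())

    entries = []
    for level, lab in label_map.items():
        if lab not in present:
            raise MissingLabelError(
                f"label {lab} ({level}) not in volume; found {sorted(present)}"
            )
        mask = (vol == lab).astype(np.float32)
        # pad so surfaces at the volume border still close
        mask = np.pad(mask, 1)
        verts, faces, _, _ = measure.marching_cubes(mask, level=0.5)
        verts = verts - 1.0  # undo pad
        if smooth:
            verts = _laplacian_smooth(verts, faces)
        world = verts @ affine[:3, :3].T + affine[:3, 3]
        entries.append((level, TriangleMesh(vertices=world, faces=faces)))

    # cranio-caudal ordering along the dominant axis of centroid spread
    cents = np.array([m.centroid() for _, m in entries])
    if len(entries) > 1:
        axis = int(np.argmax(cents.max(axis=0) - cents.min(axis=0)))
        order = np.argsort(-cents[:, axis])  # superior (larger coord) first
        entries = [entries[i] for i in order]
    return LabeledSpine(levels=entries)


def _laplacian_smooth(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    neigh_sum = np.zeros_like(verts)
    counts = np.zeros(len(verts))
    for a, b in ((0, 1), (1, 2), (2, 0)):
        np.add.at(neigh_sum, faces[:, a], verts[faces[:, b]])
        np.add.at(neigh_sum, faces[:, b], verts[faces[:, a]])
        np.add.at(counts, faces[:, a], 1)
        np.add.at(counts, faces[:, b], 1)
    counts[counts == 0] = 1
    return 0.5 * verts + 0.5 * neigh_sum / counts[:, None]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_cloud(pc: PointCloud) -> tuple[PointCloud, tuple[np.ndarray, float]]:
    """Center at the centroid and scale so the farthest point has norm 1.

    Returns the normalized cloud and the ``(center, scale)`` transform such
    that ``original = normalized * scale + center``.
    """
    if len(pc) == 0:
        raise ValueError("empty point cloud")
    center = pc.points.mean(axis=0)
    shifted = pc.points - center
    scale = float(np.linalg.norm(shifted, axis=1).max())
    if scale <= 0.0:
        raise DegenerateScaleError("all points identical; scale undefined")
    return (
        PointCloud(points=shifted / scale, normals=pc.normals, labels=pc.labels),
        (center, scale),
    )


def denormalize_cloud(pc: PointCloud, transform: tuple[np.ndarray, float]) -> PointCloud:
    center, scale = transform
    return PointCloud(
        points=pc.points * scale + np.asarray(center),
        normals=pc.normals,
        labels=pc.labels,
    )


# ---------------------------------------------------------------------------
# Geometry helpers shared across modules
# ---------------------------------------------------------------------------


def point_mesh_distance(points: np.ndarray, mesh: TriangleMesh, chunk: int = 256) -> np.ndarray:
    """Unsigned distance from each point to the nearest triangle of ``mesh``."""
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    tri = mesh.triangles
    out = np.empty(len(points))
    for start in range(0, len(points), chunk):
        p = points[start : start + chunk]
        d = _point_triangles_distance(p, tri)
        out[start : start + chunk] = d.min(axis=1)
    return out


def _point_triangles_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """(P, F) distances, Eberly-style closest point on triangle."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    p = points[:, None, :]  # (P, 1, 3)
    ap = p - a[None]
    d1 = np.einsum("fk,pfk->pf", ab, ap)
    d2 = np.einsum("fk,pfk->pf", ac, ap)
    bp = p - b[None]
    d3 = np.einsum("fk,pfk->pf", ab, bp)
    d4 = np.einsum("fk,pfk->pf", ac, bp)
    cp = p - c[None]
    d5 = np.einsum("fk,pfk->pf", ab, cp)
    d6 = np.einsum("fk,pfk->pf", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    denom = np.where(np.abs(denom) < 1e-30, 1e-30, denom)
    v = vb / denom
    w = vc / denom
    closest = a[None] + v[..., None] * ab[None] + w[..., None] * ac[None]

    # vertex regions
    reg_a = (d1 <= 0) & (d2 <= 0)
    reg_b = (d3 >= 0) & (d4 <= d3)
    reg_c = (d6 >= 0) & (d5 <= d6)
    # edge regions
    v_ab = np.where(np.abs(d1 - d3) < 1e-30, 0.0, d1 / np.where(d1 - d3 == 0, 1e-30, d1 - d3))
    reg_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    w_ac = np.where(np.abs(d2 - d6) < 1e-30, 0.0, d2 / np.where(d2 - d6 == 0, 1e-30, d2 - d6))
    reg_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    t_bc = (d4 - d3) / np.where((d4 - d3) + (d5 - d6) == 0, 1e-30, (d4 - d3) + (d5 - d6))
    reg_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)

    pt_ab = a[None] + np.clip(v_ab, 0, 1)[..., None] * ab[None]
    pt_ac = a[None] + np.clip(w_ac, 0, 1)[..., None] * ac[None]
    pt_bc = b[None] + np.clip(t_bc, 0, 1)[..., None] * (c - b)[None]

    closest = np.where(reg_bc[..., None], pt_bc, closest)
    closest = np.where(reg_ac[..., None], pt_ac, closest)
    closest = np.where(reg_ab[..., None], pt_ab, closest)
    closest = np.where(reg_c[..., None], c[None] + 0 * closest, closest)
    closest = np.where(reg_b[..., None], b[None] + 0 * closest, closest)
    closest = np.where(reg_a[..., None], a[None] + 0 * closest, closest)
    return np.linalg.norm(p - closest, axis=2)


def points_inside_mesh(points: np.ndarray, mesh: TriangleMesh, chunk: int = 64) -> np.ndarray:
    """Even-odd containment test for a watertight mesh (boolean per point)."""
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    lo, hi = mesh.bounds()
    inside_box = np.all((points > lo) & (points < hi), axis=1)
    out = np.zeros(len(points), dtype=bool)
    idx = np.flatnonzero(inside_box)
    if len(idx) == 0:
        return out
    tri = mesh.triangles
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    d = np.array([0.577350269, 0.577350269, 0.577350269])  # avoid axis-aligned edge grazing
    for s in range(0, len(idx), chunk):
        o = points[idx[s : s + chunk]]
        h = np.cross(d, e2)
        a = np.einsum("fk,fk->f", e1, h)
        valid = np.abs(a) > 1e-12
        inv_a = np.where(valid, 1.0 / np.where(a == 0, 1.0, a), 0.0)
        svec = o[:, None, :] - v0[None]
        u = inv_a[None] * np.einsum("rfk,fk->rf", svec, h)
        q = np.cross(svec, e1[None])
        v = inv_a[None] * (q @ d)
        t = inv_a[None] * np.einsum("rfk,fk->rf", q, e2)
        hit = valid[None] & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
        out[idx[s : s + chunk]] = hit.sum(axis=1) % 2 == 1
    return out


def farthest_point_indices(points: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Greedy farthest-point sampling; first pick seeded for determinism."""
    points = np.asarray(points)
    n = len(points)
    if k >= n:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    idx = np.empty(k, dtype=np.int64)
    idx[0] = rng.integers(n)
    dist = np.linalg.norm(points - points[idx[0]], axis=1)
    for i in range(1, k):
        idx[i] = int(np.argmax(dist))
        dist = np.minimum(dist, np.linalg.norm(points - points[idx[i]], axis=1))
    return idx
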