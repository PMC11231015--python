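"""Ultrasound-consistent partial views of a spine by incidence-aware ray-casting.

A spinal ultrasound sweep shows only the posterior bone surface: everything
beneath the first bone interface is lost to acoustic shadowing, interfaces
nearly parallel to the beam return no echo (grazing incidence), and scattering
displaces some off-plane echoes, occluding further points. This module
emulates those three effects on surface meshes:

* first-hit-only ray casting from virtual cameras placed posterior to each
  spinous process (shadowing),
* an incidence-angle cut — the angle between the ray and the inward surface
  normal must stay below a threshold (default 90°, the grazing limit),
* a "scatter" pass that duplicates the scene shifted perpendicular to the
  beam and keeps only original-surface hits not occluded by a shifted copy.

The per-vertebra views are then masked by source level and optionally
contaminated with points from adjacent levels (neighboring cloud fusion),
mimicking the imperfect level separation achievable in ultrasound.

Ray–triangle intersection is a vectorized Möller–Trumbore with an AABB
prefilter, chunked to bound memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .geometry_io import (
    LabeledSpine,
    PointCloud,
    TriangleMesh,
    farthest_point_indices,
    normalize_cloud,
)

__all__ = [
    "CameraPose",
    "RayHits",
    "PartialView",
    "OcclusionConfig",
    "EmptyViewError",
    "GeometryError",
    "place_cameras",
    "raycast_visible",
    "apply_scatter",
    "mask_by_vertebra",
    "fuse_neighbors",
    "generate_dataset",
    "cast_first_hit",
]


class EmptyViewError(RuntimeError):
    """Masking produced zero points for a vertebra level."""


class GeometryError(RuntimeError):
    """A mesh lacks the geometric feature an operation requires."""


@dataclass(frozen=True)
class CameraPose:
    """Virtual probe pose: position (mm), unit view direction, unit up."""

    position: np.ndarray
    view_dir: np.ndarray
    up: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=np.float64))
        object.__setattr__(self, "view_dir", np.asarray(self.view_dir, dtype=np.float64))
        object.__setattr__(self, "up", np.asarray(self.up, dtype=np.float64))
        for name in ("view_dir", "up"):
            v = getattr(self, name)
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be unit length")
        if abs(float(self.view_dir @ self.up)) > 1e-6:
            raise ValueError("view_dir and up must be orthogonal")

    @property
    def right(self) -> np.ndarray:
        return np.cross(self.view_dir, self.up)


@dataclass
class RayHits:
    """Struct-of-arrays collection of ray hits on bone surfaces."""

    points: np.ndarray         # (N, 3) mm
    face_normals: np.ndarray   # (N, 3) unit, mesh (outward) orientation
    incidence_deg: np.ndarray  # (N,) angle between ray and inward normal
    source_level: np.ndarray   # (N,) level labels

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.face_normals = np.asarray(self.face_normals, dtype=np.float64).reshape(-1, 3)
        self.incidence_deg = np.asarray(self.incidence_deg, dtype=np.float64).reshape(-1)
        self.source_level = np.asarray(self.source_level).reshape(-1)
        if not (0 <= self.incidence_deg.min(initial=0.0)) or self.incidence_deg.max(initial=0.0) > 180:
            raise ValueError("incidence angles must lie in [0, 180] degrees")

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def empty(cls) -> "RayHits":
        return cls(
            points=np.empty((0, 3)),
            face_normals=np.empty((0, 3)),
            incidence_deg=np.empty(0),
            source_level=np.empty(0, dtype=object),
        )

    @classmethod
    def concatenate(cls, parts: list["RayHits"]) -> "RayHits":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls.empty()
        return cls(
            points=np.vstack([p.points for p in parts]),
            face_normals=np.vstack([p.face_normals for p in parts]),
            incidence_deg=np.concatenate([p.incidence_deg for p in parts]),
            source_level=np.concatenate([p.source_level for p in parts]),
        )


@dataclass
class PartialView:
    """Occluded point cloud of one vertebra plus acquisition provenance."""

    cloud: PointCloud
    level: str
    cameras: list[CameraPose] = field(default_factory=list)
    scatter_applied: bool = False
    fusion_applied: bool = False
    shift_mm: float = 0.0

    def __post_init__(self) -> None:
        if len(self.cloud) == 0:
            raise EmptyViewError(f"empty view for level {self.level}")


# ---------------------------------------------------------------------------
# Ray-casting core
# ---------------------------------------------------------------------------

_EPS = 1e-12


def _ray_aabb_mask(
    origins: np.ndarray, dirs: np.ndarray, bounds: np.ndarray
) -> np.ndarray:
    """Slab test: which rays can intersect the axis-aligned box ``bounds``."""
    inv = np.where(np.abs(dirs) < _EPS, np.inf, 1.0 / np.where(dirs == 0, 1.0, dirs))
    t0 = (bounds[0] - origins) * inv
    t1 = (bounds[1] - origins) * inv
    tmin = np.minimum(t0, t1).max(axis=1)
    tmax = np.maximum(t0, t1).min(axis=1)
    # rays parallel to a slab and outside it: inv=inf gives ±inf handled above
    inside_slab = np.all(
        (np.abs(dirs) >= _EPS)
        | ((origins >= bounds[0] - 1e-9) & (origins <= bounds[1] + 1e-9)),
        axis=1,
    )
    return (tmax >= np.maximum(tmin, 0.0)) & inside_slab


def _moller_trumbore(
    origins: np.ndarray, dirs: np.ndarray, tri: np.ndarray, chunk: int = 128
) -> tuple[np.ndarray, np.ndarray]:
    """First intersection of each ray with a triangle soup.

    Returns (t, face_index); t = inf and face_index = -1 where a ray misses.
    """
    n_rays = len(origins)
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    best_t = np.full(n_rays, np.inf)
    best_f = np.full(n_rays, -1, dtype=np.int64)
    for s in range(0, n_rays, chunk):
        o = origins[s : s + chunk]
        d = dirs[s : s + chunk]
        h = np.cross(d[:, None, :], e2[None])                 # (r, F, 3)
        a = np.einsum("fk,rfk->rf", e1, h)
        valid = np.abs(a) > _EPS
        inv_a = np.where(valid, 1.0 / np.where(a == 0, 1.0, a), 0.0)
        svec = o[:, None, :] - v0[None]
        u = inv_a * np.einsum("rfk,rfk->rf", svec, h)
        q = np.cross(svec, e1[None])
        v = inv_a * np.einsum("rk,rfk->rf", d, q)
        t = inv_a * np.einsum("fk,rfk->rf", e2, q)
        hit = valid & (u >= -1e-10) & (v >= -1e-10) & (u + v <= 1 + 1e-10) & (t > 1e-9)
        t = np.where(hit, t, np.inf)
        f = t.argmin(axis=1)
        tmin = t[np.arange(len(o)), f]
        sel = tmin < best_t[s : s + chunk]
        best_t[s : s + chunk][sel] = tmin[sel]
        best_f[s : s + chunk][sel] = f[sel]
    best_f[~np.isfinite(best_t)] = -1
    return best_t, best_f


def cast_first_hit(
    meshes: list[TriangleMesh],
    origins: np.ndarray,
    dirs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First hit of each ray across a multi-mesh scene.

    Returns (t, mesh_index, face_index); misses get t = inf, indices -1.
    An AABB prefilter skips (ray, mesh) pairs whose box the ray misses.
    """
    origins = np.asarray(origins, dtype=np.float64).reshape(-1, 3)
    dirs = np.asarray(dirs, dtype=np.float64).reshape(-1, 3)
    n = len(origins)
    best_t = np.full(n, np.inf)
    best_mesh = np.full(n, -1, dtype=np.int64)
    best_face = np.full(n, -1, dtype=np.int64)
    for mi, mesh in enumerate(meshes):
        if len(mesh.faces) == 0:
            continue
        cand = _ray_aabb_mask(origins, dirs, mesh.bounds())
        if not cand.any():
            continue
        idx = np.flatnonzero(cand)
        t, f = _moller_trumbore(origins[idx], dirs[idx], mesh.triangles)
        closer = t < best_t[idx]
        upd = idx[closer]
        best_t[upd] = t[closer]
        best_mesh[upd] = mi
        best_face[upd] = f[closer]
    return best_t, best_mesh, best_face


def _fan_directions(camera: CameraPose, grid: tuple[int, int, float]) -> np.ndarray:
    """Rectangular angular fan of n_u × n_v unit ray directions."""
    n_u, n_v, width_deg = grid
    if n_u < 1 or n_v < 1:
        raise ValueError("grid dimensions must be >= 1")
    half = np.deg2rad(width_deg) / 2.0
    au = np.linspace(-half, half, n_u) if n_u > 1 else np.zeros(1)
    av = np.linspace(-half, half, n_v) if n_v > 1 else np.zeros(1)
    tu, tv = np.meshgrid(np.tan(au), np.tan(av), indexing="ij")
    d = (
        camera.view_dir[None, None]
        + tu[..., None] * camera.right[None, None]
        + tv[..., None] * camera.up[None, None]
    ).reshape(-1, 3)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def _hits_from_cast(
    meshes: list[TriangleMesh],
    levels: list[str],
    origins: np.ndarray,
    dirs: np.ndarray,
    t: np.ndarray,
    mesh_idx: np.ndarray,
    face_idx: np.ndarray,
    max_incidence_deg: float,
    keep: np.ndarray | None = None,
) -> RayHits:
    hit = np.isfinite(t)
    if keep is not None:
        hit &= keep
    if not hit.any():
        return RayHits.empty()
    idx = np.flatnonzero(hit)
    pts = origins[idx] + t[idx, None] * dirs[idx]
    normals = np.empty((len(idx), 3))
    lvl = np.empty(len(idx), dtype=object)
    for mi, mesh in enumerate(meshes):
        sel = mesh_idx[idx] == mi
        if not sel.any():
            continue
        fn = mesh.face_normals()
        normals[sel] = fn[face_idx[idx][sel]]
        lvl[sel] = levels[mi]
    cosang = np.einsum("ij,ij->i", dirs[idx], -normals)
    incidence = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ok = incidence < max_incidence_deg
    return RayHits(
        points=pts[ok],
        face_normals=normals[ok],
        incidence_deg=incidence[ok],
        source_level=lvl[ok],
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

POSTERIOR = np.array([0.0, -1.0, 0.0])


def _spinous_apex(mesh: TriangleMesh) -> np.ndarray:
    """Most-posterior vertex (minimum y) — the spinous-process tip."""
    if len(mesh.vertices) == 0:
        raise GeometryError("mesh has no vertices")
    extent = mesh.vertices[:, 1].max() - mesh.vertices[:, 1].min()
    if extent <= 0:
        raise GeometryError("mesh has no posterior extremum (flat in y)")
    return mesh.vertices[np.argmin(mesh.vertices[:, 1])]


def _make_pose(position: np.ndarray, target: np.ndarray) -> CameraPose:
    view = target - position
    view = view / np.linalg.norm(view)
    up = np.array([0.0, 0.0, 1.0])
    up = up - (up @ view) * view
    if np.linalg.norm(up) < 1e-9:
        up = np.array([1.0, 0.0, 0.0]) - (np.array([1.0, 0.0, 0.0]) @ view) * view
    up /= np.linalg.norm(up)
    return CameraPose(position=position, view_dir=view, up=up)


def place_cameras(
    spine: LabeledSpine,
    height_mm: float = 60.0,
    sweep_step_mm: float | None = None,
) -> list[CameraPose]:
    """Pose virtual probes posterior to each spinous-process apex.

    One pose per level at ``height_mm`` behind (−y of) the apex, looking
    anteriorly at it; when ``sweep_step_mm`` is given, additional poses are
    interpolated between consecutive apex poses at that spacing, mimicking a
    transverse sweep along the spine.
    """
    if height_mm <= 0:
        raise ValueError("height_mm must be positive")
    apexes = [_spinous_apex(m) for m in spine.meshes]
    poses = [_make_pose(a + height_mm * POSTERIOR, a) for a in apexes]
    if sweep_step_mm is None or len(apexes) < 2:
        return poses

    out: list[CameraPose] = [poses[0]]
    for a0, a1, p0, p1 in zip(apexes, apexes[1:], poses, poses[1:]):
        span = float(np.linalg.norm(p1.position - p0.position))
        n_extra = max(int(np.floor(span / sweep_step_mm + 1e-9)) - 1, 0)
        for k in range(1, n_extra + 1):
            f = k / (n_extra + 1)
            pos = (1 - f) * p0.position + f * p1.position
            tgt = (1 - f) * a0 + f * a1
            out.append(_make_pose(pos, tgt))
        out.append(p1)
    return out


def raycast_visible(
    meshes: list[TriangleMesh] | LabeledSpine,
    camera: CameraPose,
    grid: tuple[int, int, float] = (64, 64, 60.0),
    max_incidence_deg: float = 90.0,
) -> RayHits:
    """First-hit ray casting with an incidence-angle cut.

    Casts an ``n_u × n_v`` angular fan of ``fan_width_deg`` about the view
    direction; only the closest intersection across all meshes survives
    (acoustic shadowing), and a hit is kept only when the angle between the
    ray and the inward surface normal is below ``max_incidence_deg``.
    """
    if not 0 < max_incidence_deg <= 180:
        raise ValueError("max_incidence_deg must lie in (0, 180]")
    meshes, levels = _as_mesh_list(meshes)
    dirs = _fan_directions(camera, grid)
    origins = np.broadcast_to(camera.position, dirs.shape).copy()
    t, mi, fi = cast_first_hit(meshes, origins, dirs)
    return _hits_from_cast(meshes, levels, origins, dirs, t, mi, fi, max_incidence_deg)


def apply_scatter(
    meshes: list[TriangleMesh] | LabeledSpine,
    camera: CameraPose,
    shift_mm: float = 2.0,
    grid: tuple[int, int, float] = (64, 64, 60.0),
    max_incidence_deg: float = 90.0,
    shift_dir: str = "transverse_both",
) -> RayHits:
    """Ray casting with scattering emulation.

    The whole scene is duplicated, translated by ``shift_mm`` perpendicular
    to the view direction (both +δ and −δ copies for ``transverse_both``,
    one copy for ``transverse_pos``/``transverse_neg``), and rays are cast
    against originals and copies together. A hit on an original mesh is kept
    only when no shifted copy intersects the ray closer to the camera; hits
    on copies are never emitted, so the result is a subset of
    :func:`raycast_visible`.
    """
    if shift_mm < 0:
        raise ValueError("shift_mm must be >= 0")
    meshes, levels = _as_mesh_list(meshes)
    dirs = _fan_directions(camera, grid)
    origins = np.broadcast_to(camera.position, dirs.shape).copy()
    t, mi, fi = cast_first_hit(meshes, origins, dirs)

    if shift_mm > 0:
        offsets = {
            "transverse_both": [camera.right * shift_mm, -camera.right * shift_mm],
            "transverse_pos": [camera.right * shift_mm],
            "transverse_neg": [-camera.right * shift_mm],
        }[shift_dir]
        shifted = [
            TriangleMesh(vertices=m.vertices + off, faces=m.faces)
            for off in offsets
            for m in meshes
        ]
        t_shift, _, _ = cast_first_hit(shifted, origins, dirs)
        keep = t <= t_shift + 1e-9
    else:
        keep = np.ones(len(dirs), dtype=bool)
    return _hits_from_cast(
        meshes, levels, origins, dirs, t, mi, fi, max_incidence_deg, keep=keep
    )


def _as_mesh_list(
    meshes: list[TriangleMesh] | LabeledSpine,
) -> tuple[list[TriangleMesh], list[str]]:
    if isinstance(meshes, LabeledSpine):
        return meshes.meshes, meshes.labels
    return list(meshes), [f"L{i + 1}" for i in range(len(meshes))]


def mask_by_vertebra(
    hits: RayHits,
    level: str,
    cameras: list[CameraPose] | None = None,
    scatter_applied: bool = False,
    shift_mm: float = 0.0,
) -> PartialView:
    """Select the hits belonging to one vertebra level."""
    sel = hits.source_level == level
    if not sel.any():
        raise EmptyViewError(f"no hits for level {level}")
    cloud = PointCloud(
        points=hits.points[sel],
        labels=np.full(int(sel.sum()), level, dtype=object),
    )
    return PartialView(
        cloud=cloud,
        level=level,
        cameras=list(cameras or []),
        scatter_applied=scatter_applied,
        shift_mm=shift_mm,
    )


def fuse_neighbors(
    views: list[PartialView],
    fraction: float = 0.15,
    seed: int = 0,
    band: float = 0.25,
) -> list[PartialView]:
    """Contaminate each view with points of directly adjacent views.

    Each view gains ``round(fraction × |neighbor|)`` points per adjacent
    neighbor, drawn (seeded) from the ``band`` share of the neighbor's
    cranio-caudal extent nearest the shared boundary; if that band is too
    small the remaining points are taken nearest-first. Donated points keep
    their original level labels so ground-truth pairing stays clean.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    donations: list[list[PointCloud]] = [[] for _ in views]

    for i, j in [(k, k + 1) for k in range(len(views) - 1)]:
        zi = views[i].cloud.points[:, 2]
        zj = views[j].cloud.points[:, 2]
        boundary = 0.5 * (zi.min() + zj.max())  # i cranial (+z), j caudal
        for src, dst in ((j, i), (i, j)):
            donor = views[src].cloud
            k = int(round(fraction * len(donor)))
            if k == 0:
                continue
            dist = np.abs(donor.points[:, 2] - boundary)
            extent = donor.points[:, 2].max() - donor.points[:, 2].min()
            in_band = dist <= band * max(extent, 1e-9)
            band_idx = np.flatnonzero(in_band)
            if k <= len(band_idx):
                chosen = rng.choice(band_idx, size=k, replace=False)
            else:
                rest = np.flatnonzero(~in_band)
                rest = rest[np.argsort(dist[rest], kind="stable")]
                chosen = np.concatenate([band_idx, rest[: k - len(band_idx)]])
            donations[dst].append(donor.take(np.sort(chosen)))

    fused = []
    for view, extra in zip(views, donations):
        if not extra:
            fused.append(replace(view, fusion_applied=view.fusion_applied))
            continue
        pts = np.vstack([view.cloud.points] + [e.points for e in extra])
        labs = np.concatenate([view.cloud.labels] + [e.labels for e in extra])
        fused.append(
            replace(
                view,
                cloud=PointCloud(points=pts, labels=labs),
                fusion_applied=True,
            )
        )
    return fused


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OcclusionConfig:
    """Parameters of the synthetic partial-view generator."""

    n_curvatures: int = 1
    posture: str = "sitting"
    joint_limit_deg: float = 10.0
    camera_height_mm: float = 60.0
    sweep_step_mm: float | None = None
    grid: tuple[int, int, float] = (64, 64, 60.0)
    max_incidence_deg: float = 90.0
    scatter: bool = True
    shift_mm: float = 2.0
    fusion: bool = True
    fusion_fraction: float = 0.15
    n_points: int = 2048
    n_gt: int = 2048


def _resample(points: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Fix cardinality: farthest-point subsample or duplicate-pad."""
    if len(points) == n:
        return points
    if len(points) > n:
        idx = farthest_point_indices(points, n, seed=int(rng.integers(2**31)))
        return points[np.sort(idx)]
    pad = rng.choice(len(points), size=n - len(points), replace=True)
    return np.vstack([points, points[pad]])


def generate_dataset(
    spines: list[LabeledSpine],
    config: OcclusionConfig = OcclusionConfig(),
    seed: int = 0,
) -> tuple[list, list[dict]]:
    """Run the full occlusion pipeline over source spines.

    Per spine and curvature sample: deform → place cameras → ray-cast (with
    scattering when enabled) → mask per level → fuse neighbors. Each surviving
    view is paired with a ground-truth cloud of ``n_gt`` points area-sampled
    from the vertebra's complete surface; both clouds are normalized with the
    ground truth's transform. Failures of individual samples are recorded in
    the manifest and skipped; the run fails only if no pair is produced.

    Returns (pairs, manifest): ``pairs`` are
    :class:`~sonocomplete.completion_model.TrainingPair` and the manifest has
    one JSON-serializable record per produced (or skipped) view.
    """
    from .completion_model import TrainingPair
    from .spine_deformation import ConstraintError, deform_spine, sample_curvature

    import trimesh.sample

    if not spines:
        raise ValueError("need at least one source spine")
    rng = np.random.default_rng(seed)
    pairs: list[TrainingPair] = []
    manifest: list[dict] = []

    for si, spine in enumerate(spines):
        for ci in range(config.n_curvatures):
            curv_seed = int(rng.integers(2**31))
            sample = sample_curvature(
                posture=config.posture,
                n_joints=len(spine) - 1,
                joint_limit_deg=config.joint_limit_deg,
                seed=curv_seed,
            )
            if ci == 0:
                # keep one neutral posture per spine
                sample = replace(sample, joint_angles_deg=(0.0,) * (len(spine) - 1))
            try:
                deformed = deform_spine(spine, sample)
            except ConstraintError as exc:
                manifest.append(
                    dict(spine=si, curvature=ci, status="skipped", reason=str(exc))
                )
                continue

            cameras = place_cameras(
                deformed, height_mm=config.camera_height_mm,
                sweep_step_mm=config.sweep_step_mm,
            )
            parts = []
            for cam in cameras:
                if config.scatter:
                    parts.append(
                        apply_scatter(
                            deformed, cam, shift_mm=config.shift_mm,
                            grid=config.grid,
                            max_incidence_deg=config.max_incidence_deg,
                        )
                    )
                else:
                    parts.append(
                        raycast_visible(
                            deformed, cam, grid=config.grid,
                            max_incidence_deg=config.max_incidence_deg,
                        )
                    )
            hits = RayHits.concatenate(parts)

            views = []
            for level in deformed.labels:
                try:
                    views.append(
                        mask_by_vertebra(
                            hits, level, cameras=cameras,
                            scatter_applied=config.scatter,
                            shift_mm=config.shift_mm if config.scatter else 0.0,
                        )
                    )
                except EmptyViewError as exc:
                    manifest.append(
                        dict(spine=si, curvature=ci, level=level,
                             status="skipped", reason=str(exc))
                    )
            if config.fusion and config.fusion_fraction > 0:
                fuse_seed = int(rng.integers(2**31))
                views = fuse_neighbors(views, fraction=config.fusion_fraction, seed=fuse_seed)

            for view in views:
                gt_seed = int(rng.integers(2**31))
                mesh = deformed.mesh(view.level).to_trimesh()
                gt_pts, _ = trimesh.sample.sample_surface(mesh, config.n_gt, seed=gt_seed)
                gt_cloud, transform = normalize_cloud(PointCloud(points=np.asarray(gt_pts)))
                center, scale = transform
                partial_pts = (view.cloud.points - center) / scale
                # fused neighbor points far outside the vertebra's unit
                # sphere would break normalization; keep the near ones only
                in_sphere = np.linalg.norm(partial_pts, axis=1) <= 1.1
                n_clipped = int((~in_sphere).sum())
                partial_pts = partial_pts[in_sphere]
                if len(partial_pts) == 0:
                    manifest.append(
                        dict(spine=si, curvature=ci, level=view.level,
                             status="skipped", reason="no partial points in sphere")
                    )
                    continue
                partial_pts = _resample(partial_pts, config.n_points, rng)
                neutral = all(a == 0.0 for a in sample.joint_angles_deg)
                pairs.append(
                    TrainingPair(
                        partial=PointCloud(points=partial_pts),
                        complete=gt_cloud,
                        transform=transform,
                        level=view.level,
                        spine_id=si,
                        neutral_posture=neutral,
                    )
                )
                manifest.append(
                    dict(
                        spine=si, curvature=ci, level=view.level, status="ok",
                        curvature_seed=curv_seed, gt_seed=gt_seed,
                        joint_angles_deg=list(sample.joint_angles_deg),
                        n_partial_raw=int(len(view.cloud)), n_clipped=n_clipped,
                        scatter=config.scatter, fusion=view.fusion_applied,
                        shift_mm=config.shift_mm if config.scatter else 0.0,
                        max_incidence_deg=config.max_incidence_deg,
                        grid=list(config.grid), seed=seed,
                        center=[float(c) for c in center], scale=float(scale),
                    )
                )
    if not pairs:
        raise RuntimeError("dataset generation produced zero training pairs")
    return pairs, manifest


def write_manifest(manifest: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in manifest:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
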