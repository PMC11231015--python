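"""Pipeline orchestration and mesh post-processing.

Chains the stages fixtures → gen-data → train → complete → evaluate →
reconstruct into a reproducible run directory, and turns completed point
clouds back into meshes: normals are estimated by local plane fits and
oriented toward the acquisition camera, then the oriented cloud is meshed by
a screened-Poisson-style reconstruction — the normal field is splatted onto
a regular grid of side ``2**octree_depth``, the Poisson equation
∇²χ = ∇·V is solved spectrally (DCT, Neumann boundaries), and the indicator
is iso-surfaced at the mean value over the input samples.

Every run serializes its full configuration, seeds and produced manifests, so
an identical config + seed reproduces identical manifests and metric CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import fft as sfft
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from . import metrics as _metrics
from .completion_model import (
    CompletionModel,
    ModelConfig,
    PRESETS,
    TrainingPair,
    complete,
    train,
)
from .fixtures import (
    FACET_NAMES,
    VertebraParams,
    make_spine,
    read_landmarks,
    write_landmarks,
)
from .geometry_io import (
    PointCloud,
    TriangleMesh,
    denormalize_cloud,
    read_pointcloud,
    write_mesh,
    write_pointcloud,
)
from .metrics import CenterlineAnnotation, chamfer, emd, fscore, sp_centerline_cd, summarize
from .us_occlusion import OcclusionConfig, generate_dataset, write_manifest

__all__ = [
    "RunConfig",
    "ReconstructionError",
    "MissingInputError",
    "estimate_normals",
    "poisson_reconstruct",
    "run_pipeline",
    "annotate_centerline",
    "localize_facet",
    "STAGES",
]

logger = logging.getLogger("sonocomplete")

STAGES = ("fixtures", "gen-data", "train", "complete", "evaluate", "reconstruct")


class ReconstructionError(RuntimeError):
    """Poisson reconstruction produced an empty mesh."""


class MissingInputError(FileNotFoundError):
    """A stage's required inputs were not produced by an earlier stage."""


# ---------------------------------------------------------------------------
# Normal estimation and Poisson reconstruction
# ---------------------------------------------------------------------------


def estimate_normals(
    pc: PointCloud,
    k_neighbors: int = 16,
    orientation_reference: np.ndarray | None = None,
) -> PointCloud:
    """Per-point normals from k-NN plane fits, oriented toward a reference.

    The normal is the smallest-variance principal direction of each point's
    neighborhood. Signs are made globally consistent by propagating along a
    breadth-first traversal of the k-NN graph (flip to agree with the
    parent), then each connected component is flipped as a whole so the
    component's point nearest the reference satisfies
    ``normal · (reference − point) ≥ 0``. Default reference: the cloud
    centroid pushed posteriorly (−y) by the bounding diagonal — a stand-in
    for the probe position when provenance is missing.
    """
    pts = pc.points
    if len(pts) <= k_neighbors:
        raise ValueError(f"need more than k_neighbors={k_neighbors} points, got {len(pts)}")
    if orientation_reference is None:
        diag = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
        orientation_reference = pts.mean(axis=0) + np.array([0.0, -diag, 0.0])
    ref = np.asarray(orientation_reference, dtype=np.float64)

    tree = cKDTree(pts)
    _, nn = tree.query(pts, k=k_neighbors + 1)
    neigh = pts[nn]  # (N, k+1, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]  # smallest eigenvalue → plane normal

    # consistent signs: BFS over the kNN graph, flip to agree with parent
    visited = np.zeros(len(pts), dtype=bool)
    order = np.argsort(np.linalg.norm(pts - ref, axis=1))
    from collections import deque

    for start in order:
        if visited[start]:
            continue
        component = [start]
        visited[start] = True
        queue = deque([start])
        while queue:
            i = queue.popleft()
            for j in nn[i, 1:]:
                if not visited[j]:
                    if normals[j] @ normals[i] < 0:
                        normals[j] = -normals[j]
                    visited[j] = True
                    component.append(j)
                    queue.append(j)
        if normals[start] @ (ref - pts[start]) < 0:
            normals[np.array(component)] *= -1.0
    return PointCloud(points=pts, normals=normals, labels=pc.labels)


def poisson_reconstruct(
    pc: PointCloud,
    octree_depth: int = 7,
    smoothing_voxels: float = 1.5,
) -> TriangleMesh:
    """Poisson surface reconstruction of an oriented point cloud.

    Splats the (inward-pointing) normal field onto a ``2**octree_depth``
    regular grid, solves ∇²χ = ∇·V by DCT with Neumann boundaries, and
    extracts the iso-surface at the mean indicator value over the samples.
    The mesh is trimmed to the input bounding box inflated by 10% and the
    largest connected component is returned.
    """
    if pc.normals is None:
        raise ValueError("poisson_reconstruct requires per-point normals")
    if len(pc) < 100:
        raise ValueError(f"need at least 100 points, got {len(pc)}")

    n = int(2**octree_depth)
    lo, hi = pc.points.min(axis=0), pc.points.max(axis=0)
    center = (lo + hi) / 2
    half = (hi - lo) / 2
    box_lo = center - half * 1.1
    box_hi = center + half * 1.1
    pad = 0.15 * (box_hi - box_lo)
    glo, ghi = box_lo - pad, box_hi + pad
    h = (ghi - glo) / (n - 1)

    # trilinear splat of the inward normal field (∇ of the inside-indicator)
    V = np.zeros((3, n, n, n))
    W = np.zeros((n, n, n))
    g = (pc.points - glo) / h
    i0 = np.floor(g).astype(int)
    frac = g - i0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[:, 0] if dx else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dz else 1 - frac[:, 2])
                )
                ix = np.clip(i0[:, 0] + dx, 0, n - 1)
                iy = np.clip(i0[:, 1] + dy, 0, n - 1)
                iz = np.clip(i0[:, 2] + dz, 0, n - 1)
                np.add.at(W, (ix, iy, iz), w)
                for a in range(3):
                    np.add.at(V[a], (ix, iy, iz), -w * pc.normals[:, a])
    for a in range(3):
        V[a] = ndimage.gaussian_filter(V[a], smoothing_voxels)

    div = sum(np.gradient(V[a], h[a], axis=a) for a in range(3))

    # spectral Poisson solve, homogeneous Neumann via DCT-II
    rhs_hat = sfft.dctn(div, type=2, norm="ortho")
    k = [np.arange(n)] * 3
    eig = sum(
        (2.0 * np.cos(np.pi * k[a] / n) - 2.0).reshape(
            [-1 if a == i else 1 for i in range(3)]
        )
        / h[a] ** 2
        for a in range(3)
    )
    eig_flat = eig.copy()
    eig_flat[0, 0, 0] = 1.0
    chi = sfft.idctn(rhs_hat / eig_flat, type=2, norm="ortho")
    chi -= chi.mean()

    iso = float(np.mean(ndimage.map_coordinates(chi, g.T, order=1)))
    lo_val, hi_val = chi.min(), chi.max()
    if not lo_val < iso < hi_val:
        raise ReconstructionError(
            "indicator iso-level outside field range; try a different octree_depth"
        )
    verts, faces, _, _ = measure.marching_cubes(chi, level=iso)
    verts = verts * h + glo

    # trim to the inflated input bounding box
    inside = np.all((verts >= box_lo - 1e-9) & (verts <= box_hi + 1e-9), axis=1)
    keep_face = inside[faces].all(axis=1)
    faces = faces[keep_face]
    if len(faces) == 0:
        raise ReconstructionError("empty mesh after trimming; try a deeper octree_depth")
    used = np.unique(faces)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    mesh = TriangleMesh(vertices=verts[used], faces=remap[faces])

    tm = mesh.to_trimesh()
    parts = tm.split(only_watertight=False)
    if len(parts) > 1:
        biggest = max(parts, key=lambda p: len(p.faces))
        mesh = TriangleMesh.from_trimesh(biggest)
    if len(mesh.faces) == 0:
        raise ReconstructionError("reconstruction yielded an empty mesh")
    return mesh


# ---------------------------------------------------------------------------
# Automatic landmark annotation on clouds (fixture evaluation)
# ---------------------------------------------------------------------------


def annotate_centerline(
    cloud: PointCloud,
    reference_polyline: np.ndarray,
    radius_mm: float = 4.0,
    source: str = "completion",
) -> CenterlineAnnotation | None:
    """Trace the spinous-process centerline through a cloud.

    For each reference polyline vertex, the annotation point is the centroid
    of cloud points within ``radius_mm``; vertices with no support are
    dropped. Returns None when fewer than 2 vertices find support.
    """
    tree = cKDTree(cloud.points)
    pts = []
    for p in np.asarray(reference_polyline, dtype=np.float64):
        idx = tree.query_ball_point(p, radius_mm)
        if not idx:
            continue
        c = cloud.points[idx].mean(axis=0)
        # adjacent reference vertices can share their support set; keep one
        if pts and np.linalg.norm(c - pts[-1]) < 1e-9:
            continue
        pts.append(c)
    if len(pts) < 2:
        return None
    return CenterlineAnnotation(points=np.asarray(pts), source=source)


def _annotation_radius(points: np.ndarray, floor_mm: float = 4.0) -> float:
    """Annotation ball radius adapted to the cloud's sampling density."""
    d = cKDTree(points).query(points, k=2)[0][:, 1]
    d = d[d > 0]
    spacing = float(np.median(d)) if len(d) else floor_mm
    return max(floor_mm, 3.0 * spacing)


def localize_facet(
    cloud: PointCloud, gt_center: np.ndarray, radius_mm: float = 6.0, min_points: int = 5
) -> np.ndarray | None:
    """Estimate a facet-joint center as the centroid of nearby cloud points."""
    tree = cKDTree(cloud.points)
    idx = tree.query_ball_point(np.asarray(gt_center, dtype=np.float64), radius_mm)
    if len(idx) < min_points:
        return None
    return cloud.points[idx].mean(axis=0)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Structured configuration of a full pipeline run."""

    out_dir: str = "runs/run0"
    seed: int = 0
    log_level: str = "INFO"
    # fixtures
    n_spines: int = 3
    n_levels: int = 5
    lordosis_deg: float = 15.0
    gap_mm: float = 4.0
    vertebra_resolution: float = 2.0
    jitter_mm: float = 0.25
    # occlusion / data generation
    occlusion: OcclusionConfig = field(default_factory=OcclusionConfig)
    # model
    preset: str = "smoke"
    epochs: int | None = None
    batch_size: int | None = None
    learning_rate: float | None = None
    # evaluation / post-processing
    fscore_threshold: float | None = None
    facet_tolerance_mm: float = 5.0
    poisson_depth: int = 6

    def model_config(self) -> ModelConfig:
        cfg = PRESETS[self.preset]
        # cloud cardinalities follow the generated data
        over = {
            "seed": self.seed,
            "n_in": self.occlusion.n_points,
            "n_out": self.occlusion.n_gt,
            "n_coarse": max(self.occlusion.n_gt // 2, 8),
        }
        if self.epochs is not None:
            over["epochs"] = self.epochs
        if self.batch_size is not None:
            over["batch_size"] = self.batch_size
        if self.learning_rate is not None:
            over["learning_rate"] = self.learning_rate
        return dataclasses.replace(cfg, **over)

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        occ = d.pop("occlusion", {})
        if isinstance(occ.get("grid"), list):
            occ["grid"] = tuple(occ["grid"])
        return cls(occlusion=OcclusionConfig(**occ), **d)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _spine_dir(run: Path, si: int) -> Path:
    return run / "fixtures" / f"spine{si:02d}"


def _stage_fixtures(cfg: RunConfig, run: Path) -> None:
    rng = np.random.default_rng(cfg.seed)
    for si in range(cfg.n_spines):
        params = VertebraParams(
            resolution=cfg.vertebra_resolution,
            jitter_mm=cfg.jitter_mm,
            seed=int(rng.integers(2**31)),
        )
        spine, landmarks = make_spine(
            n_levels=cfg.n_levels, params=params,
            lordosis_deg=cfg.lordosis_deg, gap_mm=cfg.gap_mm,
        )
        d = _spine_dir(run, si)
        d.mkdir(parents=True, exist_ok=True)
        for label, mesh in spine.levels:
            write_mesh(mesh, d / f"{label}.ply")
        write_landmarks(landmarks, d / "landmarks.tsv")
    logger.info("fixtures: wrote %d spines", cfg.n_spines)


def _load_spines(cfg: RunConfig, run: Path):
    from .geometry_io import LabeledSpine, read_mesh

    spines = []
    for si in range(cfg.n_spines):
        d = _spine_dir(run, si)
        if not d.exists():
            raise MissingInputError(f"stage gen-data: missing fixtures at {d}")
        levels = [
            (f"L{i + 1}", read_mesh(d / f"L{i + 1}.ply")) for i in range(cfg.n_levels)
        ]
        spines.append(LabeledSpine(levels=levels))
    return spines


def _stage_gendata(cfg: RunConfig, run: Path) -> None:
    spines = _load_spines(cfg, run)
    pairs, manifest = generate_dataset(spines, cfg.occlusion, seed=cfg.seed)
    d = run / "clouds"
    d.mkdir(parents=True, exist_ok=True)
    index = []
    for i, pair in enumerate(pairs):
        write_pointcloud(pair.partial, d / f"pair{i:04d}_partial.ply")
        write_pointcloud(pair.complete, d / f"pair{i:04d}_complete.ply")
        index.append(
            dict(
                pair=i, level=pair.level, spine=pair.spine_id,
                neutral=bool(pair.neutral_posture),
                center=[float(c) for c in pair.transform[0]],
                scale=float(pair.transform[1]),
            )
        )
    write_manifest(manifest, run / "manifest.jsonl")
    with open(d / "index.json", "w") as fh:
        json.dump(index, fh, sort_keys=True)
    logger.info("gen-data: %d training pairs", len(pairs))


def _load_pairs(run: Path) -> list[TrainingPair]:
    d = run / "clouds"
    idx_path = d / "index.json"
    if not idx_path.exists():
        raise MissingInputError(f"missing generated data at {d}")
    with open(idx_path) as fh:
        index = json.load(fh)
    pairs = []
    for rec in index:
        i = rec["pair"]
        pairs.append(
            TrainingPair(
                partial=read_pointcloud(d / f"pair{i:04d}_partial.ply"),
                complete=read_pointcloud(d / f"pair{i:04d}_complete.ply"),
                transform=(np.array(rec["center"]), rec["scale"]),
                level=rec["level"],
                spine_id=rec["spine"],
                neutral_posture=rec.get("neutral", True),
            )
        )
    return pairs


def _stage_train(cfg: RunConfig, run: Path) -> None:
    pairs = _load_pairs(run)
    mcfg = cfg.model_config()
    model, history = train(pairs, mcfg)
    ck = run / "checkpoints"
    ck.mkdir(parents=True, exist_ok=True)
    model.save(ck / "model.npz")
    with open(ck / "history.json", "w") as fh:
        json.dump(history, fh, sort_keys=True)
    logger.info("train: best val loss %.4f", history["best_val"])


def _stage_complete(cfg: RunConfig, run: Path) -> None:
    ck = run / "checkpoints" / "model.npz"
    if not ck.exists():
        raise MissingInputError(f"stage complete: missing checkpoint {ck}")
    model = CompletionModel.load(ck)
    pairs = _load_pairs(run)
    with open(run / "checkpoints" / "history.json") as fh:
        split = json.load(fh)["split"]
    test_idx = split["test"] or split["val"]
    d = run / "clouds" / "completions"
    d.mkdir(parents=True, exist_ok=True)
    recs = []
    for i in test_idx:
        pair = pairs[i]
        partial_mm = denormalize_cloud(pair.partial, pair.transform)
        result = complete(partial_mm, model)
        write_pointcloud(result.fine, d / f"pair{i:04d}_fine.ply")
        write_pointcloud(result.coarse, d / f"pair{i:04d}_coarse.ply")
        recs.append(dict(pair=i, level=pair.level, spine=pair.spine_id))
    with open(d / "index.json", "w") as fh:
        json.dump(recs, fh, sort_keys=True)
    logger.info("complete: %d test completions", len(recs))


def _stage_evaluate(cfg: RunConfig, run: Path) -> None:
    d = run / "clouds" / "completions"
    if not (d / "index.json").exists():
        raise MissingInputError(f"stage evaluate: missing completions at {d}")
    pairs = _load_pairs(run)
    with open(d / "index.json") as fh:
        recs = json.load(fh)

    rows = []
    for rec in recs:
        i = rec["pair"]
        pair = pairs[i]
        fine_mm = read_pointcloud(d / f"pair{i:04d}_fine.ply")
        center, scale = pair.transform
        fine_n = (fine_mm.points - center) / scale
        gt_n = pair.complete.points
        prec, rec_, f1 = fscore(fine_n, gt_n, cfg.fscore_threshold)
        row = dict(
            id=f"pair{i:04d}", level=pair.level,
            cd_scaled=chamfer(fine_n, gt_n),
            emd=emd(fine_n, gt_n),
            precision=prec, recall=rec_, f1=f1,
        )
        # anatomy metrics against the fixture landmark table when present;
        # the table describes the neutral posture only
        lm_path = _spine_dir(run, rec["spine"]) / "landmarks.tsv"
        if lm_path.exists() and pair.neutral_posture:
            lms = read_landmarks(lm_path)
            lvl = lms[lms.level == pair.level]
            sp = lvl[lvl.landmark.str.startswith("spinous")][["x", "y", "z"]].to_numpy()
            partial_mm = denormalize_cloud(pair.partial, pair.transform)
            ann_in = annotate_centerline(
                partial_mm, sp, radius_mm=_annotation_radius(partial_mm.points),
                source="input",
            )
            ann_out = annotate_centerline(
                fine_mm, sp, radius_mm=_annotation_radius(fine_mm.points),
                source="completion",
            )
            if ann_in is not None and ann_out is not None:
                row["sp_cd"] = sp_centerline_cd(ann_out, ann_in, scale=1.0)
            for side, name in (("left", "articular_sup_left"), ("right", "articular_sup_right")):
                gt_c = lvl[lvl.landmark == name][["x", "y", "z"]].to_numpy()[0]
                found = localize_facet(fine_mm, gt_c)
                if found is not None:
                    row[f"facet_{side}_mm"] = float(np.linalg.norm(found - gt_c))
        rows.append(row)

    report = summarize(rows, facet_tolerance_mm=cfg.facet_tolerance_mm)
    report.to_csv(run / "report.csv", index=False, float_format="%.6f")
    logger.info("evaluate: %d rows -> report.csv", len(rows))


def _stage_reconstruct(cfg: RunConfig, run: Path) -> None:
    d = run / "clouds" / "completions"
    if not (d / "index.json").exists():
        raise MissingInputError(f"stage reconstruct: missing completions at {d}")
    with open(d / "index.json") as fh:
        recs = json.load(fh)
    out = run / "meshes"
    out.mkdir(parents=True, exist_ok=True)
    for rec in recs:
        i = rec["pair"]
        cloud = read_pointcloud(d / f"pair{i:04d}_fine.ply")
        oriented = estimate_normals(cloud)
        mesh = poisson_reconstruct(oriented, octree_depth=cfg.poisson_depth)
        write_mesh(mesh, out / f"pair{i:04d}.ply")
    logger.info("reconstruct: %d meshes", len(recs))


_STAGE_FN = {
    "fixtures": _stage_fixtures,
    "gen-data": _stage_gendata,
    "train": _stage_train,
    "complete": _stage_complete,
    "evaluate": _stage_evaluate,
    "reconstruct": _stage_reconstruct,
}


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Execute the requested stages in canonical order into the run directory.

    Persists the configuration and a library-version stamp; a failing stage
    halts the run with the stage named, keeping partial outputs.
    """
    stages = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = (set(stages or [])) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    run = Path(config.out_dir)
    run.mkdir(parents=True, exist_ok=True)
    (run / "config.yaml").write_text(config.to_yaml())

    import scipy
    import skimage
    import trimesh as _trimesh

    stamp = {
        "numpy": np.__version__, "scipy": scipy.__version__,
        "skimage": skimage.__version__, "trimesh": _trimesh.__version__,
        "pandas": pd.__version__,
    }
    (run / "versions.json").write_text(json.dumps(stamp, sort_keys=True))

    handler = logging.FileHandler(run / "log.txt")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        for stage in stages:
            logger.info("stage %s: start", stage)
            try:
                _STAGE_FN[stage](config, run)
            except MissingInputError:
                logger.exception("stage %s: missing inputs", stage)
                raise
            except Exception as exc:
                logger.exception("stage %s: failed", stage)
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return run
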