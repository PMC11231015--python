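"""Incidence-aware ray casting, scattering, masking and fusion.

The ray-casting oracle here is deliberately independent of the package's
Möller–Trumbore implementation: it intersects each ray with every triangle's
plane and checks barycentric coordinates via a least-squares solve, one ray
and one face at a time.
"""

import numpy as np
import pytest

from sonocomplete.geometry_io import PointCloud, TriangleMesh
from sonocomplete.us_occlusion import (
    CameraPose,
    EmptyViewError,
    OcclusionConfig,
    PartialView,
    RayHits,
    apply_scatter,
    cast_first_hit,
    fuse_neighbors,
    generate_dataset,
    mask_by_vertebra,
    place_cameras,
    raycast_visible,
    _fan_directions,
)


# ---------------------------------------------------------------------------
# Independent oracle
# ---------------------------------------------------------------------------


def oracle_first_hit(meshes, origins, dirs):
    """Exhaustive per-ray, per-face first-intersection oracle."""
    n = len(origins)
    best_t = np.full(n, np.inf)
    best_mesh = np.full(n, -1)
    best_face = np.full(n, -1)
    for r in range(n):
        o, d = origins[r], dirs[r]
        for mi, mesh in enumerate(meshes):
            for fi, face in enumerate(mesh.faces):
                a, b, c = mesh.vertices[face]
                normal = np.cross(b - a, c - a)
                denom = normal @ d
                if abs(denom) < 1e-12:
                    continue
                t = (normal @ (a - o)) / denom
                if t <= 1e-9 or t >= best_t[r]:
                    continue
                p = o + t * d
                # barycentric via least squares on the triangle's edge basis
                M = np.column_stack([b - a, c - a])
                uv, *_ = np.linalg.lstsq(M, p - a, rcond=None)
                u, v = uv
                if u >= -1e-9 and v >= -1e-9 and u + v <= 1 + 1e-9:
                    best_t[r] = t
                    best_mesh[r] = mi
                    best_face[r] = fi
    return best_t, best_mesh, best_face


def _plane_mesh(z=0.0, size=100.0, normal_up=True):
    v = np.array(
        [[-size, -size, z], [size, -size, z], [size, size, z], [-size, size, z]]
    )
    f = np.array([[0, 1, 2], [0, 2, 3]]) if normal_up else np.array([[0, 2, 1], [0, 3, 2]])
    return TriangleMesh(vertices=v, faces=f)


def _box(center, extents):
    import trimesh

    b = trimesh.creation.box(extents=extents)
    return TriangleMesh(vertices=np.asarray(b.vertices) + np.asarray(center), faces=np.asarray(b.faces))


def _sphere(center, radius, subdivisions=1):
    import trimesh

    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(vertices=np.asarray(s.vertices) + np.asarray(center), faces=np.asarray(s.faces))


DOWN_CAM = CameraPose(position=[0, 0, 50.0], view_dir=[0, 0, -1.0], up=[0, 1.0, 0])


# ---------------------------------------------------------------------------
# Cameras
# ---------------------------------------------------------------------------


class TestPlaceCameras:
    def test_straight_spine_parallel_views(self, straight_spine):
        sp, _ = straight_spine
        poses = place_cameras(sp, height_mm=60.0)
        dirs = np.array([p.view_dir for p in poses])
        assert np.abs(dirs - dirs[0]).max() < 1e-3

    def test_height_scales_apex_distance(self, spine):
        sp, _ = spine
        near = place_cameras(sp, height_mm=40.0)
        far = place_cameras(sp, height_mm=80.0)
        apexes = [m.vertices[np.argmin(m.vertices[:, 1])] for m in sp.meshes]
        for a, pn, pf in zip(apexes, near, far):
            dn = np.linalg.norm(pn.position - a)
            df = np.linalg.norm(pf.position - a)
            assert df == pytest.approx(2 * dn, rel=1e-9)

    def test_sweep_poses_cover_each_apex(self, spine):
        sp, _ = spine
        apexes = np.array([m.vertices[np.argmin(m.vertices[:, 1])] for m in sp.meshes])
        pitch = float(np.mean(np.abs(np.diff(apexes[:, 2]))))
        poses = place_cameras(sp, height_mm=60.0, sweep_step_mm=pitch)
        assert len(poses) >= 5
        positions = np.array([p.position for p in poses])
        nearest = np.argmin(
            np.linalg.norm(positions[:, None, :] - apexes[None], axis=2), axis=1
        )
        assert set(nearest) == set(range(5))

    def test_invalid_height(self, spine):
        with pytest.raises(ValueError):
            place_cameras(spine[0], height_mm=0.0)


# ---------------------------------------------------------------------------
# Ray casting
# ---------------------------------------------------------------------------


class TestRaycast:
    def test_normal_incidence_plane_all_kept(self):
        plane = _plane_mesh(z=0.0)
        hits = raycast_visible([plane], DOWN_CAM, grid=(8, 8, 20.0), max_incidence_deg=90.0)
        assert len(hits) == 64
        assert hits.incidence_deg.max() < 15.0
        center = raycast_visible([plane], DOWN_CAM, grid=(1, 1, 0.0))
        assert center.incidence_deg[0] == pytest.approx(0.0, abs=1e-6)

    def test_grazing_plane_no_hits(self):
        # plane containing the view direction: every hit would be at 90°
        v = np.array([[0, -100, -100], [0, 100, -100], [0, 100, 100], [0, -100, 100.0]])
        plane = TriangleMesh(vertices=v, faces=[[0, 1, 2], [0, 2, 3]])
        cam = CameraPose(position=[0, 0, 50.0], view_dir=[0, 0, -1.0], up=[0, 1.0, 0])
        hits = raycast_visible([plane], cam, grid=(6, 6, 10.0), max_incidence_deg=90.0)
        assert len(hits) == 0

    def test_matches_oracle_on_sphere(self):
        sphere = _sphere([0, 0, 0.0], 10.0)
        dirs = _fan_directions(DOWN_CAM, (12, 12, 40.0))
        origins = np.broadcast_to(DOWN_CAM.position, dirs.shape)
        t, mi, fi = cast_first_hit([sphere], origins, dirs)
        t0, mi0, fi0 = oracle_first_hit([sphere], origins, dirs)
        assert np.array_equal(np.isfinite(t), np.isfinite(t0))
        ok = np.isfinite(t)
        assert np.abs(t[ok] - t0[ok]).max() < 1e-9
        assert np.array_equal(fi[ok], fi0[ok])

    def test_shadowing_box_behind_box(self):
        front = _box([0, 0, 10.0], [40, 40, 4.0])
        hidden = _box([0, 0, -10.0], [10, 10, 4.0])
        hits = raycast_visible([front, hidden], DOWN_CAM, grid=(16, 16, 30.0))
        assert not np.any(hits.source_level == "L2")  # second mesh fully shadowed

    def test_incidence_threshold_monotone(self):
        sphere = _sphere([0, 0, 0.0], 10.0, subdivisions=2)
        sizes = []
        sets = []
        for thr in (30.0, 60.0, 90.0):
            hits = raycast_visible([sphere], DOWN_CAM, grid=(16, 16, 40.0), max_incidence_deg=thr)
            sizes.append(len(hits))
            sets.append({tuple(np.round(p, 9)) for p in hits.points})
        assert sizes[0] <= sizes[1] <= sizes[2]
        assert sets[0] <= sets[1] <= sets[2]

    def test_adding_mesh_never_adds_points(self):
        sphere = _sphere([0, 0, 0.0], 10.0)
        blocker = _box([5, 0, 20.0], [10, 10, 2.0])
        alone = raycast_visible([sphere], DOWN_CAM, grid=(16, 16, 40.0))
        both = raycast_visible([sphere, blocker], DOWN_CAM, grid=(16, 16, 40.0))
        n_sphere_alone = int((alone.source_level == "L1").sum())
        n_sphere_both = int((both.source_level == "L1").sum())
        assert n_sphere_both <= n_sphere_alone


class TestScatter:
    def test_zero_shift_identity(self):
        sphere = _sphere([0, 0, 0.0], 10.0)
        base = raycast_visible([sphere], DOWN_CAM, grid=(12, 12, 40.0))
        scat = apply_scatter([sphere], DOWN_CAM, shift_mm=0.0, grid=(12, 12, 40.0))
        assert np.array_equal(base.points, scat.points)

    def test_monotone_and_subset(self):
        sphere = _sphere([0, 0, 0.0], 10.0, subdivisions=2)
        base = raycast_visible([sphere], DOWN_CAM, grid=(16, 16, 40.0))
        baseset = {tuple(np.round(p, 9)) for p in base.points}
        prev = len(base)
        for shift in (1.0, 3.0):
            scat = apply_scatter([sphere], DOWN_CAM, shift_mm=shift, grid=(16, 16, 40.0))
            assert len(scat) <= prev or len(scat) <= len(base)
            assert all(tuple(np.round(p, 9)) in baseset for p in scat.points)

    def test_matches_two_mesh_oracle(self):
        box = _box([0, 0, 0.0], [20, 20, 10.0])
        shift = 10.0  # half the box width
        cam = DOWN_CAM
        dirs = _fan_directions(cam, (10, 10, 50.0))
        origins = np.broadcast_to(cam.position, dirs.shape)
        scat = apply_scatter([box], cam, shift_mm=shift, grid=(10, 10, 50.0),
                             max_incidence_deg=180.0, shift_dir="transverse_pos")
        shifted = TriangleMesh(vertices=box.vertices + cam.right * shift, faces=box.faces)
        t_orig, _, _ = oracle_first_hit([box], origins, dirs)
        t_shift, _, _ = oracle_first_hit([shifted], origins, dirs)
        keep = np.isfinite(t_orig) & (t_orig <= t_shift + 1e-9)
        expected = origins[keep] + t_orig[keep, None] * dirs[keep]
        got = np.round(scat.points, 9)
        expected = np.round(expected, 9)
        got = got[np.lexsort(got.T)]
        expected = expected[np.lexsort(expected.T)]
        assert got.shape == expected.shape
        assert np.abs(got - expected).max() < 1e-8


# ---------------------------------------------------------------------------
# Masking and fusion
# ---------------------------------------------------------------------------


def _toy_hits():
    pts = np.array([[0, 0, 10.0], [0, 0, 9.0], [0, 0, -9.0], [0, 0, -10.0]])
    return RayHits(
        points=pts,
        face_normals=np.tile([0, 0, 1.0], (4, 1)),
        incidence_deg=np.zeros(4),
        source_level=np.array(["L1", "L1", "L2", "L2"], dtype=object),
    )


class TestMaskFuse:
    def test_mask_partition_and_conservation(self):
        hits = _toy_hits()
        v1 = mask_by_vertebra(hits, "L1")
        v2 = mask_by_vertebra(hits, "L2")
        assert len(v1.cloud) + len(v2.cloud) == len(hits)
        assert set(v1.cloud.labels) == {"L1"} and set(v2.cloud.labels) == {"L2"}
        with pytest.raises(EmptyViewError):
            mask_by_vertebra(hits, "L5")

    def test_fuse_zero_fraction_unchanged(self):
        hits = _toy_hits()
        views = [mask_by_vertebra(hits, lev) for lev in ("L1", "L2")]
        fused = fuse_neighbors(views, fraction=0.0, seed=1)
        for v, f in zip(views, fused):
            assert np.array_equal(v.cloud.points, f.cloud.points)
            assert not f.fusion_applied

    def test_fuse_full_fraction_union(self):
        hits = _toy_hits()
        views = [mask_by_vertebra(hits, lev) for lev in ("L1", "L2")]
        fused = fuse_neighbors(views, fraction=1.0, seed=1)
        for f in fused:
            assert len(f.cloud) == 4
            assert set(f.cloud.labels) == {"L1", "L2"}  # labels preserved

    def test_fuse_count_and_reproducibility(self, rng):
        pts1 = np.column_stack([rng.normal(size=(40, 2)), rng.uniform(5, 15, 40)])
        pts2 = np.column_stack([rng.normal(size=(30, 2)), rng.uniform(-15, -5, 30)])
        views = [
            PartialView(cloud=PointCloud(points=pts1, labels=np.array(["L1"] * 40)), level="L1"),
            PartialView(cloud=PointCloud(points=pts2, labels=np.array(["L2"] * 30)), level="L2"),
        ]
        a = fuse_neighbors(views, fraction=0.2, seed=7)
        b = fuse_neighbors(views, fraction=0.2, seed=7)
        assert len(a[0].cloud) == 40 + round(0.2 * 30)
        assert len(a[1].cloud) == 30 + round(0.2 * 40)
        for va, vb in zip(a, b):
            assert np.array_equal(va.cloud.points, vb.cloud.points)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

GEN_CFG = OcclusionConfig(grid=(24, 24, 60.0), n_points=128, n_gt=128)


class TestGenerateDataset:
    def test_one_spine_one_curvature_five_pairs(self, spine):
        sp, _ = spine
        pairs, manifest = generate_dataset([sp], GEN_CFG, seed=1)
        assert len(pairs) == 5
        assert sorted(p.level for p in pairs) == ["L1", "L2", "L3", "L4", "L5"]
        assert all(m["status"] == "ok" for m in manifest)

    def test_partial_on_gt_surface_without_fusion(self, spine):
        import dataclasses

        from sonocomplete.geometry_io import point_mesh_distance

        sp, _ = spine
        cfg = dataclasses.replace(GEN_CFG, fusion=False)
        pairs, _ = generate_dataset([sp], cfg, seed=1)
        for pair in pairs:
            center, scale = pair.transform
            mm = pair.partial.points * scale + center
            assert point_mesh_distance(mm, sp.mesh(pair.level)).max() < 1.0

    def test_replay_reproduces_pairs(self, spine):
        sp, _ = spine
        a, ma = generate_dataset([sp], GEN_CFG, seed=4)
        b, mb = generate_dataset([sp], GEN_CFG, seed=4)
        assert ma == mb
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.partial.points, pb.partial.points)
            assert np.array_equal(pa.complete.points, pb.complete.points)

    def test_visibility_below_half_of_surface(self, spine):
        """Ultrasound shows only the posterior surface: the partial view must
        cover well under half of the complete vertebra surface."""
        import trimesh.sample
        from scipy.spatial import cKDTree

        sp, _ = spine
        pairs, _ = generate_dataset([sp], GEN_CFG, seed=2)
        for pair in pairs[:3]:
            center, scale = pair.transform
            mm = pair.partial.points * scale + center
            gt, _ = trimesh.sample.sample_surface(
                sp.mesh(pair.level).to_trimesh(), 2000, seed=0
            )
            covered = (cKDTree(mm).query(np.asarray(gt))[0] < 2.0).mean()
            assert covered < 0.5
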