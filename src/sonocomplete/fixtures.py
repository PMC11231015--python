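"""Procedural lumbar-vertebra-like meshes and five-level spines.

The generator exists so the occlusion simulator, completion network and
metrics can be exercised without any external CT dataset. Vertebrae are
stylized, not anatomically exact: what matters is the topological layout an
ultrasound sweep exploits — an anterior body hidden beneath a posterior arch
carrying a spinous process, transverse processes and articular prominences.

Each vertebra is the implicit union (pointwise min) of analytic signed
distance primitives sampled on a grid that is mirror-symmetric about the
sagittal plane, then iso-surfaced at zero with marching cubes. This makes
the mesh connected, watertight, exactly deterministic under a fixed seed and
sagittally symmetric up to floating-point error before jitter.

Axes convention: +x right, +y anterior (−y posterior), +z cranial.
The coordinate origin of a single vertebra is the center of its spinal canal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import measure

from .geometry_io import LabeledSpine, TriangleMesh

__all__ = [
    "VertebraParams",
    "PlacementError",
    "make_vertebra",
    "make_vertebra_with_landmarks",
    "make_spine",
    "write_landmarks",
    "read_landmarks",
]

LANDMARK_COLUMNS = ["level", "landmark", "x", "y", "z"]

FACET_NAMES = (
    "articular_sup_left",
    "articular_sup_right",
    "articular_inf_left",
    "articular_inf_right",
)


class PlacementError(RuntimeError):
    """Vertebra placement produced overlapping bodies."""


@dataclass(frozen=True)
class VertebraParams:
    """Shape parameters of one synthetic vertebra (all lengths in mm)."""

    body_radii: tuple[float, float, float] = (17.0, 13.0, 11.0)
    canal_radius: float = 8.0
    arch_radius: float = 4.0
    spinous_length: float = 28.0
    spinous_caudal_angle: float = 30.0
    spinous_radius: float = 5.0
    transverse_length: float = 22.0
    transverse_radius: float = 3.5
    articular_offset: float = 11.0
    articular_radius: float = 4.5
    articular_height: float = 9.0
    level_scale: float = 1.0
    jitter_mm: float = 0.0
    resolution: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        lengths = (
            *self.body_radii, self.canal_radius, self.arch_radius,
            self.spinous_length, self.spinous_radius, self.transverse_length,
            self.transverse_radius, self.articular_offset,
            self.articular_radius, self.articular_height, self.resolution,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all lengths must be positive")
        if self.canal_radius >= min(self.body_radii):
            raise ValueError("canal_radius must be smaller than every body semi-axis")
        if not 0.8 <= self.level_scale <= 1.3:
            raise ValueError("level_scale must lie in [0.8, 1.3]")
        if self.jitter_mm < 0:
            raise ValueError("jitter_mm must be non-negative")


# --- signed distance primitives -------------------------------------------


def _sd_ellipsoid(p: np.ndarray, center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    # Bound-preserving approximation: exact sign, near-metric outside.
    q = (p - center) / radii
    k0 = np.linalg.norm(q, axis=-1)
    k1 = np.linalg.norm(q / radii, axis=-1)
    k1 = np.where(k1 == 0, 1e-12, k1)
    return k0 * (k0 - 1.0) / k1


def _sd_torus(p: np.ndarray, center: np.ndarray, ring_r: float, tube_r: float) -> np.ndarray:
    # Ring lies in the x–y plane (wraps the canal about the z axis).
    q = p - center
    ring = np.sqrt(q[..., 0] ** 2 + q[..., 1] ** 2) - ring_r
    return np.sqrt(ring**2 + q[..., 2] ** 2) - tube_r


def _sd_capsule(
    p: np.ndarray, a: np.ndarray, b: np.ndarray, r_a: float, r_b: float
) -> np.ndarray:
    """Rounded cone: distance to segment ab minus a linearly tapered radius."""
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    radius = r_a + (r_b - r_a) * t
    return np.linalg.norm(p - closest, axis=-1) - radius


def _sd_sphere(p: np.ndarray, center: np.ndarray, r: float) -> np.ndarray:
    return np.linalg.norm(p - center, axis=-1) - r


def _vertebra_field(pts: np.ndarray, prm: VertebraParams) -> np.ndarray:
    s = prm.level_scale
    ax, ay, az = (r * s for r in prm.body_radii)
    canal = prm.canal_radius * s
    tube = prm.arch_radius * s
    ring = canal + tube

    body_center = np.array([0.0, canal + ay, 0.0])
    d = _sd_ellipsoid(pts, body_center, np.array([ax, ay, az]))
    d = np.minimum(d, _sd_torus(pts, np.zeros(3), ring, tube))

    # spinous process: posterior midline, angled caudally
    th = np.deg2rad(prm.spinous_caudal_angle)
    sp_a = np.array([0.0, -ring + tube * 0.5, 0.0])
    sp_b = sp_a + prm.spinous_length * s * np.array([0.0, -np.cos(th), -np.sin(th)])
    d = np.minimum(
        d, _sd_capsule(pts, sp_a, sp_b, prm.spinous_radius * s, prm.spinous_radius * s * 0.45)
    )

    # transverse processes: lateral capsules from the arch
    for sign in (-1.0, 1.0):
        t_a = np.array([sign * ring * 0.8, 0.0, 0.0])
        t_b = np.array([sign * (ring * 0.8 + prm.transverse_length * s), -2.0 * s, 0.0])
        d = np.minimum(
            d, _sd_capsule(pts, t_a, t_b, prm.transverse_radius * s, prm.transverse_radius * s * 0.6)
        )

    # articular prominences: superior and inferior pairs, rooted on the arch
    # so the union stays a single connected component
    for cz in (prm.articular_height * s, -prm.articular_height * s):
        for sign in (-1.0, 1.0):
            root = np.array([sign * prm.articular_offset * s, -canal * 0.4, 0.0])
            tip = np.array([sign * prm.articular_offset * s, -canal * 0.4, cz])
            d = np.minimum(
                d,
                _sd_capsule(
                    pts, root, tip, prm.articular_radius * s, prm.articular_radius * s * 0.8
                ),
            )
    return d


def _facet_centers(prm: VertebraParams) -> dict[str, np.ndarray]:
    s = prm.level_scale
    canal = prm.canal_radius * s
    out = {}
    for name, (sign, up) in zip(
        FACET_NAMES, [(-1.0, 1.0), (1.0, 1.0), (-1.0, -1.0), (1.0, -1.0)]
    ):
        out[name] = np.array(
            [sign * prm.articular_offset * s, -canal * 0.4, up * prm.articular_height * s]
        )
    return out


def _spinous_centerline(prm: VertebraParams, n: int = 12) -> np.ndarray:
    """Dorsal crest polyline of the spinous process, on the analytic surface."""
    s = prm.level_scale
    canal = prm.canal_radius * s
    tube = prm.arch_radius * s
    ring = canal + tube
    th = np.deg2rad(prm.spinous_caudal_angle)
    axis_dir = np.array([0.0, -np.cos(th), -np.sin(th)])
    # outward normal of the crest: perpendicular to the axis in the sagittal
    # plane, pointing posterior-cranial (away from the body)
    crest_dir = np.array([0.0, -np.sin(th), np.cos(th)])
    a = np.array([0.0, -ring + tube * 0.5, 0.0])
    t = np.linspace(0.15, 0.95, n)
    radius = prm.spinous_radius * s * (1.0 + t * (0.45 - 1.0))
    pts = a + np.outer(t * prm.spinous_length * s, axis_dir) + np.outer(radius, crest_dir)
    return pts


def _grid(prm: VertebraParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    s = prm.level_scale
    res = prm.resolution
    ext_x = (prm.canal_radius + prm.arch_radius) * 0.8 * s + prm.transverse_length * s + prm.transverse_radius * s
    ext_x = max(ext_x, prm.articular_offset * s + prm.articular_radius * s)
    y_max = (prm.canal_radius + 2 * prm.body_radii[1]) * s
    y_min = -((prm.canal_radius + 1.5 * prm.arch_radius) * s + prm.spinous_length * s + prm.spinous_radius * s)
    ext_z = max(
        prm.body_radii[2] * s,
        prm.articular_height * s + prm.articular_radius * s,
        prm.spinous_length * s * np.sin(np.deg2rad(prm.spinous_caudal_angle)) + prm.spinous_radius * s,
    )
    margin = 2.0 * res
    nx = int(np.ceil((ext_x + margin) / res))
    xs = np.arange(-nx, nx + 1) * res  # symmetric about x=0 incl. 0
    ys = np.arange(y_min - margin, y_max + margin + res, res)
    nz = int(np.ceil((ext_z + margin) / res))
    zs = np.arange(-nz, nz + 1) * res
    return xs, ys, zs


def make_vertebra_with_landmarks(
    params: VertebraParams,
) -> tuple[TriangleMesh, dict[str, np.ndarray]]:
    """Build one vertebra mesh plus its construction-time landmark table.

    Landmarks: the four articular-prominence centers and the spinous-process
    dorsal crest polyline (key ``spinous_centerline``, an (N, 3) array).
    Emitting ground truth at construction time removes annotation ambiguity.
    """
    params.validate()
    xs, ys, zs = _grid(params)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    fld = _vertebra_field(pts.reshape(-1, 3), params).reshape(gx.shape)

    verts, faces, _, _ = measure.marching_cubes(fld, level=0.0)
    origin = np.array([xs[0], ys[0], zs[0]])
    verts = verts * params.resolution + origin

    if params.jitter_mm > 0:
        verts = verts + _smooth_jitter(verts, params.jitter_mm, params.seed)

    mesh = TriangleMesh(vertices=verts, faces=faces)
    landmarks: dict[str, np.ndarray] = dict(_facet_centers(params))
    landmarks["spinous_centerline"] = _spinous_centerline(params)
    return mesh, landmarks


def make_vertebra(params: VertebraParams) -> TriangleMesh:
    """Build one synthetic vertebra mesh (see :func:`make_vertebra_with_landmarks`)."""
    return make_vertebra_with_landmarks(params)[0]


def _smooth_jitter(verts: np.ndarray, amplitude: float, seed: int) -> np.ndarray:
    """Low-frequency deterministic displacement field (sum of random waves)."""
    rng = np.random.default_rng(seed)
    disp = np.zeros_like(verts)
    for _ in range(4):
        k = rng.normal(scale=0.08, size=3)  # ~80 mm wavelength
        phase = rng.uniform(0, 2 * np.pi)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        disp += np.sin(verts @ k + phase)[:, None] * direction
    mx = np.abs(disp).max()
    if mx > 0:
        disp *= amplitude / mx
    return disp


# --- spine assembly ---------------------------------------------------------


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def make_spine(
    n_levels: int = 5,
    params: VertebraParams | list[VertebraParams] | None = None,
    lordosis_deg: float = 15.0,
    gap_mm: float = 4.0,
    seed: int = 0,
) -> tuple[LabeledSpine, pd.DataFrame]:
    """Stack vertebrae cranio-caudally along a circular sagittal arc.

    Returns the spine (L1 first, cranial at +z) and a landmark table with one
    row per landmark point: columns ``level, landmark, x, y, z``. Spinous
    centerline points are rows ``spinous_00..``; the four articular centers
    are the fixture's facet-joint ground truth.

    ``lordosis_deg`` is the total sagittal arc angle across the stack;
    0 gives a straight column. ``gap_mm`` separates adjacent vertebrae.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if params is None:
        params = VertebraParams()
    if isinstance(params, VertebraParams):
        param_list = [replace(params, seed=params.seed + i) for i in range(n_levels)]
    else:
        param_list = list(params)
        if len(param_list) != n_levels:
            raise ValueError("need one VertebraParams per level")

    heights = [
        2 * p.body_radii[2] * p.level_scale + gap_mm for p in param_list
    ]
    # arc-length positions of vertebra centers (cranial to caudal)
    s_pos = np.concatenate([[0.0], np.cumsum(heights)])[:n_levels]
    s_pos = s_pos + np.array(heights) / 2.0
    total = float(np.cumsum(heights)[-1])

    angle_rad = np.deg2rad(lordosis_deg)
    entries: list[tuple[str, TriangleMesh]] = []
    rows: list[dict] = []
    prev_body_bounds: np.ndarray | None = None

    for i, prm in enumerate(param_list):
        mesh, marks = make_vertebra_with_landmarks(prm)
        if abs(angle_rad) < 1e-12:
            center = np.array([0.0, 0.0, -s_pos[i]])
            rot = np.eye(3)
        else:
            # circular arc in the sagittal (y–z) plane, lordosis = posterior
            # concavity: arc center anterior of the column
            radius = total / angle_rad
            phi = s_pos[i] / radius
            center = np.array([0.0, radius * (1 - np.cos(phi)), -radius * np.sin(phi)])
            rot = _rot_x(np.rad2deg(phi))

        verts = mesh.vertices @ rot.T + center
        placed = TriangleMesh(vertices=verts, faces=mesh.faces)

        # conservative inter-body overlap check along the stacking direction
        s = prm.level_scale
        body_c = rot @ np.array([0.0, prm.canal_radius * s + prm.body_radii[1] * s, 0.0]) + center
        half_z = prm.body_radii[2] * s
        bb = np.array([body_c[2] - half_z, body_c[2] + half_z])
        if prev_body_bounds is not None and bb[1] > prev_body_bounds[0] + 1e-9:
            raise PlacementError(
                f"vertebral bodies of levels {i} and {i + 1} interpenetrate"
            )
        prev_body_bounds = bb

        label = f"L{i + 1}"
        entries.append((label, placed))
        for name in FACET_NAMES:
            p = rot @ marks[name] + center
            rows.append(dict(level=label, landmark=name, x=p[0], y=p[1], z=p[2]))
        for j, p0 in enumerate(marks["spinous_centerline"]):
            p = rot @ p0 + center
            rows.append(dict(level=label, landmark=f"spinous_{j:02d}", x=p[0], y=p[1], z=p[2]))

    return LabeledSpine(levels=entries), pd.DataFrame(rows, columns=LANDMARK_COLUMNS)


def write_landmarks(table: pd.DataFrame, path) -> None:
    """Write the landmark sidecar (TSV: level, landmark, x, y, z)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_landmarks(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
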