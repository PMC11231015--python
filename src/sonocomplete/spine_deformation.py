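"""Rigid per-vertebra reposing along sampled sagittal curvatures.

Training-set diversity requires spines in the postures met during an
ultrasound exam (sitting flexes the lumbar spine and opens the interlaminar
space; prone extends it mildly). Each curvature sample assigns one sagittal
rotation per intervertebral joint, drawn from a truncated normal inside a
physiological limit, and every vertebra is moved by a single rigid transform
(cumulative joint rotations about mid-centroid pivots) so individual
vertebrae are never strained.

Sagittal-only rotations share the left-right axis, which makes deformation by
a sample followed by its negation an exact inverse; the opt-in axial/coronal
jitter augmentation does not carry that guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import truncnorm

from .geometry_io import LabeledSpine, TriangleMesh

__all__ = [
    "CurvatureSample",
    "SpineCurve",
    "ConstraintError",
    "fit_spine_curve",
    "sample_curvature",
    "deform_spine",
]

POSTURES = ("sitting", "prone")


class ConstraintError(RuntimeError):
    """A deformation violated the no-interpenetration constraint."""


@dataclass(frozen=True)
class CurvatureSample:
    """Per-joint sagittal rotations (degrees) for one posture draw.

    Positive angles flex (posterior convexity), negative extend.
    """

    posture: str
    joint_angles_deg: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.posture not in POSTURES:
            raise ValueError(f"posture must be one of {POSTURES}")

    def negated(self) -> "CurvatureSample":
        return CurvatureSample(
            posture=self.posture,
            joint_angles_deg=tuple(-a for a in self.joint_angles_deg),
            seed=self.seed,
        )


@dataclass
class SpineCurve:
    """Arc-length parameterized interpolant through vertebral centroids."""

    knots: np.ndarray          # (L, 3) centroids, cranial first
    arclength: np.ndarray      # (L,) cumulative chordal arc length
    spline: CubicSpline = field(repr=False)

    def __call__(self, s: np.ndarray | float) -> np.ndarray:
        return self.spline(s)

    @property
    def total_length(self) -> float:
        return float(self.arclength[-1])

    def curvature(self, s: np.ndarray) -> np.ndarray:
        d1 = self.spline(s, 1)
        d2 = self.spline(s, 2)
        num = np.linalg.norm(np.cross(d1, d2), axis=-1)
        den = np.linalg.norm(d1, axis=-1) ** 3
        return num / np.where(den == 0, 1.0, den)


def fit_spine_curve(spine: LabeledSpine) -> SpineCurve:
    """Cubic spline through the vertebral-body centroids, chord-length
    parameterized (natural boundary, so a straight column stays exactly
    straight with zero curvature everywhere)."""
    if len(spine) < 2:
        raise ValueError("need at least 2 levels to fit a curve")
    knots = spine.centroids()
    seg = np.linalg.norm(np.diff(knots, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    spline = CubicSpline(s, knots, bc_type="natural")
    return SpineCurve(knots=knots, arclength=s, spline=spline)


def sample_curvature(
    posture: str = "sitting",
    n_joints: int = 4,
    joint_limit_deg: float = 10.0,
    seed: int = 0,
) -> CurvatureSample:
    """Draw per-joint sagittal rotations from a truncated normal within
    ±joint_limit_deg.

    Sitting biases toward flexion (mean +limit/3), prone toward mild
    extension (mean −limit/6). A zero limit returns the identity sample.
    """
    if joint_limit_deg < 0:
        raise ValueError("joint_limit_deg must be >= 0")
    if joint_limit_deg == 0:
        return CurvatureSample(posture=posture, joint_angles_deg=(0.0,) * n_joints, seed=seed)
    mean = joint_limit_deg / 3.0 if posture == "sitting" else -joint_limit_deg / 6.0
    sd = joint_limit_deg / 2.5
    a = (-joint_limit_deg - mean) / sd
    b = (joint_limit_deg - mean) / sd
    rng = np.random.default_rng(seed)
    angles = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n_joints, random_state=rng)
    return CurvatureSample(posture=posture, joint_angles_deg=tuple(angles), seed=seed)


def _rot_about(angle_deg: float, axis: np.ndarray, pivot: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix + translation for a rotation about a line (axis, pivot)."""
    th = np.deg2rad(angle_deg)
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    t = pivot - R @ pivot
    return R, t


def deform_spine(
    spine: LabeledSpine,
    sample: CurvatureSample,
    *,
    check_interpenetration: bool = True,
) -> LabeledSpine:
    """Repose every vertebra rigidly along the sampled curvature.

    Joint j sits midway between the centroids of levels j and j+1; its
    rotation (about the left-right axis through the moved pivot) is applied
    to all levels caudal to it, so each vertebra receives the composition of
    the rotations of the joints above it — intra-vertebra distances are
    bit-exactly preserved.

    The output spine carries its (moved) joint pivots as provenance; when a
    spine already has them (i.e. it was produced by this function), they are
    reused, which makes deformation by a sample followed by its negation an
    exact inverse.
    """
    n = len(spine)
    if len(sample.joint_angles_deg) != n - 1:
        raise ValueError(
            f"sample has {len(sample.joint_angles_deg)} joints, spine needs {n - 1}"
        )
    cents = spine.centroids()
    if spine.joint_pivots is not None:
        pivots = np.asarray(spine.joint_pivots)
    else:
        pivots = 0.5 * (cents[:-1] + cents[1:])
    axis = np.array([1.0, 0.0, 0.0])  # left-right: sagittal-plane rotation

    transforms: list[tuple[np.ndarray, np.ndarray]] = [(np.eye(3), np.zeros(3))]
    moved_pivots = np.empty_like(pivots)
    R_acc, t_acc = np.eye(3), np.zeros(3)
    for j, ang in enumerate(sample.joint_angles_deg):
        pivot_moved = R_acc @ pivots[j] + t_acc
        moved_pivots[j] = pivot_moved
        Rj, tj = _rot_about(ang, axis, pivot_moved)
        R_acc = Rj @ R_acc
        t_acc = Rj @ t_acc + tj
        transforms.append((R_acc.copy(), t_acc.copy()))

    new_levels = []
    for (label, mesh), (R, t) in zip(spine.levels, transforms):
        new_levels.append(
            (label, TriangleMesh(vertices=mesh.vertices @ R.T + t, faces=mesh.faces))
        )
    out = LabeledSpine(levels=new_levels, joint_pivots=moved_pivots)

    if check_interpenetration:
        _check_no_interpenetration(out)
    return out


def _check_no_interpenetration(spine: LabeledSpine, max_probe: int = 300) -> None:
    """Adjacent-pair interpenetration check.

    A bounding-box prefilter selects candidate vertices, which are then
    parity-tested for containment in the neighboring mesh. Vertices exactly
    on a shared surface do not trigger (strict interior test).
    """
    from .geometry_io import points_inside_mesh

    for (la, ma), (lb, mb) in zip(spine.levels, spine.levels[1:]):
        for src, dst in ((ma, mb), (mb, ma)):
            verts = src.vertices
            if len(verts) > max_probe:
                step = len(verts) // max_probe
                verts = verts[::step]
            if points_inside_mesh(verts, dst).any():
                raise ConstraintError(
                    f"levels {la} and {lb} interpenetrate after deformation"
                )
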