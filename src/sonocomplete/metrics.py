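"""Shape-completion evaluation: CD, EMD, F1 and anatomy-aware measures.

Conventions:

* Chamfer distance (CD) averages *squared* Euclidean nearest-neighbor
  distances in each direction and sums the two directions; reported ×10⁴ on
  unit-normalized clouds (the usual completion-benchmark convention) unless
  the caller changes ``scale``.
* EMD is the mean per-point transport cost under the optimal one-to-one
  assignment (Euclidean ground cost) between equal-size clouds, solved
  exactly up to 4096 points; larger clouds are farthest-point subsampled to
  4096 and the result flagged approximate.
* F1 follows the relative-threshold precision/recall construction: by
  default the threshold is 1% of the ground-truth bounding-box diagonal.
* SP-CD applies the CD convention to spinous-process centerline polylines
  densified to ≤ 0.5 mm spacing; facet distance is the plain Euclidean
  error of a facet-joint center, with 5 mm the accepted tolerance for
  injection delivery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .geometry_io import PointCloud, farthest_point_indices

__all__ = [
    "CenterlineAnnotation",
    "FacetLandmark",
    "PairingError",
    "chamfer",
    "emd",
    "fscore",
    "sp_centerline_cd",
    "facet_distance",
    "summarize",
    "densify_polyline",
    "FACET_TOLERANCE_MM",
]

FACET_TOLERANCE_MM = 5.0
_EMD_EXACT_LIMIT = 4096


class PairingError(ValueError):
    """Landmarks to compare do not belong to the same level/side."""


@dataclass
class CenterlineAnnotation:
    """Ordered polyline along the spinous-process crest (mm)."""

    points: np.ndarray
    source: str = "input"  # "input" or "completion"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValueError("centerline needs at least 2 points")
        if np.any(np.linalg.norm(np.diff(self.points, axis=0), axis=1) == 0):
            raise ValueError("centerline has repeated consecutive points")


@dataclass(frozen=True)
class FacetLandmark:
    level: str
    side: str
    center: np.ndarray

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=np.float64).reshape(3))


def _as_points(pc) -> np.ndarray:
    pts = pc.points if isinstance(pc, PointCloud) else np.asarray(pc, dtype=np.float64)
    pts = pts.reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("empty point cloud")
    return pts


def chamfer(P, Q, scale: float = 1e4, squared: bool = True) -> float:
    """Symmetric Chamfer distance, mean per direction, times ``scale``."""
    p, q = _as_points(P), _as_points(Q)
    d_pq = cKDTree(q).query(p)[0]
    d_qp = cKDTree(p).query(q)[0]
    if squared:
        d_pq, d_qp = d_pq**2, d_qp**2
    return float(scale * (d_pq.mean() + d_qp.mean()))


def emd(P, Q, seed: int = 0) -> float:
    """Earth Mover's Distance: mean cost of the optimal 1:1 assignment."""
    p, q = _as_points(P), _as_points(Q)
    if len(p) != len(q):
        raise ValueError(f"EMD needs equal-size clouds, got {len(p)} vs {len(q)}")
    if len(p) > _EMD_EXACT_LIMIT:
        warnings.warn(
            f"clouds larger than {_EMD_EXACT_LIMIT} points: farthest-point "
            "subsampling makes this EMD approximate",
            RuntimeWarning,
            stacklevel=2,
        )
        p = p[np.sort(farthest_point_indices(p, _EMD_EXACT_LIMIT, seed=seed))]
        q = q[np.sort(farthest_point_indices(q, _EMD_EXACT_LIMIT, seed=seed))]
    cost = np.linalg.norm(p[:, None, :] - q[None, :, :], axis=2)
    ri, ci = linear_sum_assignment(cost)
    return float(cost[ri, ci].mean())


def fscore(P, Q, d_threshold: float | None = None) -> tuple[float, float, float]:
    """Precision/recall/F1 of P against Q at a distance threshold.

    Default threshold: 1% of Q's bounding-box diagonal.
    """
    p, q = _as_points(P), _as_points(Q)
    if d_threshold is None:
        d_threshold = 0.01 * float(np.linalg.norm(q.max(axis=0) - q.min(axis=0)))
    if d_threshold <= 0:
        raise ValueError("d_threshold must be positive")
    precision = float((cKDTree(q).query(p)[0] <= d_threshold).mean())
    recall = float((cKDTree(p).query(q)[0] <= d_threshold).mean())
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def densify_polyline(points: np.ndarray, max_spacing: float = 0.5) -> np.ndarray:
    """Insert points so no segment of the polyline exceeds ``max_spacing``."""
    points = np.asarray(points, dtype=np.float64)
    out = [points[:1]]
    for a, b in zip(points, points[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / max_spacing)), 1)
        ts = np.linspace(0.0, 1.0, n + 1)[1:]
        out.append(a + ts[:, None] * (b - a))
    return np.vstack(out)


def sp_centerline_cd(
    pred: CenterlineAnnotation,
    ref: CenterlineAnnotation,
    scale: float = 1e4,
    squared: bool = True,
    max_spacing: float = 0.5,
) -> float:
    """Chamfer distance between densified spinous-process centerlines."""
    p = densify_polyline(pred.points, max_spacing)
    r = densify_polyline(ref.points, max_spacing)
    return chamfer(p, r, scale=scale, squared=squared)


def facet_distance(pred: FacetLandmark, gt: FacetLandmark) -> float:
    """Euclidean distance (mm) between matching facet-joint centers."""
    if pred.level != gt.level or pred.side != gt.side:
        raise PairingError(
            f"cannot pair {pred.level}/{pred.side} with {gt.level}/{gt.side}"
        )
    return float(np.linalg.norm(pred.center - gt.center))


# ---------------------------------------------------------------------------
# Report aggregation
# ---------------------------------------------------------------------------

_NUMERIC = ["cd_scaled", "emd", "f1", "precision", "recall",
            "sp_cd", "facet_left_mm", "facet_right_mm"]


def summarize(
    rows: list[dict] | pd.DataFrame,
    facet_tolerance_mm: float = FACET_TOLERANCE_MM,
) -> pd.DataFrame:
    """Assemble the per-item metric rows plus mean/median aggregate rows.

    Rows may carry any subset of the metric columns; aggregates use the
    non-missing entries per column. Rows with both facet distances also get
    ``facet_pair_acceptable``: whether the mean of the left and right facet
    errors stays within the injection tolerance (default 5 mm).
    """
    df = pd.DataFrame(rows).copy() if not isinstance(rows, pd.DataFrame) else rows.copy()
    if len(df) == 0:
        raise ValueError("need at least one metrics row")
    for col in _NUMERIC:
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "id" not in df.columns:
        df["id"] = [f"item{i}" for i in range(len(df))]

    if {"f1"} <= set(df.columns) and df["f1"].notna().any():
        bad = df["f1"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError("f1 outside [0, 1]")

    pair_mean = df[["facet_left_mm", "facet_right_mm"]].mean(axis=1)
    has_both = df["facet_left_mm"].notna() & df["facet_right_mm"].notna()
    df["facet_pair_acceptable"] = np.where(
        has_both, pair_mean <= facet_tolerance_mm, np.nan
    ).astype(object)
    df.loc[~has_both, "facet_pair_acceptable"] = pd.NA

    agg_rows = []
    for name, fn in (("mean", np.nanmean), ("median", np.nanmedian)):
        rec = {"id": name}
        for col in _NUMERIC:
            vals = df[col].to_numpy(dtype=float)
            rec[col] = fn(vals) if np.isfinite(vals).any() else np.nan
        agg_rows.append(rec)
    agg = pd.DataFrame(agg_rows)
    agg["facet_pair_acceptable"] = pd.NA
    out = pd.concat([df, agg], ignore_index=True)
    out.attrs["facet_tolerance_mm"] = facet_tolerance_mm
    out.attrs["n_acceptable_facet_pairs"] = int(
        sum(bool(v) for v in df.loc[has_both, "facet_pair_acceptable"])
    )
    out.attrs["n_facet_pairs"] = int(has_both.sum())
    return out
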