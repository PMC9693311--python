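"""Core 3D types and primitives for point-cloud registration.

Everything downstream of raw scans is built on three primitives: k-d-tree
nearest-neighbor correspondence, statistical outlier rejection at the
threshold ``th = mean + 2*sd`` of the current nearest-neighbor distances,
and closed-form least-squares rigid alignment (Kabsch/SVD with a reflection
guard).  Coordinates are millimetres throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateRegistrationError, InvalidInputError

__all__ = [
    "PointCloud",
    "RigidTransform",
    "CorrespondenceSet",
    "nearest_neighbors",
    "reject_outliers",
    "estimate_rigid",
    "estimate_rigid_point_to_plane",
]


def _as_points(obj) -> np.ndarray:
    """Coerce a PointCloud or array-like to a validated (n, 3) float array."""
    pts = obj.points if isinstance(obj, PointCloud) else np.asarray(obj, dtype=float)
    pts = np.atleast_2d(pts)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidInputError(f"expected an (n, 3) point array, got shape {pts.shape}")
    if pts.shape[0] == 0:
        raise InvalidInputError("empty point cloud")
    if not np.all(np.isfinite(pts)):
        raise InvalidInputError("point coordinates must be finite")
    return pts


@dataclass(frozen=True)
class PointCloud:
    """An unordered set of 3D points (one scan of one surface), millimetres.

    Parameters
    ----------
    points : (n, 3) array
        Vertex coordinates.  No topology is implied.
    label : str, optional
        Subject identifier, when known.
    scan_id : str, optional
        Stable identifier of the individual scan.
    """

    points: np.ndarray
    label: str | None = None
    scan_id: str | None = None

    def __post_init__(self):
        pts = np.ascontiguousarray(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InvalidInputError(f"points must be (n, 3), got shape {pts.shape}")
        if pts.shape[0] < 1:
            raise InvalidInputError("a point cloud needs at least one point")
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("point coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def bounding_box_diagonal(self) -> float:
        extent = self.points.max(axis=0) - self.points.min(axis=0)
        return float(np.linalg.norm(extent))

    def transformed(self, transform: "RigidTransform") -> "PointCloud":
        return replace(self, points=transform.apply(self.points))


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InvalidInputError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise InvalidInputError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise InvalidInputError("reflections are not rigid motions (det must be +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``first`` then ``self``."""
        return RigidTransform(
            self.rotation @ first.rotation,
            self.rotation @ first.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


@dataclass
class CorrespondenceSet:
    """Per-point nearest-neighbor matches between a source and a target cloud.

    ``distances`` are Euclidean (mm); ``inlier_mask`` marks matches that
    survive outlier rejection.  Houses the quantities ``d̄``, ``σd`` and the
    rejection threshold ``th = d̄ + 2 σd``.
    """

    source_indices: np.ndarray
    target_indices: np.ndarray
    distances: np.ndarray
    inlier_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    threshold: float | None = None

    def __post_init__(self):
        self.source_indices = np.asarray(self.source_indices, dtype=int)
        self.target_indices = np.asarray(self.target_indices, dtype=int)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.inlier_mask is None:
            self.inlier_mask = np.ones(len(self.distances), dtype=bool)
        else:
            self.inlier_mask = np.asarray(self.inlier_mask, dtype=bool)
        n = len(self.distances)
        if not (len(self.source_indices) == len(self.target_indices) == n == len(self.inlier_mask)):
            raise InvalidInputError("correspondence arrays must have equal length")
        if n and self.distances.min() < 0:
            raise InvalidInputError("distances must be nonnegative")

    def __len__(self) -> int:
        return len(self.distances)

    @property
    def n_inliers(self) -> int:
        return int(self.inlier_mask.sum())

    def inlier_rmse(self) -> float:
        d = self.distances[self.inlier_mask]
        if d.size == 0:
            return float("nan")
        return float(np.sqrt(np.mean(d**2)))


def nearest_neighbors(source, target) -> CorrespondenceSet:
    """Match every source point to its closest target point (k-d tree).

    Returns a :class:`CorrespondenceSet` with the all-true inlier mask.
    Deterministic for fixed input.
    """
    src = _as_points(source)
    tgt = _as_points(target)
    tree = cKDTree(tgt)
    distances, indices = tree.query(src, k=1)
    return CorrespondenceSet(
        source_indices=np.arange(src.shape[0]),
        target_indices=indices,
        distances=distances,
    )


def reject_outliers(corr: CorrespondenceSet) -> CorrespondenceSet:
    """Flag correspondences with distance strictly above ``th = d̄ + 2 σd``.

    The mean and the population standard deviation are taken over *all*
    correspondences of the set (the current iteration's distances), not just
    previous inliers.  Raises if fewer than 3 inliers survive — that is too
    degenerate to estimate a rigid transform from.
    """
    d = corr.distances
    if d.size == 0:
        raise InvalidInputError("cannot reject outliers of an empty correspondence set")
    th = float(d.mean() + 2.0 * d.std())  # population sd (ddof=0)
    mask = d <= th
    if mask.sum() < 3:
        raise DegenerateRegistrationError(
            f"only {int(mask.sum())} inliers remain below th={th:.4g}; need at least 3"
        )
    return CorrespondenceSet(
        source_indices=corr.source_indices,
        target_indices=corr.target_indices,
        distances=corr.distances,
        inlier_mask=mask,
        threshold=th,
    )


def estimate_rigid(source_pts, target_pts) -> RigidTransform:
    """Least-squares proper rigid transform mapping source points onto targets.

    Closed-form Kabsch solution via SVD of the cross-covariance; a reflection
    is excluded by flipping the sign of the smallest singular direction when
    the determinant would be negative.
    """
    src = _as_points(source_pts)
    tgt = _as_points(target_pts)
    if src.shape != tgt.shape:
        raise InvalidInputError("source and target point sets must be paired (same shape)")
    if src.shape[0] < 3:
        raise DegenerateRegistrationError("need at least 3 point pairs")

    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)

    # collinear (rank < 2) source or target leaves the rotation underdetermined
    for pts, name in ((src_c, "source"), (tgt_c, "target")):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] <= 1e-10 * max(sv[0], 1e-30):
            raise DegenerateRegistrationError(f"{name} points are collinear or coincident")

    H = src_c.T @ tgt_c
    U, _, Vt = np.linalg.svd(H)
    D = np.eye(3)
    if np.linalg.det(Vt.T @ U.T) < 0:
        D[2, 2] = -1.0
    R = Vt.T @ D @ U.T
    t = tgt.mean(axis=0) - R @ src.mean(axis=0)
    return RigidTransform(R, t)


def estimate_rigid_point_to_plane(source_pts, target_pts, target_normals) -> RigidTransform:
    """One Gauss-Newton step of point-to-plane rigid alignment.

    Minimizes Σ ((R p + t − v) · n̂)² over a linearized rotation, where the
    pairs (p, v) are matched source/target points and n̂ the target-side unit
    normals.  Point-to-plane alignment does not suffer the tangential-sliding
    bias of point-to-point estimation on smooth surfaces; it is the rigid
    step of choice wherever the target carries a mesh.
    """
    p = _as_points(source_pts)
    v = _as_points(target_pts)
    n = np.asarray(target_normals, dtype=float)
    if not (p.shape == v.shape == n.shape):
        raise InvalidInputError("matched points and normals must have identical shapes")
    if p.shape[0] < 3:
        raise DegenerateRegistrationError("need at least 3 point pairs")
    A = np.hstack([np.cross(p, n), n])
    b = np.sum((v - p) * n, axis=1)
    x, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 6:
        raise DegenerateRegistrationError("point-to-plane system is rank deficient")
    w, t = x[:3], x[3:]
    angle = float(np.linalg.norm(w))
    if angle < 1e-15:
        R = np.eye(3)
    else:
        k = w / angle
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    return RigidTransform(R, t)
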