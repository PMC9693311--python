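"""Rigid ICP, template-morphing non-rigid ICP, and template bootstrapping.

Dense correspondence is established by morphing a single template mesh onto
every scan: rigid ICP pre-aligns the scan to the template frame, then an
optimal-step non-rigid ICP (locally affine regularization, solved as a
sparse linear least-squares problem per stiffness level) deforms the
template onto the scan.  Iterating register → average → re-template
("bootstrapping") removes the bias of the initial template choice.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import Delaunay, cKDTree
from scipy.sparse.csgraph import connected_components

from .errors import (
    CorrespondenceError,
    DegenerateRegistrationError,
    EarMorphError,
    InvalidConfigError,
    InvalidInputError,
    PipelineError,
)
from .geometry import (
    PointCloud,
    RigidTransform,
    estimate_rigid,
    estimate_rigid_point_to_plane,
    nearest_neighbors,
    reject_outliers,
)

__all__ = [
    "TemplateMesh",
    "CorrespondedShape",
    "BootstrapResult",
    "DEFAULT_STIFFNESS_SCHEDULE",
    "rigid_icp",
    "rigid_align_to_mesh",
    "nonrigid_icp",
    "bootstrap_correspondence",
    "procrustes_align",
    "mesh_from_points",
    "vertex_normals",
]


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted unit vertex normals of a triangle mesh."""
    V = np.asarray(vertices, dtype=float)
    F = np.asarray(faces, dtype=np.int64)
    fn = np.cross(V[F[:, 1]] - V[F[:, 0]], V[F[:, 2]] - V[F[:, 0]])
    vn = np.zeros_like(V)
    for k in range(3):
        np.add.at(vn, F[:, k], fn)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    return vn / np.maximum(norms, 1e-30)

#: Default stiffness schedule for the non-rigid step: 8 levels decreasing
#: geometrically from 50 to 0.2, standard practice for optimal-step
#: locally-affine non-rigid ICP.
DEFAULT_STIFFNESS_SCHEDULE: tuple[float, ...] = tuple(
    float(x) for x in np.geomspace(50.0, 0.2, 8)
)


def _faces_hash(faces: np.ndarray, n_vertices: int) -> str:
    h = hashlib.sha1()
    h.update(np.int64(n_vertices).tobytes())
    h.update(np.ascontiguousarray(faces, dtype=np.int64).tobytes())
    return h.hexdigest()[:16]


@dataclass(frozen=True)
class TemplateMesh:
    """A triangle mesh whose vertex indexing defines the correspondence.

    ``topology_id`` is a stable hash of the face array (plus vertex count);
    all shapes claimed to be in dense correspondence share it.
    """

    vertices: np.ndarray
    faces: np.ndarray
    topology_id: str = field(default="")

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise InvalidInputError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise InvalidInputError("faces must be (m, 3) triangles")
        if f.size and (f.min() < 0 or f.max() >= v.shape[0]):
            raise InvalidInputError("face indices out of range")
        # single connected component over the edge graph
        i = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
        j = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
        adj = sp.coo_matrix((np.ones(len(i)), (i, j)), shape=(v.shape[0],) * 2)
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp != 1:
            raise InvalidInputError(f"template mesh must be a single connected component, found {n_comp}")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        object.__setattr__(self, "topology_id", _faces_hash(f, v.shape[0]))

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) index array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def bounding_box_diagonal(self) -> float:
        extent = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(extent))

    def with_vertices(self, vertices: np.ndarray) -> "TemplateMesh":
        return TemplateMesh(vertices, self.faces)


@dataclass(frozen=True)
class CorrespondedShape:
    """A shape vector over a shared template topology.

    The vector stacks coordinates as ``[x1..xn, y1..yn, z1..zn]`` and
    round-trips losslessly to an (n, 3) vertex array.
    """

    vector: np.ndarray
    topology_id: str
    label: str | None = None

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vector, dtype=float).reshape(-1))
        if v.size % 3 != 0 or v.size == 0:
            raise InvalidInputError("shape vector length must be a positive multiple of 3")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("shape vector must be finite")
        object.__setattr__(self, "vector", v)

    @classmethod
    def from_points(cls, points: np.ndarray, topology_id: str, label: str | None = None) -> "CorrespondedShape":
        pts = np.asarray(points, dtype=float)
        return cls(np.concatenate([pts[:, 0], pts[:, 1], pts[:, 2]]), topology_id, label)

    @property
    def n_vertices(self) -> int:
        return self.vector.size // 3

    def to_points(self) -> np.ndarray:
        n = self.n_vertices
        v = self.vector
        return np.column_stack([v[:n], v[n : 2 * n], v[2 * n :]])


def _principal_axes(points: np.ndarray) -> np.ndarray:
    """Right-handed principal-axis basis, columns sorted by variance."""
    c = points - points.mean(axis=0)
    _, _, Vt = np.linalg.svd(c, full_matrices=False)
    B = Vt.T
    if np.linalg.det(B) < 0:
        B[:, 2] = -B[:, 2]
    return B


#: Largest rotation (degrees) a coarse initializer may apply.  Scans are
#: assumed consistently oriented (the "upward facing" input contract): a
#: candidate alignment that turns the scan by more than this is a mirror or
#: flip artifact of the principal-axis sign ambiguity, not a plausible pose.
MAX_INIT_ROTATION_DEG = 75.0


def _coarse_init_candidates(src: np.ndarray, tgt: np.ndarray) -> list[RigidTransform]:
    """Deterministic coarse initializers: centroid shift plus the proper
    principal-axis alignments compatible with the orientation contract.

    The four sign combinations of the principal axes include mirrored and
    flipped alignments; those rotating the scan by more than
    :data:`MAX_INIT_ROTATION_DEG` are discarded, since consistently oriented
    scans never need them.  The centroid-only candidate is always kept.
    """
    t0 = tgt.mean(axis=0) - src.mean(axis=0)
    candidates = [RigidTransform(np.eye(3), t0)]
    Bs, Bt = _principal_axes(src), _principal_axes(tgt)
    cos_max = np.cos(np.deg2rad(MAX_INIT_ROTATION_DEG))
    for s1, s2 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        S = np.diag([s1, s2, s1 * s2])  # keeps det(R) = +1
        R = Bt @ S @ Bs.T
        if (np.trace(R) - 1.0) / 2.0 < cos_max:
            continue
        t = tgt.mean(axis=0) - R @ src.mean(axis=0)
        candidates.append(RigidTransform(R, t))
    return candidates


def _inlier_rmse(src: np.ndarray, tree: cKDTree) -> float:
    d, _ = tree.query(src, k=1)
    th = d.mean() + 2.0 * d.std()
    d = d[d <= th]
    return float(np.sqrt(np.mean(d**2))) if d.size else float("inf")


def _symmetric_nn_score(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric mean nearest-neighbor distance; robust against partial
    overlap tricks that fool a one-directional trimmed score (e.g. a flipped
    patch lying close to the target on one side only)."""
    da, _ = cKDTree(b).query(a)
    db, _ = cKDTree(a).query(b)
    return float(da.mean() + db.mean())


def upsample_mesh(vertices: np.ndarray, faces: np.ndarray, levels: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic midpoint subdivision (no smoothing), for dense scoring.

    Distances measured against sparse template vertices are dominated by the
    ~vertex-spacing quantization; registration scores therefore evaluate
    against a subdivided copy of the surface instead.
    """
    V = np.asarray(vertices, dtype=float)
    F = np.asarray(faces, dtype=np.int64)
    for _ in range(levels):
        e = np.vstack([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]])
        e.sort(axis=1)
        e, inv = np.unique(e, axis=0, return_inverse=True)
        mids = V[e].mean(axis=1)
        midx = len(V) + inv.reshape(3, -1).T  # per face: mid01, mid12, mid20
        V = np.vstack([V, mids])
        f0, f1, f2 = F[:, 0], F[:, 1], F[:, 2]
        m01, m12, m20 = midx[:, 0], midx[:, 1], midx[:, 2]
        F = np.vstack([
            np.column_stack([f0, m01, m20]),
            np.column_stack([f1, m12, m01]),
            np.column_stack([f2, m20, m12]),
            np.column_stack([m01, m12, m20]),
        ])
    return V, F


def _trimmed_rms(d: np.ndarray) -> float:
    th = d.mean() + 2.0 * d.std()
    d = d[d <= th]
    return float(np.sqrt(np.mean(d**2))) if d.size else float("inf")


def _inplane_spins(ref: np.ndarray, angles_deg) -> list[RigidTransform]:
    """Rotations about the reference patch's normal axis, through its centroid."""
    axis = _principal_axes(ref)[:, 2]
    center = ref.mean(axis=0)
    out = []
    for ang in angles_deg:
        th = np.deg2rad(float(ang))
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        out.append(RigidTransform(R, center - R @ center))
    return out


#: In-plane start angles for rigid alignment; alignment of a shallow patch
#: against a template has nearby local minima that a single start can miss.
INPLANE_START_GRID_DEG: tuple[float, ...] = (-20.0, -10.0, 0.0, 10.0, 20.0)


def rigid_align_to_mesh(
    points: np.ndarray,
    mesh: TemplateMesh,
    max_iter: int = 60,
    tol: float = 1e-10,
    inplane_grid_deg=INPLANE_START_GRID_DEG,
) -> tuple[RigidTransform, np.ndarray]:
    """Robust rigid alignment of a scan onto a template mesh.

    Multi-start: the deterministic coarse initializers (centroid shift plus
    proper principal-axis alignments within the orientation contract) are
    combined with a grid of in-plane spins; every start is refined by
    point-to-plane ICP — mesh vertices matched into the scan by a k-d tree,
    outliers rejected at ``th = d̄ + 2σd``, the scan moved onto the matched
    vertices' tangent planes — and the pose with the best symmetric
    nearest-neighbor score wins.  Returns the cumulative transform and the
    aligned points.
    """
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points, dtype=float)
    ref = mesh.vertices
    normals = vertex_normals(ref, mesh.faces)
    spins = _inplane_spins(ref, inplane_grid_deg)
    starts = [spin.compose(c) for c in _coarse_init_candidates(pts, ref) for spin in spins]
    dense_ref, _ = upsample_mesh(ref, mesh.faces, levels=2)
    dense_tree = cKDTree(dense_ref)

    def refine(T0: RigidTransform) -> tuple[RigidTransform, np.ndarray]:
        T = T0
        cur = T.apply(pts)
        for _ in range(max_iter):
            dists, idx = cKDTree(cur).query(ref)
            th = dists.mean() + 2.0 * dists.std()
            inl = dists <= th
            if inl.sum() < 3:
                raise DegenerateRegistrationError("too few inliers for point-to-plane alignment")
            step = estimate_rigid_point_to_plane(cur[idx[inl]], ref[inl], normals[inl])
            cur = step.apply(cur)
            T = step.compose(T)
            if np.abs(step.rotation - np.eye(3)).max() < tol and np.abs(step.translation).max() < tol:
                break
        return T, cur

    # dedupe starts cheaply by refining only poses that are still distinct
    best = None
    seen: list[RigidTransform] = []
    for T0 in starts:
        if any(
            np.degrees(np.arccos(np.clip((np.trace(T0.rotation @ S.rotation.T) - 1) / 2, -1, 1))) < 3.0
            for S in seen
        ):
            continue
        seen.append(T0)
        try:
            T, cur = refine(T0)
        except DegenerateRegistrationError:
            continue
        # coverage score against the densified surface: penalizes scan
        # regions the pose leaves unexplained, which a vertex-only score
        # blurs away under the vertex-spacing quantization
        d_cov, _ = dense_tree.query(cur)
        d_vtx, _ = cKDTree(cur).query(ref)
        score = _trimmed_rms(d_cov) + _trimmed_rms(d_vtx)
        if best is None or score < best[0]:
            best = (score, T, cur)
    if best is None:
        raise DegenerateRegistrationError("rigid alignment failed from every start")
    return best[1], best[2]


def rigid_icp(
    source,
    target,
    max_iter: int = 50,
    tol: float = 1e-8,
    init: str | RigidTransform = "auto",
) -> tuple[RigidTransform, float]:
    """Iterative closest point with outlier rejection.

    Alternates nearest-neighbor correspondence, rejection at
    ``th = d̄ + 2σd``, and closed-form rigid estimation until the inlier
    RMSE change drops below ``tol`` or ``max_iter`` is reached.  A step that
    would increase the RMSE is rejected and iteration stops, so the RMSE is
    non-increasing over accepted iterations.

    ``init`` may be a :class:`RigidTransform`, ``"identity"``/``"centroid"``
    (centroid alignment only) or ``"auto"`` (centroid alignment plus the
    best of four proper principal-axis alignments by initial inlier RMSE).

    Returns the cumulative source→target transform and the final inlier RMSE.
    """
    if max_iter < 1:
        raise InvalidConfigError("max_iter must be >= 1")
    src = source.points if isinstance(source, PointCloud) else np.asarray(source, dtype=float)
    tgt = target.points if isinstance(target, PointCloud) else np.asarray(target, dtype=float)
    tree = cKDTree(tgt)

    if isinstance(init, RigidTransform):
        T = init
    elif init in ("identity", "centroid"):
        T = RigidTransform(np.eye(3), tgt.mean(axis=0) - src.mean(axis=0))
    elif init == "auto":
        cands = _coarse_init_candidates(src, tgt)
        T = min(cands, key=lambda c: _inlier_rmse(c.apply(src), tree))
    else:
        raise InvalidConfigError(f"unknown init {init!r}")

    cur = T.apply(src)
    rmse_prev: float | None = None
    for _ in range(max_iter):
        corr = nearest_neighbors(cur, tgt)
        corr = reject_outliers(corr)
        inl = corr.inlier_mask
        step = estimate_rigid(cur[inl], tgt[corr.target_indices[inl]])
        cur_new = step.apply(cur)
        resid = cur_new[inl] - tgt[corr.target_indices[inl]]
        rmse = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
        if rmse_prev is not None and rmse > rmse_prev:
            break  # reject the step; keep the previous (better) transform
        T = step.compose(T)
        cur = cur_new
        converged = rmse_prev is not None and (rmse_prev - rmse) < tol
        rmse_prev = rmse
        if converged:
            break
    return T, float(rmse_prev if rmse_prev is not None else np.nan)


def nonrigid_icp(
    template: TemplateMesh,
    target,
    stiffness_schedule=DEFAULT_STIFFNESS_SCHEDULE,
    gamma: float = 1.0,
    max_inner: int = 20,
    inner_tol_frac: float = 1e-4,
    match_k: int = 5,
    data_term: str = "normal",
    label: str | None = None,
) -> CorrespondedShape:
    """Optimal-step non-rigid ICP: morph the template onto a target cloud.

    Each template vertex carries an unknown 3×4 affine transform; per
    stiffness level the algorithm alternates (a) nearest-neighbor
    correspondences from the deformed template into the target with outlier
    down-weighting at ``th = d̄ + 2σd`` and (b) an exact sparse
    least-squares solve of

        || α (M ⊗ G) X ||² + || W (D X − U) ||²  →  min over X,

    where ``M`` is the node-arc incidence of the template edges, ``G``
    weights the affine skew against translation (``gamma``), ``D`` maps the
    stacked transforms onto deformed vertex positions and ``U`` holds the
    matched target points.  The schedule must be strictly decreasing; the
    caller is expected to have pre-aligned the inputs rigidly (misalignment
    is not detected).

    Returns a :class:`CorrespondedShape` on the template's topology.
    """
    schedule = [float(a) for a in stiffness_schedule]
    if not schedule or any(a <= 0 for a in schedule):
        raise InvalidConfigError("stiffness schedule must be non-empty and positive")
    if any(b >= a for a, b in zip(schedule, schedule[1:])):
        raise InvalidConfigError("stiffness schedule must be strictly decreasing")

    tgt = target.points if isinstance(target, PointCloud) else np.asarray(target, dtype=float)
    tree = cKDTree(tgt)

    n = template.n_vertices
    V = template.vertices
    edges = template.edges()
    E = edges.shape[0]

    # M ⊗ G : (4E, 4n) edge-difference regularizer on the affine unknowns
    G = np.array([1.0, 1.0, 1.0, gamma])
    rows = np.repeat(np.arange(4 * E), 2)
    cols = np.empty(8 * E, dtype=np.int64)
    vals = np.empty(8 * E)
    for k in range(4):
        cols[2 * k :: 8] = 4 * edges[:, 0] + k
        cols[2 * k + 1 :: 8] = 4 * edges[:, 1] + k
        vals[2 * k :: 8] = -G[k]
        vals[2 * k + 1 :: 8] = G[k]
    MG = sp.csr_matrix((vals, (rows, cols)), shape=(4 * E, 4 * n))

    # D : (n, 4n), row i = [x_i y_i z_i 1] in block i
    d_cols = (4 * np.arange(n)[:, None] + np.arange(4)[None, :]).ravel()
    d_rows = np.repeat(np.arange(n), 4)
    d_vals = np.column_stack([V, np.ones(n)]).ravel()
    D = sp.csr_matrix((d_vals, (d_rows, d_cols)), shape=(n, 4 * n))

    # X0 = identity affine per vertex
    X = np.zeros((4 * n, 3))
    X[0::4, 0] = 1.0
    X[1::4, 1] = 1.0
    X[2::4, 2] = 1.0

    diag = template.bounding_box_diagonal()
    move_tol = inner_tol_frac * diag

    for alpha in schedule:
        reg = alpha * MG
        regTreg = (reg.T @ reg).tocsc()
        # density-adaptive correspondence averaging: each vertex is matched
        # to the mean of its k nearest target points, damping the jitter of
        # snapping to individual samples; k collapses to 1 for sparse targets
        k = max(1, min(match_k, tgt.shape[0] // n, tgt.shape[0]))
        for _ in range(max_inner):
            V_def = D @ X
            dists, idx = tree.query(V_def, k=k)
            if k == 1:
                dists, idx = dists[:, None], idx[:, None]
            d0 = dists[:, 0]
            th = d0.mean() + 2.0 * d0.std()
            w = (d0 <= th).astype(float)
            U_t = tgt[idx].mean(axis=1)
            if data_term == "normal":
                # project each correction onto the current vertex normal:
                # sampling noise is tangentially random, so tangential
                # placement is left to the (deterministic) regularizer and
                # correspondence stays consistent across scans
                n_def = vertex_normals(V_def, template.faces)
                U_t = V_def + n_def * np.sum((U_t - V_def) * n_def, axis=1, keepdims=True)
            elif data_term != "full":
                raise InvalidConfigError("data_term must be 'normal' or 'full'")
            WD = sp.diags(w) @ D
            A_data = (WD.T @ WD).tocsc()
            rhs = WD.T @ (w[:, None] * U_t)
            X_new = spla.spsolve(A_data + regTreg, rhs)
            if X_new.ndim == 1:
                X_new = X_new.reshape(4 * n, 3)
            move = float(np.linalg.norm(D @ X_new - V_def, axis=1).mean())
            X = X_new
            if move < move_tol:
                break

    return CorrespondedShape.from_points(D @ X, template.topology_id, label=label)


def _farthest_point_subsample(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy farthest-point sampling for a roughly uniform subset."""
    n = points.shape[0]
    if k >= n:
        return points
    chosen = np.empty(k, dtype=int)
    chosen[0] = int(rng.integers(n))
    dist = np.linalg.norm(points - points[chosen[0]], axis=1)
    for i in range(1, k):
        chosen[i] = int(np.argmax(dist))
        dist = np.minimum(dist, np.linalg.norm(points - points[chosen[i]], axis=1))
    return points[np.sort(chosen)]


def mesh_from_points(
    points: np.ndarray,
    target_size: int | None = None,
    seed: int = 0,
) -> TemplateMesh:
    """Triangulate a patch-like point cloud into a template mesh.

    Projects the points onto their two leading principal axes and applies a
    planar Delaunay triangulation — appropriate for surfaces that are
    (approximately) height fields over a plane, as segmented ear patches
    are.  ``target_size`` optionally subsamples the cloud first
    (farthest-point sampling) so the template stays compact.
    """
    pts = np.asarray(points, dtype=float)
    rng = np.random.default_rng(seed)
    if target_size is not None and target_size < pts.shape[0]:
        pts = _farthest_point_subsample(pts, target_size, rng)
    B = _principal_axes(pts)
    uv = (pts - pts.mean(axis=0)) @ B[:, :2]
    tri = Delaunay(uv)
    return TemplateMesh(pts, tri.simplices)


def procrustes_align(shapes: list[CorrespondedShape], max_iter: int = 5, tol: float = 1e-10) -> list[CorrespondedShape]:
    """Generalized Procrustes alignment of corresponded shapes.

    Rigidly aligns every shape to the evolving mean using the exact
    vertex correspondence (closed-form Kabsch per shape), iterating until
    the mean stabilizes.  Removes residual pose variance from the
    corresponded set so that the shape model built on it contains no
    rotation- or translation-like modes; standard practice in statistical
    shape modeling.
    """
    if not shapes:
        return []
    tid = shapes[0].topology_id
    if any(s.topology_id != tid for s in shapes):
        raise CorrespondenceError("shapes do not share a topology_id")
    pts = [s.to_points() for s in shapes]
    mean = np.mean(pts, axis=0)
    for _ in range(max_iter):
        pts = [estimate_rigid(p, mean).apply(p) for p in pts]
        new_mean = np.mean(pts, axis=0)
        if np.abs(new_mean - mean).max() < tol:
            mean = new_mean
            break
        mean = new_mean
    return [
        CorrespondedShape.from_points(p, tid, label=s.label) for p, s in zip(pts, shapes)
    ]


@dataclass
class BootstrapResult:
    """Output of :func:`bootstrap_correspondence`.

    Unpacks as ``template, shapes = result`` for convenience; failed scans
    are listed in ``failures`` as ``(scan_index, round, message)``.
    """

    template: TemplateMesh
    shapes: list[CorrespondedShape]
    failures: list[tuple[int, int, str]] = field(default_factory=list)

    def __iter__(self):
        return iter((self.template, self.shapes))


def bootstrap_correspondence(
    scans: list[PointCloud],
    rounds: int = 2,
    seed: int = 0,
    template: TemplateMesh | None = None,
    template_size: int = 250,
    stiffness_schedule=DEFAULT_STIFFNESS_SCHEDULE,
) -> BootstrapResult:
    """Bring a set of raw scans into dense correspondence by re-templating.

    Round 0 picks one scan at random (seeded) as the initial template
    (triangulated via :func:`mesh_from_points`) unless a template mesh is
    supplied.  Each round rigidly and non-rigidly registers every scan to
    the current template, averages the corresponded shapes, and uses the
    mean as the next template.  Scans failing registration are excluded and
    reported; fewer than 2 survivors abort the pipeline.
    """
    if len(scans) < 2:
        raise InvalidInputError("bootstrapping needs at least 2 scans")
    if rounds < 1:
        raise InvalidConfigError("rounds must be >= 1")
    rng = np.random.default_rng(seed)

    if template is None:
        pick = int(rng.integers(len(scans)))
        template = mesh_from_points(scans[pick].points, target_size=template_size, seed=seed)

    active = list(range(len(scans)))
    failures: list[tuple[int, int, str]] = []
    shapes: list[CorrespondedShape] = []

    for rnd in range(rounds):
        shapes = []
        survivors = []
        for i in active:
            scan = scans[i]
            try:
                _, aligned = rigid_align_to_mesh(scan.points, template)
                shape = nonrigid_icp(
                    template, aligned, stiffness_schedule=stiffness_schedule, label=scan.label
                )
            except EarMorphError as exc:
                failures.append((i, rnd, str(exc)))
                continue
            shapes.append(shape)
            survivors.append(i)
        active = survivors
        if len(shapes) < 2:
            raise PipelineError(
                f"fewer than 2 scans survived registration in round {rnd} "
                f"({len(failures)} failures)"
            )
        # Procrustes-align the corresponded set before averaging so residual
        # per-scan pose error does not leak into the template or, later,
        # into the shape model as rotation-like variance
        shapes = procrustes_align(shapes)
        mean_vec = np.mean([s.vector for s in shapes], axis=0)
        mean_pts = CorrespondedShape(mean_vec, template.topology_id).to_points()
        template = template.with_vertices(mean_pts)

    return BootstrapResult(template=template, shapes=shapes, failures=failures)
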