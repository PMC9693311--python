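"""You-Morph-Once (YMO) fitting: one registration per scan, then parameter-space matching.

Instead of registering a probe against every gallery scan, the query cloud
is registered once against the deforming morphable model.  Each iteration
interleaves a rigid step and a shape step:

* rigid — the current model vertices are matched into the query by a k-d
  tree, correspondences beyond ``th = d̄ + 2σd`` are rejected, and the query
  is moved onto the model's tangent planes (one point-to-plane Gauss-Newton
  step).  Point-to-plane is used because point-to-point estimation slides
  tangentially on smooth surfaces and lets pose absorb shape.
* shape — every model vertex takes the mean of its ``match_k`` nearest
  query points as its matched datum (averaging suppresses sampling noise);
  outlier vertices keep their current position.  The re-ordered query
  ``q_r`` then updates the shape parameters by the regularized least squares

      α_i = argmin ‖ (μ + U α) − q_r ‖² + λ ‖ α − α_{i−1} ‖² ,

  whose closed form under an orthonormal basis is
  ``α = (Uᵀ(q_r − μ) + λ α_prev) / (1 + λ)``.

Pose initialization is multi-start: five deterministic coarse candidates
(centroid shift + four proper principal-axis alignments) are each refined
rigidly against the mean and run through the full loop; the result with the
lowest final inlier RMS wins.  The resulting α is the biometric signature
compared against the gallery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .errors import (
    DegenerateRegistrationError,
    EarMorphError,
    FittingError,
    InvalidConfigError,
    InvalidInputError,
)
from .geometry import PointCloud, RigidTransform, estimate_rigid, estimate_rigid_point_to_plane
from .model import MorphableModel, ShapeParameters, synthesize
from .registration import (
    CorrespondedShape,
    _coarse_init_candidates,
    _inplane_spins,
    _symmetric_nn_score,
    vertex_normals,
)


def _rotation_angle_deg(R: np.ndarray) -> float:
    return float(np.degrees(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0))))

__all__ = ["FitConfig", "FitResult", "regularized_alpha_update", "fit", "enroll"]


@dataclass(frozen=True)
class FitConfig:
    """Tunables of the YMO loop.

    lambda_stiffness : λ, weight of the step-to-step shape regularizer (0.6).
    eta : η, convergence tolerance on the residual (1e−5; millimetres under
        the default RMS convention).
    max_iter : iteration cap per start.
    verify_threshold : distance threshold for accept/reject decisions (0.62).
    residual : ``"rms"`` (root-mean-square vertex distance between the
        synthesized shape and the registered, re-ordered query, over inlier
        vertices) or ``"spearman"`` (Spearman dissimilarity of the two
        stacked coordinate vectors).
    match_k : nearest query points averaged into each vertex's matched datum.
    multi_start : try all coarse pose candidates (robust, ~5× cost) instead
        of only the best-scoring one.
    prealign_iters : rigid-only iterations against the mean before the loop.
    patience : iterations without an η-improvement before stopping at the
        best residual seen.
    """

    lambda_stiffness: float = 0.6
    eta: float = 1e-5
    max_iter: int = 100
    verify_threshold: float = 0.62
    residual: str = "rms"
    match_k: int = 5
    multi_start: bool = True
    prealign_iters: int = 25
    patience: int = 20
    inplane_grid_deg: tuple[float, ...] = (-15.0, 0.0, 15.0)
    symmetric_match: bool = False

    def __post_init__(self):
        if self.lambda_stiffness < 0:
            raise InvalidConfigError("lambda_stiffness must be >= 0")
        if self.eta <= 0:
            raise InvalidConfigError("eta must be > 0")
        if self.max_iter < 1:
            raise InvalidConfigError("max_iter must be >= 1")
        if self.residual not in ("rms", "spearman"):
            raise InvalidConfigError("residual must be 'rms' or 'spearman'")
        if self.match_k < 1:
            raise InvalidConfigError("match_k must be >= 1")


@dataclass
class FitResult:
    """Outcome of one YMO fit.

    ``converged`` is true when the final residual fell to ≤ η or when it
    stopped improving by more than η for a few consecutive iterations (on
    noisy scans the residual plateaus at the sensor-noise floor rather than
    reaching η itself); the active convention is recorded in
    ``residual_convention``.
    """

    alpha: ShapeParameters
    transform: RigidTransform
    residual_trace: list[float]
    iterations: int
    converged: bool
    residual_convention: str = "rms-or-improvement<=eta"
    inlier_fraction: float = 1.0
    final_rms: float = float("nan")


def regularized_alpha_update(
    model: MorphableModel,
    q_registered: CorrespondedShape | np.ndarray,
    alpha_prev: ShapeParameters | np.ndarray,
    lambda_stiffness: float,
) -> np.ndarray:
    """Closed-form minimizer of ‖μ + Uα − q‖² + λ‖α − α_prev‖².

    With orthonormal U the normal equations
    ``(UᵀU + λI) α = Uᵀ(q − μ) + λ α_prev`` collapse to
    ``α = (Uᵀ(q − μ) + λ α_prev) / (1 + λ)``.
    """
    if lambda_stiffness < 0:
        raise InvalidConfigError("lambda_stiffness must be >= 0")
    q = q_registered.vector if isinstance(q_registered, CorrespondedShape) else np.asarray(q_registered, dtype=float)
    a_prev = alpha_prev.alpha if isinstance(alpha_prev, ShapeParameters) else np.asarray(alpha_prev, dtype=float)
    if q.size != model.mean.size:
        raise InvalidInputError("query vector length does not match the model")
    if a_prev.size != model.d:
        raise InvalidInputError("alpha_prev length does not match the model")
    proj = model.components.T @ (q - model.mean)
    return (proj + lambda_stiffness * a_prev) / (1.0 + lambda_stiffness)


def _spearman_dissimilarity(x: np.ndarray, y: np.ndarray) -> float:
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        return 0.0
    return float(1.0 - (rx @ ry) / denom)


def _rigid_step(em_pts, em_normals, q_cur, use_planes):
    """One rigid step moving the query toward the current model shape."""
    dists, idx = cKDTree(q_cur).query(em_pts)
    th = dists.mean() + 2.0 * dists.std()
    inl = dists <= th
    if inl.sum() < 3:
        raise DegenerateRegistrationError("fewer than 3 inlier correspondences")
    if use_planes:
        return estimate_rigid_point_to_plane(q_cur[idx[inl]], em_pts[inl], em_normals[inl])
    return estimate_rigid(q_cur[idx[inl]], em_pts[inl])


def _prealign(model, q_pts, T0, cfg, faces):
    """Rigid-only refinement of one coarse pose candidate against the mean."""
    mu_pts = model.mean_points()
    use_planes = faces is not None
    q_cur = T0.apply(q_pts)
    T = T0
    mu_normals = vertex_normals(mu_pts, faces) if use_planes else None
    for _ in range(cfg.prealign_iters):
        step = _rigid_step(mu_pts, mu_normals, q_cur, use_planes)
        q_cur = step.apply(q_cur)
        T = step.compose(T)
    return T


def _run_loop(model, q_pts, T0, cfg, faces, prealigned: bool = False):
    """The YMO loop from one pose initializer; returns a candidate result."""
    mu_pts = model.mean_points()
    use_planes = faces is not None
    T = T0 if prealigned else _prealign(model, q_pts, T0, cfg, faces)
    q_cur = T.apply(q_pts)

    alpha = np.zeros(model.d)
    em_pts = mu_pts.copy()  # EM_0 = μ
    trace: list[float] = []
    converged = False
    inlier_frac = 1.0
    best_e = np.inf
    best_state = None
    stall = 0

    it = 0
    for it in range(1, cfg.max_iter + 1):
        em_normals = vertex_normals(em_pts, faces) if use_planes else None
        try:
            step = _rigid_step(em_pts, em_normals, q_cur, use_planes)
        except DegenerateRegistrationError as exc:
            raise FittingError(str(exc), iteration=it) from exc
        q_cur = step.apply(q_cur)
        T = step.compose(T)

        tree = cKDTree(q_cur)
        # density-adaptive averaging: only average as many query points per
        # vertex as the sampling density supports, else sparse queries are
        # over-smoothed (k collapses to 1 when the query is no denser than
        # the model vertices)
        k = min(cfg.match_k, max(1, q_cur.shape[0] // em_pts.shape[0]), q_cur.shape[0])
        dists, idx = tree.query(em_pts, k=k)
        if k == 1:
            dists, idx = dists[:, None], idx[:, None]
        if cfg.symmetric_match:
            # also let every query point claim its nearest vertex, so query
            # regions the current fit leaves unexplained still exert pull
            d_rev, v_rev = cKDTree(em_pts).query(q_cur)
            th_rev = d_rev.mean() + 2.0 * d_rev.std()
            keep = d_rev <= th_rev
            sums = np.zeros_like(em_pts)
            counts = np.zeros(em_pts.shape[0])
            np.add.at(sums, v_rev[keep], q_cur[keep])
            np.add.at(counts, v_rev[keep], 1.0)
            fwd_sum = q_cur[idx].sum(axis=1)
            total = counts + k
            match = (fwd_sum + sums) / total[:, None]
        else:
            match = q_cur[idx].mean(axis=1)
        d0 = dists[:, 0]
        th = d0.mean() + 2.0 * d0.std()
        inl = d0 <= th
        if inl.sum() < 3:
            raise FittingError("degenerate correspondence: fewer than 3 inliers", iteration=it)
        inlier_frac = float(inl.mean())

        # re-ordered query; outlier vertices keep the current model position
        # so they contribute nothing to the α update
        qer_pts = em_pts.copy()
        qer_pts[inl] = match[inl]
        qer = CorrespondedShape.from_points(qer_pts, model.topology_id)

        alpha = regularized_alpha_update(model, qer, alpha, cfg.lambda_stiffness)
        qm = synthesize(model, alpha)
        em_pts = qm.to_points()

        if cfg.residual == "rms":
            diff = em_pts[inl] - qer_pts[inl]
            e_i = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
        else:
            e_i = _spearman_dissimilarity(qm.vector, qer.vector)
        trace.append(e_i)

        # convergence: residual ≤ η, or residual change ≤ η between
        # successive iterations (noisy scans plateau at the sensor-noise
        # floor instead of reaching η itself); an oscillating residual that
        # never settles is cut off after `patience` iterations without an
        # η-improvement, restoring the best state seen
        if e_i < best_e - cfg.eta:
            best_e = e_i
            best_state = (alpha.copy(), T, em_pts.copy(), q_cur.copy())
            stall = 0
        else:
            stall += 1
        if e_i <= cfg.eta or (len(trace) >= 2 and abs(trace[-2] - e_i) <= cfg.eta):
            converged = True
            break
        if stall >= cfg.patience:
            converged = True
            alpha, T, em_pts, q_cur = best_state
            break

    d_fin, _ = cKDTree(q_cur).query(em_pts)
    th = d_fin.mean() + 2.0 * d_fin.std()
    final_rms = float(np.sqrt(np.mean(d_fin[d_fin <= th] ** 2)))
    return alpha, T, trace, it, converged, inlier_frac, final_rms, final_rms


def fit(model: MorphableModel, query: PointCloud | np.ndarray, config: FitConfig | None = None) -> FitResult:
    """Fit the morphable model to a query scan with the YMO loop.

    The query may be in an arbitrary rigid pose; deterministic coarse
    initializers are refined as described in the module docstring.  When the
    model carries no faces the rigid steps fall back to point-to-point
    (Kabsch) estimation.  Non-convergence is reported in the result, not
    raised.
    """
    cfg = config or FitConfig()
    q_pts = query.points if isinstance(query, PointCloud) else np.asarray(query, dtype=float)
    if q_pts.shape[0] < 4:
        raise InvalidInputError("query scan too small to fit")

    mu_pts = model.mean_points()
    cands = _coarse_init_candidates(q_pts, mu_pts)
    if not cfg.multi_start:
        cands = [min(cands, key=lambda c: _symmetric_nn_score(c.apply(q_pts), mu_pts))]
    else:
        # widen the search with in-plane rotations about the mean's normal
        # axis: alignment against the mean has nearby local minima that a
        # single start can fall into
        cands = [spin.compose(T0) for T0 in cands
                 for spin in _inplane_spins(mu_pts, cfg.inplane_grid_deg)]

    # prealign every start rigidly (cheap), then run the full loop only once
    # per distinct pose basin; the basin whose fit explains the query best
    # (lowest final trimmed RMS) wins
    poses: list[RigidTransform] = []
    last_err: EarMorphError | None = None
    for T0 in cands:
        try:
            T = _prealign(model, q_pts, T0, cfg, model.faces)
        except (FittingError, DegenerateRegistrationError) as exc:
            last_err = exc if isinstance(exc, FittingError) else FittingError(str(exc))
            continue
        if all(_rotation_angle_deg(T.rotation @ P.rotation.T) > 3.0 for P in poses):
            poses.append(T)

    best = None
    for T in poses:
        try:
            result = _run_loop(model, q_pts, T, cfg, model.faces, prealigned=True)
        except FittingError as exc:
            last_err = exc
            continue
        if best is None or result[7] < best[7]:
            best = result
    if best is None:
        raise last_err if last_err is not None else FittingError("all pose starts failed")

    alpha, T, trace, it, converged, inlier_frac, final_rms, _ = best
    return FitResult(
        alpha=ShapeParameters(alpha, model.model_hash, label=getattr(query, "label", None)),
        transform=T,
        residual_trace=trace,
        iterations=it,
        converged=converged,
        residual_convention=cfg.residual + "-or-improvement<=eta",
        inlier_fraction=inlier_frac,
        final_rms=final_rms,
    )


def enroll(
    model: MorphableModel,
    scans: list[PointCloud],
    config: FitConfig | None = None,
):
    """Fit every gallery scan and collect the parameters into a Gallery.

    Exactly one scan per subject label is expected; duplicate labels raise.
    Scans whose fit fails are excluded and reported in ``gallery.diagnostics``.
    """
    from .recognition import Gallery  # local import to avoid a cycle

    cfg = config or FitConfig()
    labels = [s.label for s in scans]
    if any(l is None for l in labels):
        raise InvalidInputError("every gallery scan needs a subject label")
    if len(set(labels)) != len(labels):
        raise InvalidInputError("duplicate subject labels in the gallery scans")

    entries: dict[str, ShapeParameters] = {}
    diagnostics: dict[str, dict] = {}
    for scan in scans:
        try:
            res = fit(model, scan, cfg)
        except EarMorphError as exc:
            diagnostics[scan.label] = {"status": "failed", "error": str(exc)}
            continue
        entries[scan.label] = ShapeParameters(res.alpha.alpha, model.model_hash, label=scan.label)
        diagnostics[scan.label] = {
            "status": "ok",
            "iterations": res.iterations,
            "converged": res.converged,
            "final_residual": res.residual_trace[-1] if res.residual_trace else float("nan"),
        }
    return Gallery(entries=entries, model_hash=model.model_hash, diagnostics=diagnostics)
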