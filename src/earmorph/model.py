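"""The 3D morphable ear model (3DMEM): a PCA shape space over corresponded shapes.

Given N shapes in dense correspondence the model is

    M(α) = μ + U α ,

with μ the mean shape, U an orthonormal basis of principal shape modes
(left singular vectors of the centered data matrix) and α the shape
parameters.  Projection is the adjoint, α = Uᵀ(m − μ).  Eigenvalues are
stored as per-shape variances s²/(N−1) of the singular values s.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .errors import CorrespondenceError, InvalidConfigError, InvalidInputError
from .registration import BootstrapResult, CorrespondedShape, bootstrap_correspondence

__all__ = [
    "MorphableModel",
    "ShapeParameters",
    "mean_shape",
    "build_model",
    "build_model_from_scans",
    "synthesize",
    "project",
]


@dataclass(frozen=True)
class MorphableModel:
    """Mean shape, orthonormal principal components and eigenvalue spectrum.

    ``components`` has shape (3n, d) with orthonormal columns; eigenvalues
    (per-shape variances along each component) are sorted descending.
    ``faces`` carries the template triangulation when available so the model
    can be rendered or sampled as a surface.
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    topology_id: str
    faces: np.ndarray | None = None
    loadings: np.ndarray | None = None

    def __post_init__(self):
        mean = np.ascontiguousarray(np.asarray(self.mean, dtype=float).reshape(-1))
        comp = np.ascontiguousarray(np.asarray(self.components, dtype=float))
        ev = np.ascontiguousarray(np.asarray(self.eigenvalues, dtype=float).reshape(-1))
        if comp.ndim != 2 or comp.shape[0] != mean.size:
            raise InvalidInputError("components must be (3n, d) matching the mean length")
        if ev.size != comp.shape[1]:
            raise InvalidInputError("one eigenvalue per component required")
        if np.any(ev < -1e-12):
            raise InvalidInputError("eigenvalues must be nonnegative")
        if np.any(np.diff(ev) > 1e-10):
            raise InvalidInputError("eigenvalues must be sorted descending")
        if not np.allclose(comp.T @ comp, np.eye(comp.shape[1]), atol=1e-8):
            raise InvalidInputError("component columns must be orthonormal")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "components", comp)
        object.__setattr__(self, "eigenvalues", np.maximum(ev, 0.0))
        if self.faces is not None:
            object.__setattr__(
                self, "faces", np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
            )

    @property
    def d(self) -> int:
        return self.components.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.mean.size // 3

    @property
    def model_hash(self) -> str:
        """Stable identity of the model's numerical content."""
        h = hashlib.sha256()
        for arr in (self.mean, self.components, self.eigenvalues):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(self.topology_id.encode())
        return h.hexdigest()[:16]

    def mean_points(self) -> np.ndarray:
        return CorrespondedShape(self.mean, self.topology_id).to_points()


@dataclass(frozen=True)
class ShapeParameters:
    """PCA coefficients α of one fitted or enrolled shape — the biometric signature."""

    alpha: np.ndarray
    model_ref: str
    label: str | None = None

    def __post_init__(self):
        a = np.ascontiguousarray(np.asarray(self.alpha, dtype=float).reshape(-1))
        if not np.all(np.isfinite(a)):
            raise InvalidInputError("shape parameters must be finite")
        object.__setattr__(self, "alpha", a)

    def __len__(self) -> int:
        return self.alpha.size


def _check_topology(shapes: list[CorrespondedShape]):
    if not shapes:
        raise InvalidInputError("need at least one shape")
    tid = shapes[0].topology_id
    if any(s.topology_id != tid for s in shapes):
        raise CorrespondenceError("shapes do not share a topology_id")
    return tid


def mean_shape(shapes: list[CorrespondedShape]) -> CorrespondedShape:
    """Elementwise arithmetic mean of corresponded shape vectors."""
    tid = _check_topology(shapes)
    return CorrespondedShape(np.mean([s.vector for s in shapes], axis=0), tid)


def build_model(
    shapes: list[CorrespondedShape],
    d: int | None = None,
    variance_cutoff: float = 0.98,
    faces: np.ndarray | None = None,
) -> MorphableModel:
    """Build the morphable model from corresponded shapes by SVD.

    The data matrix Γ stacks shape vectors as columns; the mean is
    subtracted from every column and the top-``d`` left singular vectors are
    retained.  When ``d`` is omitted it defaults to the smallest number of
    components explaining ``variance_cutoff`` of the total variance, capped
    at N − 1.
    """
    tid = _check_topology(shapes)
    if len(shapes) < 2:
        raise InvalidInputError("model building needs at least 2 shapes")
    gamma = np.column_stack([s.vector for s in shapes])  # (3n, N)
    N = gamma.shape[1]
    mu = gamma.mean(axis=1)
    R = gamma - mu[:, None]
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    ev = s**2 / (N - 1)

    max_d = min(N - 1, gamma.shape[0])
    if d is None:
        total = ev[:max_d].sum()
        if total <= 0:
            d = 1
        else:
            frac = np.cumsum(ev[:max_d]) / total
            d = int(np.searchsorted(frac, variance_cutoff) + 1)
        d = min(d, max_d)
    if not (1 <= d <= max_d):
        raise InvalidConfigError(f"d must be in [1, {max_d}], got {d}")

    return MorphableModel(
        mean=mu,
        components=U[:, :d],
        eigenvalues=ev[:d],
        topology_id=tid,
        faces=faces,
        loadings=Vt[:d].T,
    )


def build_model_from_scans(
    scans,
    rounds: int = 2,
    seed: int = 0,
    template=None,
    template_size: int = 250,
    d: int | None = None,
    variance_cutoff: float = 0.98,
) -> tuple[MorphableModel, BootstrapResult]:
    """End-to-end model construction: bootstrap correspondence, then PCA.

    Convenience wrapper used by the CLI and the evaluation harness; returns
    the model together with the bootstrap result (template, corresponded
    shapes, failures).
    """
    boot = bootstrap_correspondence(
        scans, rounds=rounds, seed=seed, template=template, template_size=template_size
    )
    mdl = build_model(boot.shapes, d=d, variance_cutoff=variance_cutoff, faces=boot.template.faces)
    return mdl, boot


def synthesize(model: MorphableModel, params: ShapeParameters | np.ndarray) -> CorrespondedShape:
    """Generate the shape μ + U α for given parameters."""
    alpha = params.alpha if isinstance(params, ShapeParameters) else np.asarray(params, dtype=float)
    if isinstance(params, ShapeParameters) and params.model_ref != model.model_hash:
        raise InvalidInputError("shape parameters were computed against a different model")
    if alpha.size != model.d:
        raise InvalidInputError(f"expected {model.d} parameters, got {alpha.size}")
    return CorrespondedShape(model.mean + model.components @ alpha, model.topology_id)


def project(model: MorphableModel, shape: CorrespondedShape, label: str | None = None) -> ShapeParameters:
    """Shape parameters α = Uᵀ(m − μ) of a corresponded shape."""
    if shape.topology_id != model.topology_id:
        raise CorrespondenceError("shape topology does not match the model")
    alpha = model.components.T @ (shape.vector - model.mean)
    return ShapeParameters(alpha, model.model_hash, label=label if label is not None else shape.label)
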