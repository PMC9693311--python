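"""Shape-parameter distances, gallery matching and biometric evaluation.

Probes and gallery entries are compared purely in shape-parameter space.
Nine dissimilarities are supported (metric codes in parentheses): Euclidean
(E), standardized Euclidean (SE), Mahalanobis (MH), Minkowski (MN), city
block (CT), Chebyshev (CH), cosine (CS), correlation (CR) and Spearman
(SP — the correlation distance of coordinate-wise rank vectors, average
ranks for ties).  Closed-set identification is evaluated by the cumulative
match characteristic (CMC) curve; verification by FAR/FRR sweeps, the ROC,
and verification accuracy 100 − (FAR + FRR)/2 maximized over thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
from scipy.spatial import distance as ssd
from scipy.stats import rankdata

from .errors import (
    IncompatibilityError,
    InvalidInputError,
    NumericalError,
    UndefinedDistanceError,
)
from .model import ShapeParameters

__all__ = [
    "METRICS",
    "Gallery",
    "MatchResult",
    "EvalReport",
    "param_distance",
    "gallery_covariance",
    "gallery_scaling",
    "identify",
    "verify",
    "cmc_curve",
    "verification_metrics",
    "evaluate",
]

METRICS = ("E", "SE", "MH", "MN", "CT", "CH", "CS", "CR", "SP")

#: Default verification threshold on the SP dissimilarity.
DEFAULT_THRESHOLD = 0.62


@dataclass
class Gallery:
    """Subject-labeled shape parameters: the enrollment database."""

    entries: dict[str, ShapeParameters]
    model_hash: str
    created: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        lengths = {len(p) for p in self.entries.values()}
        if len(lengths) > 1:
            raise InvalidInputError("all gallery parameter vectors must have equal length")
        for label, p in self.entries.items():
            if p.model_ref != self.model_hash:
                raise IncompatibilityError(
                    f"gallery entry {label!r} was fitted against a different model"
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return sorted(self.entries)

    def alpha_matrix(self) -> np.ndarray:
        """Gallery parameters stacked row-wise in sorted-label order."""
        return np.vstack([self.entries[l].alpha for l in self.labels])


@dataclass
class MatchResult:
    """Ranked gallery distances for one probe, plus the accept decision."""

    ranking: list[tuple[str, float]]
    metric: str
    accepted: bool
    threshold_used: float

    @property
    def best_label(self) -> str:
        return self.ranking[0][0]

    @property
    def best_distance(self) -> float:
        return self.ranking[0][1]


@dataclass
class EvalReport:
    """CMC, FAR/FRR sweep, ROC points and verification accuracy."""

    cmc: dict[int, float]
    rank1: float
    thresholds: np.ndarray
    far_curve: np.ndarray
    frr_curve: np.ndarray
    roc: np.ndarray  # columns (FAR %, 100 − FRR %)
    verification_accuracy: float
    best_threshold: float
    metric: str = "SP"


def _vec(x) -> np.ndarray:
    return x.alpha if isinstance(x, ShapeParameters) else np.asarray(x, dtype=float).reshape(-1)


def param_distance(a, b, metric: str = "SP", *, scaling=None, covariance=None, p: float = 3) -> float:
    """Dissimilarity between two shape-parameter vectors.

    ``scaling`` (per-dimension standard deviations) is required for SE,
    ``covariance`` for MH, and ``p`` sets the Minkowski order (default 3;
    p = 1 and p = 2 duplicate CT and E).  CS/CR/SP are dissimilarities, not
    metrics: symmetric and zero at identity but without the triangle
    inequality.
    """
    x, y = _vec(a), _vec(b)
    if x.size != y.size:
        raise InvalidInputError("parameter vectors must have equal length")
    if metric == "E":
        return float(ssd.euclidean(x, y))
    if metric == "SE":
        if scaling is None:
            raise InvalidInputError("SE requires a scaling vector of per-dimension sd")
        s = np.asarray(scaling, dtype=float).reshape(-1)
        if s.size != x.size or np.any(s <= 0):
            raise InvalidInputError("scaling must be positive and match the vector length")
        return float(ssd.seuclidean(x, y, s**2))
    if metric == "MH":
        if covariance is None:
            raise InvalidInputError("MH requires a covariance matrix")
        C = np.asarray(covariance, dtype=float)
        try:
            VI = np.linalg.inv(C)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"Mahalanobis: singular covariance ({exc})") from exc
        d2 = float((x - y) @ VI @ (x - y))
        if not np.isfinite(d2) or d2 < -1e-8:
            raise NumericalError("Mahalanobis: covariance is not positive definite")
        return float(np.sqrt(max(d2, 0.0)))
    if metric == "MN":
        return float(ssd.minkowski(x, y, p=p))
    if metric == "CT":
        return float(ssd.cityblock(x, y))
    if metric == "CH":
        return float(ssd.chebyshev(x, y))
    if metric == "CS":
        if np.linalg.norm(x) == 0 or np.linalg.norm(y) == 0:
            raise UndefinedDistanceError("cosine distance undefined for a zero vector")
        return float(ssd.cosine(x, y))
    if metric == "CR":
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            raise UndefinedDistanceError("correlation distance undefined for a constant vector")
        return float(ssd.correlation(x, y))
    if metric == "SP":
        rx, ry = rankdata(x), rankdata(y)
        if np.allclose(rx, rx[0]) or np.allclose(ry, ry[0]):
            raise UndefinedDistanceError("Spearman distance undefined for a constant vector")
        return float(ssd.correlation(rx, ry))
    raise InvalidInputError(f"unknown metric {metric!r}; choose from {METRICS}")


def gallery_covariance(gallery: Gallery, shrinkage_cond: float = 1e6) -> np.ndarray:
    """Unbiased covariance of the gallery's α population.

    When ill-conditioned (condition number above ``shrinkage_cond``) the
    estimate is shrunk toward its diagonal until usable.
    """
    A = gallery.alpha_matrix()
    if A.shape[0] < 2:
        raise InvalidInputError("covariance needs at least 2 gallery entries")
    C = np.cov(A, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    diag = np.diag(np.diag(C))
    gamma = 0.0
    while gamma < 1.0:
        Cs = (1 - gamma) * C + gamma * diag
        if np.linalg.cond(Cs) < shrinkage_cond:
            return Cs
        gamma += 0.1
    return diag + 1e-12 * np.eye(C.shape[0])


def gallery_scaling(gallery: Gallery) -> np.ndarray:
    """Per-dimension standard deviation of the gallery's α population."""
    A = gallery.alpha_matrix()
    s = A.std(axis=0, ddof=1)
    if np.any(s <= 0):
        raise InvalidInputError("gallery has a zero-variance parameter dimension")
    return s


def _metric_aux(gallery: Gallery, metric: str, scaling, covariance):
    if metric == "SE" and scaling is None:
        scaling = gallery_scaling(gallery)
    if metric == "MH" and covariance is None:
        covariance = gallery_covariance(gallery)
    return scaling, covariance


def identify(
    gallery: Gallery,
    probe: ShapeParameters,
    metric: str = "SP",
    threshold: float = DEFAULT_THRESHOLD,
    *,
    scaling=None,
    covariance=None,
    p: float = 3,
) -> MatchResult:
    """Rank all gallery entries by distance to the probe (closed set).

    Distances are sorted ascending with ties broken by label order; the
    probe is accepted when the minimum distance is strictly below the
    threshold.
    """
    if len(gallery) == 0:
        raise InvalidInputError("cannot identify against an empty gallery")
    if probe.model_ref != gallery.model_hash:
        raise IncompatibilityError("probe parameters come from a different model than the gallery")
    scaling, covariance = _metric_aux(gallery, metric, scaling, covariance)
    pairs = [
        (label, param_distance(gallery.entries[label], probe, metric, scaling=scaling, covariance=covariance, p=p))
        for label in gallery.labels
    ]
    pairs.sort(key=lambda lp: (lp[1], lp[0]))
    return MatchResult(
        ranking=pairs,
        metric=metric,
        accepted=pairs[0][1] < threshold,
        threshold_used=threshold,
    )


def verify(
    gallery_entry: ShapeParameters,
    probe: ShapeParameters,
    threshold: float = DEFAULT_THRESHOLD,
    metric: str = "SP",
    *,
    scaling=None,
    covariance=None,
    p: float = 3,
) -> tuple[bool, float]:
    """One-to-one verification: accept iff distance < threshold (strict)."""
    if gallery_entry.model_ref != probe.model_ref:
        raise IncompatibilityError("cannot verify parameters from different models")
    d = param_distance(gallery_entry, probe, metric, scaling=scaling, covariance=covariance, p=p)
    return (d < threshold, d)


def cmc_curve(
    gallery: Gallery,
    probes: list[ShapeParameters],
    metric: str = "SP",
    max_rank: int | None = None,
    *,
    scaling=None,
    covariance=None,
    p: float = 3,
) -> dict[int, float]:
    """Cumulative match characteristic: % of probes whose true subject
    appears within the top r ranks, for r = 1..max_rank (closed set)."""
    if not probes:
        raise InvalidInputError("no probes supplied")
    for pr in probes:
        if pr.label is None:
            raise InvalidInputError("every probe needs a subject label")
        if pr.label not in gallery.entries:
            raise InvalidInputError(f"probe label {pr.label!r} is not enrolled (closed-set only)")
    max_rank = min(max_rank or len(gallery), len(gallery))
    scaling, covariance = _metric_aux(gallery, metric, scaling, covariance)
    ranks = []
    for pr in probes:
        res = identify(gallery, pr, metric, scaling=scaling, covariance=covariance, p=p)
        labels = [l for l, _ in res.ranking]
        ranks.append(labels.index(pr.label) + 1)
    ranks = np.asarray(ranks)
    return {r: float(100.0 * np.mean(ranks <= r)) for r in range(1, max_rank + 1)}


def verification_metrics(
    genuine_distances,
    impostor_distances,
    thresholds=None,
    metric: str = "SP",
) -> EvalReport:
    """FAR/FRR sweep, ROC and verification accuracy 100 − (FAR + FRR)/2.

    At a threshold t, FAR is the % of impostor distances strictly below t
    (falsely accepted) and FRR the % of genuine distances at or above t
    (falsely rejected) — the same strict-acceptance rule as :func:`verify`.
    ``best_threshold`` maximizes the verification accuracy (lowest t on ties).
    """
    gen = np.asarray(genuine_distances, dtype=float).reshape(-1)
    imp = np.asarray(impostor_distances, dtype=float).reshape(-1)
    if gen.size == 0 or imp.size == 0:
        raise InvalidInputError("both genuine and impostor score sets must be non-empty")
    if thresholds is None:
        allv = np.concatenate([gen, imp])
        lo, hi = allv.min(), allv.max()
        pad = 1e-9 + 0.05 * (hi - lo)
        thresholds = np.linspace(lo - pad, hi + pad, 512)
    thresholds = np.asarray(thresholds, dtype=float).reshape(-1)

    far = np.array([100.0 * np.mean(imp < t) for t in thresholds])
    frr = np.array([100.0 * np.mean(gen >= t) for t in thresholds])
    acc = 100.0 - (far + frr) / 2.0
    best = int(np.argmax(acc))
    roc = np.column_stack([far, 100.0 - frr])
    return EvalReport(
        cmc={},
        rank1=float("nan"),
        thresholds=thresholds,
        far_curve=far,
        frr_curve=frr,
        roc=roc,
        verification_accuracy=float(acc[best]),
        best_threshold=float(thresholds[best]),
        metric=metric,
    )


def evaluate(
    gallery: Gallery,
    probes: list[ShapeParameters],
    metric: str = "SP",
    max_rank: int | None = None,
    thresholds=None,
    *,
    scaling=None,
    covariance=None,
    p: float = 3,
) -> EvalReport:
    """Full closed-set evaluation: CMC plus verification sweep.

    Genuine scores are probe-to-own-gallery-entry distances; impostor
    scores are probe-to-every-other-entry distances.
    """
    cmc = cmc_curve(gallery, probes, metric, max_rank, scaling=scaling, covariance=covariance, p=p)
    scaling, covariance = _metric_aux(gallery, metric, scaling, covariance)
    genuine, impostor = [], []
    for pr in probes:
        for label in gallery.labels:
            d = param_distance(gallery.entries[label], pr, metric, scaling=scaling, covariance=covariance, p=p)
            (genuine if label == pr.label else impostor).append(d)
    report = verification_metrics(genuine, impostor, thresholds, metric=metric)
    report.cmc = cmc
    report.rank1 = cmc[1]
    return report
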