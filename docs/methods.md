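# Methods

`earmorph` implements shape-based identification of people from 3D ear
surface scans.  The pipeline has four stages: dense correspondence by
iterative template registration, a PCA shape space (the 3D morphable ear
model, 3DMEM), a one-registration fitting loop ("You Morph Once", YMO) that
converts any scan into a low-dimensional shape-parameter vector, and
closed-set identification / verification by distances between those
vectors.  This note records the model assumptions, the numerical choices,
and what the synthetic benchmark does and does not demonstrate.

## Shape model

Every corresponded surface is a vector `v = [x1..xn, y1..yn, z1..zn]` over
a shared template topology of `n` vertices (millimetres throughout).  Given
`N` corresponded shapes the model is

    M(α) = μ + U α,

with `μ` the arithmetic mean shape, `U` the top `d` left singular vectors
of the column-centered data matrix, and eigenvalues stored as per-shape
variances `s²/(N−1)`.  Projection is `α = Uᵀ(m − μ)`.  The SVD is taken on
the centered data matrix directly (never the 3n×3n covariance) for
stability when `3n ≫ N`.  `d` defaults to the smallest dimension explaining
98 % of the total variance, capped at `N − 1`; both `d` and the cutoff are
configurable.

One subtlety the implementation guards: the mean is the sum *divided by N*
(a plain arithmetic mean).  Without the 1/N the subsequent centering step
would not produce zero-mean columns and the PCA would be meaningless.

## Dense correspondence

A template mesh is morphed onto every scan:

1. **Rigid pre-alignment** (`rigid_align_to_mesh`): multi-start — centroid
   shift plus proper principal-axis alignments, each combined with a small
   grid of in-plane spins (±20°, ±10°, 0°) — refined by point-to-plane ICP
   (template vertices matched into the scan by a k-d tree, outliers
   rejected at `th = d̄ + 2σd`, the scan moved onto the matched tangent
   planes), selected by symmetric mean nearest-neighbor distance.
   Alignment of a shallow anatomical patch against a template has nearby
   local minima; a single start occasionally lands ~10–20° off, which is
   the dominant failure mode of the whole pipeline, so the multi-start here
   is not an optimization nicety but load-bearing.
   Principal-axis candidates rotating the scan by more than 75° are
   discarded: scans are assumed consistently oriented toward the sensor
   (the usual acquisition convention, stated as an input contract), and
   larger candidate rotations are mirror artifacts of the PCA sign
   ambiguity.
2. **Non-rigid ICP** (`nonrigid_icp`): optimal-step, locally affine
   regularized.  Each vertex carries an unknown 3×4 affine transform; per
   stiffness level the data term (vertex → mean of its k nearest scan
   points, k density-adaptive up to 5) and the edge-wise stiffness term are
   solved exactly as one sparse linear least-squares problem, with
   correspondences and `th`-outlier weights refreshed each inner iteration
   (≤ 20, or until mean vertex motion < 1e−4 of the bounding-box
   diagonal).  The default schedule is 8 geometric levels from 50 to 0.2
   with the skew weight γ = 1.
   The matched datum is projected onto the current vertex normal ("normal
   shooting"): sampling noise is tangentially random, so tangential vertex
   placement is left to the deterministic regularizer.  This halves the
   correspondence jitter between re-scans of the same surface, which
   otherwise dominates the shape model's noise tail.
3. **Bootstrapping** (`bootstrap_correspondence`): round 0 picks one scan
   (seeded) and triangulates it by planar Delaunay over its two principal
   axes (valid for patch-like surfaces; a user-supplied template mesh is
   also accepted), subsampled to 250 vertices by farthest-point sampling.
   Each round registers every scan, generalized-Procrustes-aligns the
   corresponded set (exact per-shape Kabsch to the evolving mean — residual
   per-scan pose error must not enter the model as rotation-like variance),
   averages, and re-templates.  Two rounds by default.  Scans that fail
   registration are excluded and reported; fewer than two survivors abort.

## The YMO fitting loop

Fitting a query cloud `QE` to the model alternates, per iteration:

* **rigid** — current model vertices matched into the query (k-d tree),
  outliers rejected at `th = d̄ + 2σd`, and the query moved into the model
  frame by one point-to-plane Gauss-Newton step.  Point-to-plane rather
  than point-to-point: on smooth surfaces point-to-point estimation slides
  tangentially and lets pose absorb shape, which empirically destroys
  parameter recovery.
* **shape** — the query is re-ordered by correspondence into `q_r` (each
  vertex takes the mean of its k nearest query points; outlier vertices
  keep their current position and thus exert no pull), and the parameters
  are updated by the regularized least squares

      α_i = argmin ‖(μ + U α) − q_r‖² + λ‖α − α_{i−1}‖²,
      closed form: α_i = (Uᵀ(q_r − μ) + λ α_{i−1}) / (1 + λ),

  with λ = 0.6 and α₀ = 0.

Pose is initialized by the same multi-start used in registration
(coarse candidates × in-plane grid, deduplicated after a rigid-only
prealignment of 25 iterations); the full loop runs once per distinct pose
basin and the fit with the lowest final trimmed RMS wins.

**Convergence.** The loop stops when the residual `e_i` (RMS vertex
distance between the synthesized shape and `q_r` over inlier vertices;
a Spearman-dissimilarity variant is available by configuration) reaches
η = 1e−5, when it changes by ≤ η between successive iterations, or — for
residuals that oscillate at the sensor-noise floor without settling — after
20 iterations without an η-improvement, restoring the best state seen.
All three count as converged and the convention is recorded in the result;
on noisy scans the residual plateaus at the noise floor and the literal
`e ≤ η` criterion alone would never fire.  `max_iter` defaults to 100.

Enrollment runs the same fit once per gallery scan (exactly one scan per
subject) and stores each α; identification is then a pure parameter-space
distance computation, independent of gallery size — the point of fitting
"once".

## Distance metrics and evaluation

Nine dissimilarities between parameter vectors: Euclidean, standardized
Euclidean (scaling = per-dimension sd of the gallery α population),
Mahalanobis (covariance estimated from the gallery, shrunk toward its
diagonal when its condition number exceeds 1e6), Minkowski (default order
p = 3; p = 1, 2 duplicate city block and Euclidean), city block, Chebyshev,
cosine, correlation, and Spearman (correlation distance of coordinate-wise
rank vectors, average ranks on ties).  Cosine/correlation/Spearman are
dissimilarities, not metrics — symmetric and zero at identity, no triangle
inequality.

Closed-set identification sorts gallery distances ascending (ties broken by
label) and reports CMC curves; verification accepts iff distance <
threshold (strictly; default 0.62), and the sweep defines FAR (% impostor
distances < t), FRR (% genuine distances ≥ t, the complementary boundary
so the sweep agrees with the accept rule), ROC, and verification accuracy
`100 − (FAR + FRR)/2` maximized over thresholds.

## Synthetic data: what it emulates, what it does not

Real 3D ear databases are license-restricted, so the benchmark population
is synthetic with fully known structure.

* **Base surface**: a procedural ear-like patch (≈35 × 55 mm): an
  elliptical dome with a rim ridge that is higher toward the top (helix
  analog), a concave bowl shifted low (concha), and two localized bumps
  (lobule, tragus).  The pronounced asymmetry rotationally locks rigid
  registration the way real ear anatomy does; a more symmetric patch makes
  pose and shape fundamentally harder to separate.
* **Identity**: 8 orthonormal deformation modes, each a smooth scalar field
  (low-order angular harmonics × radial powers × an asymmetric envelope)
  displacing vertices along the base normals.  Tangential displacement
  only re-parameterizes a surface without changing its geometry, so
  normal-displacement modes keep identity recoverable from surface
  measurements.  The scalar fields are orthogonalized against the six
  rigid-motion normal fields, making shape identifiable from closest-point
  data in the presence of unknown pose.  Coefficients are Gaussian with
  sds 15 → 5 mm (geometric across modes), i.e. ≈1 mm rms per-vertex shape
  variation — of the order of inter-individual ear shape differences at
  this patch scale.
* **Scans**: 1200 points uniformly by area, isotropic Gaussian sensor noise
  (default sd 1 % of the bounding-box diagonal ≈ 0.65 mm), a random rigid
  pose (±20° about a random axis, ±10 mm), optionally a contiguous
  occlusion patch (nearest-neighbor ball around a seeded point — the
  earring/hair analog) and far outlier points.  One scan per subject
  (seeded choice) is the gallery; the rest are probes.  Isotropic noise of
  sd σ projects onto a unit-norm mode with sd σ, so separability requires
  σ (mm) below the smallest between-subject sd; this is validated at
  generation time.
* **Not emulated**: scanner-specific noise structure (quantization,
  specular dropouts), non-rigid deformation of the ear itself (earrings
  pulling the lobule), demographic covariates, and the full depth relief of
  real ears (the patch is a height field; real conchas are deeper and lock
  pose more strongly).  Passing tests therefore demonstrate the machinery
  — correspondence, model building, fitting, evaluation — under controlled,
  favorable geometry; they do not certify accuracy on any real database.

The noise-robustness harness builds the model once from a noiseless
rendering of the population and re-generates gallery/probes at increasing
noise, isolating sensor-noise effects from model quality.

## Numerical choices and degeneracies

* `th = d̄ + 2σd` uses the population (ddof = 0) standard deviation over
  all correspondences of the current iteration; comparison is strict
  (`> th` is rejected).  Constant distances ⇒ σ = 0 ⇒ nothing rejected.
* Rigid estimation is closed-form Kabsch with a reflection guard; collinear
  or coincident point sets raise a degenerate-registration error, as does
  any correspondence set with fewer than 3 inliers.
* Nearest-neighbor ties are resolved by the k-d tree deterministically;
  exact ties between distinct target points are measure-zero for real scan
  data.
* The ridge parameter λ only damps the iteration path: the fixed point of
  the α update is the plain projection, so λ introduces no asymptotic bias.
* Model/gallery containers carry a SHA-256 content hash verified on load;
  galleries refuse to match probes fitted against a different model hash.

## Known limitations

* Template-based pairwise correspondence retains shape-correlated
  tangential sliding that groupwise methods would remove; it surfaces as a
  noise tail in the PCA spectrum and occasionally (a few percent of fits on
  the default synthetic population) lets a query settle in a pose-shape
  basin ~15° away whose residual ties the true one within sampling noise.
  When gallery and probe fits of one subject disagree on the basin, that
  subject's matches fail: noiseless closed-set rank-1 on the default
  population measures 95–100 % depending on the seed, not a guaranteed
  100 %.  Deeper, more distinctive geometry (as in real ears) separates the
  basins; so would groupwise correspondence, which is out of scope.
* Parameter recovery from sampled, noisy, posed scans has a floor: the
  median per-coefficient correlation between generating and fitted
  coefficients measures ≈ 0.985 at the default study conditions (1200
  points per scan, noise 1 % of the bounding-box diagonal, pose ±30°).
  The budget is dominated not by sensor noise (alone it would allow
  ≈ 0.997) but by the sampling-footpoint bias of closest-point
  correspondence — the matched datum is the nearest *sample*, not the
  true corresponding surface point.  Denser scans raise the ceiling.
  A further identifiability fact: a model learned through the registration
  pipeline contains tangential mode content that no surface measurement can
  recover (tangential displacement re-parameterizes a surface without
  changing it), capping recovery against such a model near 0.92 regardless
  of the fitter.
* On this benchmark the Spearman dissimilarity is *not* the strongest
  metric once sensor noise is present: with only ≈ 14 model dimensions, of
  which the trailing ones are registration-noise-dominated, coordinate
  ranks scramble easily (rank-1 85 % vs Chebyshev 97.5 % at 1 % noise).
  Rank-based comparison pays off for long, monotonically related feature
  vectors; for short PCA coefficient vectors magnitude-based metrics are
  more robust.
* Open-set identification, score normalization and multi-probe fusion are
  deliberately not implemented.
* The fit assumes the query is a plausible ear patch, oriented toward the
  sensor within ~75°; orientation normalization beyond that contract is the
  caller's responsibility.
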