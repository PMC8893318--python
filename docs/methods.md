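# Methods

`aneufuse` implements a multidimensional feature-fusion pipeline for
estimating the rupture risk of intracranial aneurysms from angiographic
volumes, segmentation masks and surface meshes, together with a synthetic
phantom generator that makes the whole pipeline testable without clinical
data. This note documents the models, the numerical choices and the
limitations.

## The feature model

Each case contributes a 136-column feature vector built from four groups:

| group | count | source |
|---|---|---|
| morphological | 25 | STL surface mesh |
| radiomics | 107 | volume + mask |
| deep | 2 | pluggable extractor + output transform |
| clinical | 2 | sex (female=0 / male=1), age (years) |

### Morphological features (25)

Five global quantities — oriented-bounding-box length/width/height (extents
of the vertex cloud along its covariance eigenvectors, sorted descending,
hence pose-invariant), surface area (summed triangle areas) and enclosed
volume (divergence-theorem signed-tetrahedron sum on a watertight,
consistently oriented mesh) — plus {max, min, mean, std} of five per-vertex
curvature scalars: principal curvatures κ₁ ≥ κ₂, Gaussian K = κ₁κ₂, mean
H = (κ₁+κ₂)/2 and curvedness C = √((κ₁²+κ₂²)/2). Curvedness is our choice
of fifth scalar to complete the 5 × 4 = 20 curvature statistics; it is a
standard rotation-invariant summary and its identity is visible in the
feature names so it can be swapped.

Discrete curvature uses the mixed-Voronoi scheme: K from the angle deficit
divided by the mixed area (so Gauss–Bonnet, Σ deficits = 4π, holds to
floating point on closed genus-0 meshes), H from the cotangent
Laplace–Beltrami mean-curvature vector, signed by the outward vertex normal
(sphere of radius r ⇒ H = +1/r). Because the two estimators are
independent, H² < K can occur pointwise on coarse meshes; the exported
field clamps the discriminant and re-derives K = κ₁κ₂ so the algebraic
identities hold exactly. Curvature statistics are unweighted over vertices
by default; an `area_weighted` flag switches the mean/std to
mixed-area-weighted moments.

### Radiomics features (107)

Preprocessing: trilinear resampling of the image to 0.5 × 0.5 × 0.5 mm³
(nearest-neighbour for the mask, which conserves mask volume — linear
interpolation plus thresholding was measured to inflate a cube mask by
~13%), grid anchored at the original origin with ceil(extent/0.5) voxels
per axis, then whole-image min–max rescaling to [0, 100]. Gray levels are
discretized with a fixed bin count (default 32) over the in-mask range:
after the [0, 100] rescale a fixed bin *width* of e.g. 25 would leave only
a handful of populated levels, so fixed count is both better conditioned
and the standard choice. A constant ROI collapses to a single level and is
handled by documented degenerate rules everywhere downstream.

The battery is 18 first-order + 14 shape + 24 GLCM + 16 GLRLM + 16 GLSZM +
5 NGTDM + 14 GLDM features, every formula implemented from its standard
definition (no external radiomics package). Conventions:

* GLCM/GLRLM: the 13 unique 3-D directions at distance 1, accumulated into
  one merged matrix before features are computed (per-direction averaging is
  available on the builders); GLCM symmetrized P + Pᵀ and normalized.
* GLSZM/GLDM: 26-connectivity; GLDM dependence tolerance α = 0, dependence
  size = 1 + dependent-neighbour count (the centre counts, sizes in [1, 27]).
* NGTDM: 26-neighbourhood gray-tone averages over in-mask neighbours only.
* Shape: mesh quantities from a marching-cubes isosurface of the zero-padded
  mask at level 0.5. The binary mask is anti-aliased with a 0.5-voxel
  Gaussian before meshing: the raw binary isosurface carries a staircase
  artifact that inflates surface area by ~10% (a radius-10-voxel digital
  ball would score sphericity 0.91), while the mild smoothing keeps the
  enclosed volume within ~2%. Axis lengths are 4√λ of the inertia
  eigenvalues of foreground voxel centres; elongation = √(λ₂/λ₁), flatness
  = √(λ₃/λ₁).
* Degenerate denominators never yield NaN: correlation → 1, IMC1/IMC2 → 0,
  MCC → 1, NGTDM busyness/contrast/strength → 0, coarseness capped at 1e6,
  variances/entropies → 0 for point masses. First-order skewness/kurtosis of
  a constant ROI are 0; percentiles use linear interpolation; kurtosis is
  the non-excess (Pearson) form.

### Deep features (2)

The trained 3-D CNN extractor that produced the published deep features is
out of scope (GPU-scale training, no desk-scale verification surface); the
package fixes only its contract — a callable mapping (volume, mask) to the
two raw outputs of a final fully connected layer — and implements the three
published output transforms: identity ("no-sigmoid"), elementwise logistic
("sigmoid"), and sigmoid followed by thresholding at 0.5 with the boundary
assigned to 1 ("binarization"). A deterministic stub extractor (scaled mean
in-mask intensity and a mask-volume z-score, plus a small seeded jitter) is
provided so the fused pipeline can be exercised; it is explicitly not a
learned model. External extractors plug in as a command printing two
scores. Sigmoid outputs are clamped to the nearest representable values
inside (0, 1) since large scores saturate in floating point.

## Feature selection

Features are standardized per column ((x − μ)/σ, population σ, fit on
training rows only; constant columns map to 0 and are flagged). Selection
runs over an 8-fold split of the rows it is given:

* **Step 1** — on each fold's training split, fit a random forest
  (impurity importances) and a gradient-boosted-tree model (total-gain
  importances); each method selects the features whose importance exceeds
  its own mean importance (the standard mean-importance threshold); the
  fold keeps the intersection of the two selections; M is
  the union over the 8 folds.
* **Step 2** — accumulate each method's importances over the folds, rank
  the members of M, keep the top ⌈|M|/2⌉ per method (ties broken by feature
  name) as M_r and M_x, and return N = M_r ∩ M_x.

Degenerate cohorts cannot kill the pipeline: an empty M falls back to all
features and an empty N to M_r ∪ M_x, each with a loud warning.

## Evaluation

Nested stratified 8-fold cross-validation: outer folds assigned by seeded
within-class shuffle + round-robin (per-fold class counts within one case
of exact proportionality); per outer fold the scaler, the feature selection
(run with its own 8-fold split of the outer-training rows) and an
exhaustive inner grid search (stratified 7-fold, scored by mean F2, ties to
the first grid point) are functions of the training split only. The
`global_selection` flag instead runs selection once over the outer folds
and reuses the single subset — the other defensible reading of the
published protocol. Seven inner folds keep at least one positive per inner
fold at cohort sizes near 125.

Metrics per fold and averaged: F2 = 5PR/(4P+R) on hard labels at the
classifiers' default 0.5 threshold, accuracy, precision, recall, and AUC
computed as the Mann–Whitney pair-count statistic with ties counted ½
(identical to the trapezoidal area under the empirical ROC). The mean ROC
interpolates each fold's curve onto a common 101-point FPR grid, averages
pointwise and forces the (0,0)/(1,1) endpoints; single-class folds are
skipped with a warning.

Five classifiers are benchmarked — SVM (RBF), logistic regression, random
forest, gradient-boosted trees, KNN — with small exhaustive default grids
(C ∈ {0.1,1,10,100} × γ ∈ {scale,0.01,0.1}; C ∈ {0.01,…,10}; trees
{100,300} × depth {∅,3,5}; trees {100,300} × depth {2,3,4} × lr
{0.05,0.1,0.3}; k ∈ {1,…,15} × {uniform,distance}), all configurable.

## The phantom generator

Each case is a randomly oriented ellipsoid (semi-axes drawn uniformly from
3–7 mm) whose radius field is perturbed by a random combination of the five
real degree-2 spherical harmonics, rescaled so its realized sup-norm is 1 —
the per-case amplitude (uniform in [0, 0.25]) is then the true relative
surface perturbation, which is what makes the lobulation detectable by
curvature features. Rendered on a 48³ grid at 0.5 mm: mask = interior
voxels; volume = 100 inside / 10 outside, smoothed with a 1-voxel Gaussian
(contrast falloff) plus Gaussian noise (σ = 2). The mesh is the *exact*
zero-isosurface, computed in closed form as a radially deformed icosphere
(the lesion is star-shaped, so the surface point along each ray is
analytic). This emulates the high-quality modelling meshes that accompany
clinical data; a raw marching-cubes isosurface was found to carry
staircase-grade triangles whose discrete-curvature noise (H spanning
0.10–1.11 on a 5 mm sphere with true H = 0.2) swamps the lobulation
geometry.

Rupture labels follow logit(p) = 20·û + 10·v̂ + b with û the normalized
maximum semi-axis and v̂ the normalized lobulation amplitude; the intercept
b is bisected so the realized prevalence lands within 0.05 of the target
(default 0.5). The coefficients make labels near-deterministic in
morphology (Bayes-level AUC ≈ 0.98), i.e. a strong planted signal with a
label-noise band only near the decision boundary — chosen so that
signal-recovery checks measure the pipeline rather than irreducible label
noise. All randomness derives from `SeedSequence([cohort_seed, case_index])`,
so a cohort is a pure function of (n, params).

What the phantom does **not** emulate: parent vessels and necks, real
contrast-agent texture (its in-lesion texture is smoothed noise),
acquisition artifacts, and any dependence of rupture on clinical
covariates (age and sex are pure noise features). Passing tests therefore
demonstrate that the machinery recovers a morphological signal planted in
synthetic geometry — not clinical performance on real aneurysms.

## Problem sizes and determinism

The end-to-end checks run a 125-case cohort (matching the scale of the
labelled clinical cohort the pipeline targets), with nested CV on the KNN
grid and a label-permutation null; one radiomics battery takes well under a
second per case on one CPU, and the full cohort pipeline a few minutes.
Every stochastic component (cohort, fold assignment, forests, boosting,
stub jitter, permutation) is seeded, and repeated runs are byte-identical.

## Known limitations

* The 25-feature decomposition (5 global + 5 curvature scalars × 4
  statistics) and the identity of the fifth curvature scalar are this
  package's documented interpretation of an under-specified list.
* Radiomics discretization (fixed bin count 32) and merged direction
  aggregation are documented defaults, not published settings; numeric
  values are not expected to reproduce any specific external package.
* The stub extractor makes the two deep features summary statistics, so the
  "deep" group carries no information beyond what simpler features encode;
  plugging in a trained extractor restores the intended semantics.
* Run percentage normalizes by (voxels × directions) under merged
  accumulation; with per-direction matrices it reduces to the usual form.
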