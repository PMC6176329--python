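# Methods

This note documents the models and procedures implemented in `spinecurve`,
the assumptions behind them, the parameters that matter, and the numerical
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Pipeline overview and assumptions

The pipeline turns one 2-D grayscale spine slice into a curvature report in
three stages: (1) a cascade gentle-AdaBoost classifier scans the slice with
a fixed-size sub-window and returns one numbered bounding box per vertebral
body; (2) each box seeds a distance-regularized level-set evolution (DRLSE)
that contracts onto the vertebral boundary and yields a binary mask;
(3) mask centroids, ordered superior→inferior, are fit with a least-squares
polynomial whose terminal-tangent angle is compared against clinical
curvature priors.

Standing assumptions: the spine runs along image rows (the fitted curve is
`col = f(row)`; a flag flips the ordering for inverted acquisitions);
vertebral bodies are bright, roughly rectangular structures separated by
darker disc space; one slice contains a single spine; intensities are
rescaled to [0, 1] on input. Boxes are half-open `[top, top+h) × [left,
left+w)` in 0-based (row, col) coordinates everywhere.

## Detector

**Features.** The fused vector concatenates, in order: a Haar-like pool
(8 template kinds — 2 edge, 4 line including the two diagonal quadrant
patterns, 2 center-surround — placed on a coarse grid: box sizes at ½ and ¼
of the window, positions strided by ¼ window), per-subregion 256-bin LBP
histograms (radius-1, 8 neighbors, ties `f_p ≥ f_c` count as set, 4×4
subregion grid, patch-border pixels skipped), and HOG (8×8 cells, 9
unsigned orientation bins over [0, π), central differences, 2×2-cell blocks
with L2 normalization and a zero guard). For the default 90×80 window this
gives 288 Haar + 4096 LBP + 3240 HOG features; for the 24×20 phantom window
200 + 4096 + 72. Features are z-scored per column with statistics fitted on
the initial training set and serialized with the model; z-scoring is
monotone per feature, so stump selection is unaffected while the three
blocks end up on comparable scales.

**Boosting.** Weak learners are depth-1 stumps found by exhaustive search
over every midpoint between consecutive distinct sorted feature values and
both polarities (vectorized with per-stage cached argsorts); ties break
toward the lowest feature index, then the lowest threshold, then the
"accept left" polarity, making training deterministic. The weighted error
is clamped to `[1e-10, 0.5 − 1e-10]` before `β = ε/(1−ε)`, since perfectly
separable rounds would otherwise make `α = log 1/β` diverge. After each
round the stage threshold is reset to the largest additive-score cut that
keeps the configured fraction of training positives (TPR target 0.9), and
boosting stops once the training false-positive rate reaches the per-stage
target (0.03) — interpreted per stage, since the cascade conjunction then
bounds the overall rate by the product of stage rates. A floor of 5
learners per stage (configurable) keeps the stage margin graded even when
one stump already separates the data; without it every accepted window
scores exactly at the threshold and the scan cannot rank overlapping
candidates.

**Cascade bootstrapping.** Stage k+1 trains on the positives accepted so
far and on the false positives of the cascade-so-far, replenished by fresh
background crops drawn through the current cascade; training ends early
when no acceptable negatives remain. Positives that a stage rejects are
dropped (pass-through semantics); training aborts if positives are
exhausted.

**Scanning and grouping.** The window slides left-to-right, top-to-bottom
(stride 8 px by default, 4 px at phantom scale) over a shrinking image
pyramid (factor 1.1; a single unit scale when object size is known, as in
the phantom study). Accepted windows are grouped by single-link clustering
— two windows link when their centers are within 2.2 effective strides in
both axes (bridging single rejected grid positions) or overlap with IoU
above 0.3 — and each group is averaged into one box scored by its best
member. Plain score-ordered NMS was rejected: with tied margins it keeps an
arbitrary member of each acceptance run, biasing boxes by up to half a
window, whereas the group mean centers the box on the object (the same
rationale as classical rectangle grouping in cascade detectors). Grouping
assumes distinct vertebrae are farther apart than the link radius, which
holds whenever inter-vertebral spacing exceeds ~a quarter window. Survivors
are numbered 1..K in raster order of their top-left corner, giving the
superior→inferior sequence used downstream.

## Level-set segmentation

Each detection is processed on a region of interest padded by 20 % of the
box size per side (floor 4 px: the exterior rim must hold the Dirac band
plus the replicated border ring, or the outside sign can flip wholesale).
The full image is CLAHE-enhanced once (8×8 tiles, clip limit 0.01) before
edge computation. The evolution is the standard double-well-regularized
gradient flow with explicit Euler steps, central differences, Neumann
(replicate) borders, and a 1e-10 guard on |∇φ| in the length term; φ is
initialized to ±c₀ (c₀ = 2) with the zero level set on the box boundary,
negative inside, so the positive area weight α contracts the contour onto
the vertebra. No reinitialization is ever performed; the double-well term
keeps |∇φ| near 1 in the active band and near 0 far away, and φ stays
bounded over long runs.

Parameter defaults (all config-exposed): μ = 0.04, λ = 5, α = 1.5,
ε = 1.5 grid units (Dirac width), σ = 1.5 px (edge-indicator Gaussian; the
same value is used for both widths, which are independently configurable),
200 iterations. The time step is dt = 5, following the customary
`μ = 0.2/dt` coupling of the reference DRLSE parameterization; with dt = 1
the distance regularization rebuilds the interface profile too slowly for
the balloon term to move the contour more than a few pixels in 200
iterations, while μ·dt = 0.2 respects the < ¼ stability bound.

The edge indicator `g = 1/(1 + |∇(G_σ∗I)|²)` is computed after multiplying
the [0, 1] image by an `intensity_scale` (default 64). This sets the
gradient sensitivity: on the raw unit scale the squared gradient is of
order 1e-2 and g ≈ 1 everywhere (nothing stops the contour), while at the
8-bit scale of 255 the CLAHE-amplified noise already drives g toward 0 in
flat regions and the λ-weighted length term pins the contour on noise. At
64, residual noise gradients after the σ = 1.5 smoothing stay on the g ≈ 1
plateau and genuine intensity edges still drive g near 0.

After evolution the mask is the largest connected component of {φ < 0},
restored into the full image frame and tagged with its detection number; a
contour that collapses to nothing produces an empty mask with a warning,
not a failure, and is skipped by the analysis stage.

## Curvature and diagnosis

Centroids are binary-mask centers of mass (exact mean row/column of the
foreground pixels). The spinal curve is an ordinary least-squares
polynomial of lateral versus cranio-caudal coordinate; the default degree
adapts to the centroid count (3 for ≥ 5, 2 for 3–4, 1 for 2) because a
cubic is the lowest degree able to express the S-shaped sagittal profile
while staying well-conditioned for short vertebral runs. Duplicate
cranio-caudal coordinates are rejected. Fit quality is reported as R² and
RMSE of the lateral coordinates; when all lateral coordinates coincide the
R² denominator vanishes and a perfect fit reports R² = 1 (any residual,
R² = 0).

The curvature angle integrates `y″/(1+y′²)` between the terminal-centroid
coordinates, evaluated in closed form as `|arctan y′(b) − arctan y′(a)|`
(the exact antiderivative; a quadrature route exists for cross-checking and
agrees to below 1e-6 degrees on polynomial curves). The angle is reported
unsigned, since the decision rules compare magnitudes and the sign merely
encodes curve direction. Diagnosis: coronal slices are called scoliosis at
φ ≥ 10° (boundary included); sagittal slices are normal iff φ lies inside
the region's closed physiologic interval — cervical [35, 45]°, thoracic
[20, 45]°, lumbar [40, 60]° — with the region supplied by the caller (the
package does not label vertebral levels).

## Synthetic phantom

The phantom emulates the geometry the pipeline exploits: bright
superellipse blobs (exponent 4 — rounded rectangles with Haar/HOG edge
structure similar to vertebral bodies) whose centers sit at fixed arc-length
spacing along an analytic polynomial centerline, on a darker background,
lightly blurred (σ = 0.8) and corrupted by additive Gaussian noise clipped
to [0, 1]. Defaults: 256×192 image, 7 vertebrae of 24×20 px at 34 px
spacing, foreground 0.75, background 0.25, noise SD 0.05 — proportions
chosen to mimic a mid-thoracic/lumbar CT view at roughly quarter
resolution, with the 20-phantom evaluation spanning terminal tangent angles
of 0–45°. `spec_for_angle` builds a symmetric quadratic centerline whose
nominal angle is the requested one; the exact ground truth is always the
closed-form tangent-angle difference at the realized terminal centroids.

What the phantom does **not** emulate: Hounsfield-unit statistics, ribs,
spinous processes, spinal cord and sacrum, inter-subject shape variation,
pathology (fractures, osteophytes), partial-volume effects, and anisotropic
pixel spacing. Tests passing on phantoms therefore validate the machinery —
boosting, scanning, level-set convergence, centroid/curvature arithmetic,
decision rules — not clinical detection performance on real CT; the
detector trained here is phantom-specific by construction.

Training patches crop jittered (±2 px) truth boxes for positives; negatives
mix uniform background crops with near-miss crops placed just off a
vertebra (all below IoU 0.2 with every truth box), so bootstrapped stages
see the hard windows a sliding scan actually produces.

## Evaluation conventions

A detection matches a truth box greedily in descending score order at
IoU ≥ 0.5 (one detection per truth box); the matching threshold is a
convention of this package's evaluation, chosen as the standard detection
bookkeeping value. Centroid error is the mean Euclidean distance over
matched pairs (×pixel spacing for mm). ROC curves enumerate all score
thresholds with the ≥-convention, yielding a monotone curve from (0, 0) to
(1, 1).

## Problem sizes

The test suite and acceptance script run at phantom scale: a 3-stage
cascade with a 24×20 window trained on 168 positive / 336 negative patches
from six phantoms, evaluated on twenty 256×192 phantoms (140 vertebrae);
the level-set study uses a radius-30 disk in a 128×128 frame with an 80×80
initial box, 200 evolution iterations (500 for the boundedness check).
These sizes were chosen so the full study re-runs from scratch in well
under a minute on one CPU while every stage still operates in its intended
regime.

## Known limitations

* The detector is single-orientation and single-scale-family; strongly
  rotated or highly variable vertebrae would need a rotated Haar pool or a
  multi-orientation scan (out of scope).
* Window grouping assumes objects are farther apart than the link radius;
  extremely overlapping vertebrae (severe collapse) could merge.
* DRLSE contracts only (α > 0): a detection box that clips a vertebra
  cannot recover the part outside the padded ROI.
* The sagittal rules need the caller to name the region (cervical /
  thoracic / lumbar); anatomical labeling is not performed.
* `R²` of the spinal-curve fit is computed against the lateral coordinate
  variance; for nearly straight spines it is uninformative (the degenerate
  rule above applies).
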