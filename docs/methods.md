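# Methods

## Problem and pipeline

The package classifies grayscale plankton images into taxa. Devices differ
in optics and polarity (bright-field scanners, dark-field in-situ imagers),
organisms span a wide morphological range, and raw frames carry marine snow
(tiny detrital speckles) and sensor noise. The pipeline is:

1. **Pre-processing.** Otsu thresholding; foreground polarity chosen so the
   intensity class holding the majority of the one-pixel border frame is
   background (the organism is assumed not to fill the frame). Connected
   components (8-connectivity) with area strictly below 5 px are removed as
   marine snow; background pixels are replaced by their median intensity so
   texture and gradient descriptors see no artificial edges.
2. **Multi-view feature extraction** into ten groups (below).
3. **Per-group wrapper feature selection.**
4. **Classification** by nonlinear multiple kernel learning (NLMKL) over
   per-group base kernels, with plain SVMs as comparison systems.
5. **Evaluation** with per-class recall `R = TP/actual`, precision
   `P = TP/predicted`, error rate `1 − P` and `F = 2PR/(P+R)`; macro
   (unweighted class mean) averages are the headline, micro averages are
   also emitted since pooled counts are the other common convention.

## The ten feature groups

| group | dim | contents |
|---|---|---|
| geometric-grayscale | 43 | 25 size/shape measures (area, convexity, circularity 4πA/P², elongation, Feret calipers, holes, …), 8 foreground intensity statistics, 7 intensity-weighted Hu moments + 3 normalized central moments |
| gabor | 96 | mean and std of the response magnitude of 48 complex Gabor filters, frequencies F_k = 0.25/√2^k (k = 0..5) cycles/px, orientations jπ/8 (j = 0..7), isotropic envelope σ = 0.56/F (≈ one octave) |
| variogram | 8 | γ(h) = Σ[I(x) − I(x+h)]²/(2N(h)) at lags {1,2,3,4,6,8,12,16}, averaged over 0°/45°/90°/135°, on the mask bounding box |
| lbp | 4096 | 256-bin histograms of 8-neighbor ≥-codes (clockwise from top-left, MSB first) per cell of a 4×4 grid |
| bgc | 255 | normalized histogram of single-loop binary-gradient-contour codes (signs of consecutive ring differences, s(0) = 1, −1 offset → codes in [0, 254]) |
| granulometry1/2 | 13 / 12 | removed-area fraction F_B(λ) after opening with flat disks of diameter λ ∈ 2:4:50 and 5:5:60 |
| sift | 100 | bag-of-words histogram of DoG/SIFT descriptors against a 100-word k-means codebook trained on the training split |
| hog | 576 | 9 unsigned orientation bins × 8×8 grid of 32×32-px cells on a 256×256 canvas, gradient-magnitude weighted, no block normalization |
| idsc | 3 × classes | inner-distance shape-context distances to three templates per category |

Notable numerical choices:

* **Granulometry** openings are evaluated through exact Euclidean distance
  transforms on integer squared distances — identical to erosion-then-
  dilation by the explicit disk element `{(i,j): i²+j² ≤ (λ/2)²}` but one
  EDT pair per size instead of a full morphological pass. The mask is padded
  so out-of-frame counts as background. F_B is nondecreasing in λ and lies
  in [0, 1] (openings with convex elements are anti-extensive and nested).
* **Gabor** statistics use the complex magnitude |I ∗ g|, making the texture
  energy phase-insensitive; kernels are truncated at 3σ.
* **LBP/BGC** codes depend only on intensity ranks, so both descriptors are
  invariant under strictly monotone intensity remappings.
* **HOG** uses central differences and hard bin assignment (a literal
  concatenation-of-histograms reading); the "decomposed into 32×32 cells"
  phrasing is read as cell *size* 32×32 px (8×8 grid, 576 dims), the
  reading that keeps the group at a scale comparable to the others.

## Inner-distance shape context

Silhouettes are represented by n = 100 contour points sampled uniformly by
arclength (counterclockwise, canonical start at the lexicographically
smallest vertex; only the largest component is used so marine-snow remnants
cannot perturb the contour). Inner distances are shortest paths in the
visibility graph of the sample points (line-of-sight tested on the mask
dilated by one pixel to absorb raster effects; the contour ring guarantees
connectivity); inner angles are the tangent-relative departure direction of
the shortest path. Each point gets an 8 log-distance × 12 angle histogram
(K = 96); distances are normalized by the mean inner distance, the log bins
cover 0.125–2× the mean with clamped tails, so each of the other n−1 points
lands in exactly one bin.

Matching minimizes the summed χ²/2 histogram costs over order-preserving
circular correspondences by dynamic programming over all n start offsets,
with an occlusion penalty τ = 0.3 per skipped point. For matching, the
count histograms are rescaled to unit mass: the χ² cost of count histograms
grows linearly with n, and against a fixed τ the skip-everything matching
(cost 2nτ) would otherwise dominate for any realistic n. With unit-mass
histograms per-pair costs lie in [0, 1] and τ = 0.3 sits in its intended
operating regime. The raw-count histograms (row sums n−1) remain the
descriptor contract. Templates cannot be "manually extracted" in an
automated pipeline, so the template library takes the first three training
silhouettes per class each fold (ground-truth masks when the dataset
provides them, otherwise the preprocessed masks).

## Wrapper selection

Sequential forward selection per group: start empty, greedily add the
feature that maximizes 3-fold stratified CV accuracy of a linear SVM
(C = 1) on z-scored training data, stop after 3 non-improving additions or
at a 20-feature cap, return the best subset seen. Groups above 60 candidate
columns are pre-ranked by one-way ANOVA F-score and truncated — the wrapper
cost is (candidates × steps × folds) SVM fits per group, and 60 × 23 × 3 ≈
4 × 10³ fits keeps a ten-group selection in tens of seconds at n ≈ 150
while the informative columns of the high-dimensional histogram groups sit
comfortably inside the top 60 by F-score. Both caps are configuration
parameters. Selection runs inside each training fold only.

## NLMKL

One base kernel per (group, family): linear `x·z`, polynomial
`(x·z/d + 1)³`, Gaussian `exp(−‖x−z‖²/2w²)` with w the median pairwise
training distance of the group. All kernels are trace-normalized (trace =
n) so no group dominates the combination through scale. The combined kernel
is the degree-2 polynomial expansion over base kernels with entrywise
products and nonnegative weights η, ‖η‖₂ ≤ Λ = 1 (no multinomial
coefficients: the sum runs once over each multi-index). Schur's product
theorem keeps every term, hence the combination, positive semidefinite.

Each one-vs-rest binary problem alternates (a) an exact soft-margin SVM
dual solve at fixed η (box [0, C], solver tolerance 1e-8) and (b) a
projected gradient step on η that *descends* the optimal-value dual
objective J*(η) — the margin-maximizing direction, since at the dual
optimum ∂J*/∂η_m = −½ (αy)ᵀ ∂K_η/∂η_m (αy) ≤ 0 by Danskin's theorem.
Joint ascent in both blocks would be degenerate (the dual is maximized by
the empty kernel η = 0). The step is backtracked until J* does not
increase, so the recorded objective trace is nonincreasing; iteration stops
when the improvement drops below 1e-4, with a 50-iteration cap recorded as
a warning in the model metadata if hit. Multiclass prediction is
one-vs-rest argmax of Σ α_i y_i K_η(x_i, x) + b with per-problem η, ties
broken toward the lowest class index. A two-class problem trains a single
binary classifier.

With a single linear base kernel and degree 2 the combined kernel (x·z)² is
even and cannot separate sign-symmetric clusters; this is inherent to
even-degree products of centered linear kernels, not an implementation
artifact, and disappears once several families or groups enter the roster.

## Synthetic data

The generator emulates what the three study devices provide: per-class
silhouette morphologies (ellipses, chains of disks, spiny stars, appendaged
blobs, rings — up to 15 distinct silhouette×texture classes), class-specific
texture (smooth / striped / granular, amplitude 30 intensity levels around
a base of 70–105 on a 195–215 background), marine-snow speckles that are
connected components of area 1–4 px placed clear of the organism, a mild
illumination gradient, Gaussian pixel noise σ = 3, and per-image side
lengths varying in 96–160 px. Objects never touch an 8-px border frame, so
the border polarity rule is valid by construction. Images regenerate
bit-identically from the dataset seed (one spawned seed per image).

What it does **not** emulate: out-of-focus blur, overlapping organisms,
class imbalance, within-class pose articulation, device-specific contrast
transfer. Passing the benchmark therefore shows the machinery is correct
and the multi-view design functions as intended — not that the reported
accuracy transfers to real device imagery, where class overlap is far
higher.

The standard benchmark is 5 classes × 60 images (generation seed 7) under
2-fold stratified CV; the comparison grid trains single-kernel SVMs on the
concatenated selected features, single-family NLMKL and three-family NLMKL
at C ∈ {1, 10, 100}. These problem sizes (n = 300; ten groups; 30 base
kernels for the 3-family system) are the package's reference configuration;
selection caps above were chosen so a full grid run completes in minutes.

## Degenerate inputs and tie rules

Constant images binarize to an empty mask (no contrast); an empty mask
after pre-processing falls back to the full frame with a logged warning.
Empty masks are errors for mask-based extractors. LBP treats
neighbor = center as 1 (classical ≥ convention); BGC1 assigns s(0) = 1, the
only choice under which the −1 offset closes the code range at [0, 254]
(an all-zero ring is impossible because differences around a closed loop
sum to zero). Zero-keypoint images map to the zero BoW vector. Selection
ties break toward the better ANOVA pre-rank; prediction ties toward the
lowest class index.

## Known limitations

* The 43-element geometric/grayscale roster is a documented fixed choice;
  the measurements named in the underlying feature lists anchor it, but the
  exact historical roster is not recoverable.
* The variogram group is implemented as a lag curve; a single-value reading
  is possible.
* The IDSC matching searches all n circular shifts without thin-plate
  refinement; articulation experiments are out of scope.
* Wrapper selection is greedy forward only; floating variants would cost
  another factor of the dimension.
* The benchmark is near-saturated (macro recall ≈ 1.0 for the strongest
  systems), so system orderings on it are weak evidence of ranking on hard
  data; they are consistency checks, not effect-size estimates.
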