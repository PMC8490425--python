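# Methods

This note documents the models and procedures `hsifuse` implements, the
defaults it ships with, what the synthetic scene generator does and does
not emulate, and the numerical choices that were genuinely open.

## Pre-processing

**Calibration.** Raw counts become reflectance via
`R = (raw − dark) / (white − dark)` with a white reference (diffuse
high-reflectance standard) and a dark (shutter-closed) capture. The
denominator is floored at `ε = 1e-6` and the result clipped to
`[0, clip_max = 2]`: a handful of dead sensor elements would otherwise
produce unbounded reflectance values that dominate every intensity-based
registration metric. References may be full cubes, per-column/band
push-broom frames, or per-band vectors; they are broadcast to the cube
shape.

**Spectral smoothing.** A moving average along the band axis (default
window 5, odd, reflected edges). The filter family is deliberately
configurable: only the goal — suppressing high-frequency sensor noise in
the spectra without touching spatial content — is fixed; nothing in the
procedure depends on the specific kernel.

**Band cropping** is inclusive on both endpoints; wavelengths are band
centers in nm, strictly increasing; spatial indexing is 0-based
`(row, col)` and transform coordinates are `(col, row)` pixel centers.

**Pseudo-RGB.** VNIR cubes render the bands nearest 708/539/470 nm as
R/G/B (each channel min-max scaled). NIR cubes have no meaningful color
assignment, so a single mid-band plane is replicated into all three
channels (false color). Grayscale is the Rec. 601 luminance.

## Spatial registration

The VNIR image is the *fixed* image and the NIR image the *moving* one;
all transforms are homogeneous 3×3 matrices acting on `(col, row, 1)`,
with translation (2 free parameters), similarity (4), affine (6) and
projective (8) kinds.

**Intensity-based.** Mean squared intensity difference over the valid
overlap, minimised coarse-to-fine over a 3-level half-resolution pyramid.
The optimiser is a derivative-free Powell search rather than a
fixed-step gradient scheme: the objective is cheap, low-dimensional
(≤ 6 parameters) and non-smooth at the overlap boundary, conditions
under which Powell is more robust than gradient stepping and needs no
step-size tuning.

**Feature-based.** Two detector families behind one interface
(`detect_features(img, detector)`):

* `"blob"` (default, aliases `"surf"`/`"sift"`): a scale-covariant
  difference-of-Gaussians blob detector with gradient-histogram
  descriptors (scikit-image's SIFT). The contract is "scale-covariant
  blob keypoints + descriptors"; provenance records which algorithm ran.
* `"mser"`: a stable-extremal-region detector — the image is thresholded
  at 24 levels in both polarities, connected components whose area
  changes slowly across neighbouring levels are kept (stability ratio
  ≤ 0.7 per level step, area ∈ [15 px, 25% of the image]), and each
  region centroid is described by a mean/std-normalised intensity patch
  scaled to the region's equivalent radius.

Matching is nearest-neighbour with Lowe's distance-ratio test (default
0.7) plus mutual-best filtering; keypoints that share coordinates
(multi-orientation duplicates) are collapsed to one match.

**MSAC.** Random minimal samples (1 / 2 / 3 / 4 correspondences by
kind), hypothesis fit, and truncated squared-error scoring
`Σ min(r², tol²)` with `tol = 1.5 px` — unlike plain RANSAC's inlier
count, this cost grades inliers by residual. 1000 trials by default,
mandatory seed, deterministic. Hypotheses whose 2×2 linear part has
|det| outside [1e-3, 1e3], or whose projective denominator approaches
zero or changes sign over the data, are rejected as physically
impossible. The best hypothesis's inliers receive a least-squares refit,
iterated with inlier re-classification until the inlier set is stable
(≤ 10 rounds).

**Warping and ROI.** Every band is resampled by inverse mapping with
bilinear interpolation; out-of-frame pixels carry a fill value and a
False entry in the validity mask. Both cubes are then cropped to the
largest axis-aligned rectangle inside the mask (histogram-of-heights +
monotonic stack, O(rows·cols)), so fusion only ever sees pixels both
cameras observed.

**Band-pair search.** Single-band grayscale images from each camera are
registered pairwise on a coarse grid (default steps 7 VNIR / 3 NIR
bands), then at one-band steps inside the winning neighbourhood. SSIM is
the selection metric: mutual information and Pearson correlation score
intensity agreement and plateau over most of the interior band range,
while SSIM also rewards structural agreement and is the only one of the
three that cleanly separates well-registered from misregistered pairs.
Failed registrations are recorded as NaN and excluded from the argmax;
ties break toward the lowest index pair.

**Model selection across a dataset.** Each candidate transform is
applied to every scene pair and scored by SSIM on the common overlap.
The winner is the candidate with the lowest interquartile range (linear
interpolation quartiles) — the most *consistent* model — and the report
carries a paired two-tailed Student's t-test of the winner against the
highest-mean candidate at α = 0.05, so a consistency-based choice that
sacrifices significant mean quality is visible.

## Operating bandwidth and fusion

**Relative difference.** For two repeat captures `a, b` of a static
scene, `RD = 100·|a − b| / ((a + b)/2)` per pixel and band (symmetric in
the captures; elements with `a + b = 0` are excluded and counted).
`rd_mean(λ)` is the pixel mean at each band; its band average is the
cutoff threshold. This mean-normalised form is one of several reasonable
relative-difference definitions; it is isolated in a single function so
it can be swapped.

**Cutoffs.** The initial cutoff is the first band (from the
low-wavelength end) where `rd_mean` stays at or below the threshold for
`W = 5` consecutive bands; the final cutoff is symmetric from the top.
The run length exists because a noisy edge band can dip below the
threshold for a single band; `W = 5` is small relative to any realistic
operating bandwidth yet rejects such crossings. Scaling the whole curve
by a positive constant moves the threshold identically and leaves the
cutoffs unchanged. The wavelengths 435/901 nm (VNIR) and 956/1638 nm
(NIR) appear throughout as *defaults* for fixed-cutoff operation — they
are data-derived values for one particular camera pair, recomputed by
`find_cutoffs` whenever repeat captures are available.

**Upsampling.** Bilinear over the nearest 2×2 neighbourhood with
corner-aligned coordinates (`u = i·(R_s−1)/(R_t−1)`), which preserves
corner samples exactly and reproduces linear ramps analytically.
Downsampling is out of scope. Labels are categorical and transfer by
nearest neighbour; no new label values can appear.

**Reflectance offset and gap.** Per pixel,
`offset = mean(last k VNIR bands) − mean(first k NIR bands)` with
`k = 5`, added to the pixel's NIR segment so the two segments meet at the
same level. The per-pixel (rather than global) estimator keeps the
contract local: each fused spectrum is continuous at its own boundary
regardless of scene structure. The excluded wavelength interval between
the segments is recorded as `gap_nm` and must never be interpolated
across — filling it would fabricate spectral samples and distort the NIR
segment's variance. After concatenation each pixel spectrum is min-max
normalised to [0, 1] (constant spectra map to zeros, counted and
warned).

## Segmentation / classification harness

Pixel spectra (per-pixel normalised) are clustered with K-means,
K-medoids or hierarchical K-means under the Euclidean metric. K-medoids
alternates assignment and medoid updates on a subsample of ≤ 2000 pixels
(medoid updates are O(n²)) and then assigns all pixels. Hierarchical
K-means recursively bisects the cluster with the largest inertia with
2-means until K clusters exist — a common bisecting variant chosen for
determinism and simplicity. Cluster ids map to classes greedily in
descending Jaccard overlap, each cluster and class used at most once;
empty or zero-overlap clusters stay unassigned. A brain-style
qualitative preset (K = 24, keep the clusters matching the labeled
classes) is exposed through the CLI.

Supervised classification uses SVM (RBF), random forest and KNN with
hyperparameters chosen by validation accuracy: coarse grids
C, γ ∈ 10^{−3..3} (SVM, plus a 3×3 half-decade refinement around the
coarse optimum), trees ∈ {50…500} (RF), k ∈ {1, 3, …, 25} (KNN); ties
break toward the first grid entry, so results are deterministic given
the seed. The final model is refit on the training split and evaluated
once on the held-out test split.

`compare_modalities` runs the harness on VNIR-only, NIR-only and fused
data for the color / material / material-color problems, sharing
clustering/split seeds across data types so the paired one-tailed
Student's t-tests (α = 0.05) are valid.

## Synthetic scenes

Three generators, all pure functions of (spec, seed):

* **Reference panel** — spatially uniform, spectrally flat reflectance
  (default 0.95) captured twice through the noise model; the band indices
  where the injected noise returns to the interior level are stored as
  ground truth for bandwidth recovery.
* **Registration target** — a soft checkerboard plus random Gaussian
  blobs defined analytically in VNIR-frame coordinates; the NIR cube
  samples the same pattern at `T(nir_pixel)`, so the stored projective
  transform maps NIR coordinates onto VNIR coordinates exactly, and blob
  centers serve as control points in both frames. Truths are sampled as
  perturbations of identity (rotation ≤ 5°, scale 0.9–1.1, tilt ≤ 0.001),
  matching a near-perpendicular two-camera rig.
* **Plastic-like scene** — shaped regions each carrying a
  (material, color) combination; the color component of a region's
  spectrum is confined below 900 nm and the material absorption features
  above 956 nm, with every combination present by default. This makes
  the color problem VNIR-resolvable, the material problem
  NIR-resolvable, and the joint problem unsolvable from either range
  alone by construction.

The noise model is heteroscedastic Gaussian: per-band std =
base (0.01) × amplification (10×) over the first and last 10% of each
camera's grid. This reproduces the bathtub shape of real push-broom
sensor noise and the resulting RD curve, without claiming real sensors
are Gaussian. The generators emulate *statistical structure* — geometry,
band-dependent noise, spectral range separation — not the appearance,
illumination field, scattering physics or scan-timing artifacts of real
captures; a passing benchmark shows the pipeline's machinery is correct
under these conditions, not that any particular tissue is separable.

## Problem sizes and defaults

Default scene dimensions are desk-scale — 96×96 / 48×48 pixels and
120 / 60 bands — so a full pipeline run takes seconds;
`SceneSpec.full_scale()` switches to the real-rig geometry (939×743 /
320×253 pixels, 826 / 172 bands). The test suite uses 128×128
registration targets (20 random projective truths), 32×32 reference
panels (20 fixtures) and 20 plastic scenes for the modality benchmark;
`scripts/acceptance.py` uses 12 registration targets, 20 panel fixtures
and 8 plastic scenes.

## Known limitations

* Registration is restricted to global 2-D transforms between two
  near-perpendicular cameras; deformable motion and parallax from
  non-flat scenes are out of scope.
* The RD statistic needs two repeat captures of a static scene; moving
  scenes require the fixed-cutoff mode.
* The MSER-style detector is a compact reimplementation tuned for the
  synthetic fixtures; on smooth low-contrast imagery it finds few
  regions and registration falls back on failure signalling rather than
  degrading silently.
* Hierarchical K-means here is one specific bisecting rule; other
  published variants differ in the split-selection criterion.
* The fused spectrum's NIR segment is level-shifted, not radiometrically
  re-calibrated: absolute reflectance above the gap is only meaningful
  relative to the VNIR edge level.
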