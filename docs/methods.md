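# Methods

This note documents the models, conventions and numerical choices behind
`gbradiomics`, in the order the pipeline runs.

## Masks and coordinates

Coordinates are 0-based with x = column, y = row; pixel centers sit at
integer coordinates. A pixel belongs to the lesion mask iff its center lies
inside the closed contour under the even-odd rule with a half-open edge
convention (centers on a lower/left edge are inside, on an upper/right edge
outside). This makes rasterization bit-exact and translation-equivariant
under whole-pixel shifts; an axis-aligned square with corners (1,1)–(5,5)
fills exactly the 4×4 block of centers {1..4}². Contours are validated with
shapely (≥ 3 distinct vertices, simple, positive area).

The high-intensity mask is the subset of lesion pixels at or above an Otsu
threshold computed from the within-lesion intensities only: the split
t ∈ 1..255 maximizing the between-class variance of the 256-bin histogram,
ties broken toward the smallest t, high class = intensity ≥ t. A
constant-intensity lesion has no data-driven split; the whole lesion is
then classed high-intensity (area ratio 1) so that AR/CDD/DD stay defined.

The reference region is the lesion bounding box expanded by a margin on
each side (default `max(5 px, 25% of the equivalent diameter)`,
configurable), clipped to the image, minus the lesion pixels. Masks satisfy
`high ⊆ lesion` and `reference ∩ lesion = ∅`, asserted on every run.

## Spatial features (72)

First-order statistics are computed over the within-lesion intensities:
mean, median, population SD, CoV = SD/mean, base-2 Shannon entropy of the
normalized 256-bin histogram (0·log 0 := 0), skewness, and **non-excess**
kurtosis (normal = 3). RImean and RImedian divide the lesion mean/median by
the reference mean/median; a zero reference statistic yields a missing
value rather than an exception.

GLCM features use 64 equal-width gray-level bins over [0, 255]
(configurable), symmetric pair counting summed over the four directions
0°/45°/90°/135° at distance d (both pixels inside the lesion), normalized
to sum 1. For each d = 1..15:

- energy `Σ P²`, contrast `Σ (i−j)² P`, entropy `−Σ P log₂ P`, homogeneity
  `Σ P / (1 + |i−j|)`.

The base-2 log and the `1/(1+|i−j|)` kernel are fixed conventions chosen
once and documented here; offsets a small lesion cannot support are
reported missing and excluded downstream.

Binary-texture features: AR = |high| / |lesion|; CDD and DD are the mean
Euclidean distances from high-intensity pixels to the lesion centroid and
to the high-intensity centroid respectively, both normalized by the
lesion's equivalent radius `R_eq = √(|lesion|/π)`. On a uniform disk both
converge to 2/3 with O(1/R) rasterization error, which the tests verify.

## Morphological features (8)

Area = pixel count × spacing²; the convex area is the hull of the boundary
pixels' corner points (so solidity ≤ 1 holds exactly, at the cost of an
O(1/R) half-pixel positive bias on small shapes); Maj.Len/Min.Len are
4·√(eigenvalues) of the second-order central moment matrix of the pixel
coordinates — the moment-matched ellipse; orientation is the major-axis
angle against the x-axis (y up), signed degrees in [−90, 90], isotropic
ties broken toward 0; perimeter is the number of 8-connected boundary
pixels × spacing (note this count is anisotropic: a 45° staircase counts up
to √2 more pixels per unit length than an axis-aligned edge); equivalent
diameter 2·√(Area/π) and solidity Area/C.Area follow by identity. Pixel
spacing comes from the manifest or DICOM header; uncalibrated images are
rejected because these features are meaningless without units.

## Two-stage feature selection

Each feature is screened univariately: Shapiro–Wilk per group at α = 0.05
routes to a Welch two-sample t-test when both groups pass, otherwise to
Kruskal–Wallis; constant samples are treated as non-normal, and a feature
constant across both groups gets p = 1 by convention. No multiple-testing
correction is applied. Group SDs for the screening statistics use ddof = 1.

- `Fv = |x̄₀ − x̄₁| / √(σ₀² + σ₁²)` (Fisher inter–intraclass variance ratio).
- `F`: both classes standardized against the pooled sample of all
  n₀ + n₁ values; F is the absolute difference of class-mean z-scores,
  algebraically `|x̄₀ − x̄₁| / SD(pooled, ddof = 1)`. (Standardizing each
  class against its own mean would make the statistic identically zero;
  the pooled reading reproduces the published values for every row whose
  classes are displayed as mean ± SD, within the ±0.01 implied by
  3-decimal inputs.)

Stage 1 drops features with p ≥ 0.05; among the significant members of
each GLCM type, only the largest-Fv member survives as the type's
representative (tie → smallest offset); all other significant features
survive. Stage 2 computes, within each family (spatial / morphological),
the medians of the survivors' Fv and F (even count → mean of the middle
two order statistics; quartiles elsewhere by linear interpolation) and
keeps features with `Fv ≥ median(Fv)` **and** `F ≥ median(F)`. The
comparison is inclusive: replaying the published clinical selection table
retains features sitting exactly at a median, reproducing its thresholds
(0.396/0.564 spatial, 0.740/0.964 morphological) and its final 8-feature
set.

## Classification

Stratified 6:4 lesion-level train/test split (patient-level grouping
available to prevent leakage when patients carry several lesions);
standardization fitted on the training set inside the model pipeline; RBF
SVM with C ∈ {0.1, 1, 10, 100} and γ ∈ {scale, 0.01, 0.1, 1} chosen by
mean accuracy over 5 seeded stratified folds (grid order resolves ties
toward the smallest C); the winner is refit on the full training set.
The positive class defaults to class 0 (cholesterol polyp). Sensitivity
and specificity are the positive- and negative-class recalls at the SVM
decision threshold, the Youden index is Sen + Spc − 1 exactly, and the
AUC ranks the continuous decision scores (negated when the positive class
is class 0, so AUC is label-symmetric). Three subsets are reported: all
selected features, morphological only, spatial only.

## Synthetic cohort generator

The generator emulates the statistical structure of the clinical study
population, not its acoustics. Per class:

- **Geometry** — an ellipse with truncated-normal major axis (class 0:
  0.971 ± 0.485 cm on [0.35, 2.0]; class 1: 1.738 ± 0.912 cm on
  [0.5, 2.6] — centered on the clinical morphology summaries), axis ratio
  0.66 ± 0.10, random orientation and center jitter, perturbed radially by
  low-order sinusoids `r(θ) = r₀(θ)(1 + a·Σₖ cₖ/k·sin(kθ+φₖ))`, k = 2..5,
  with amplitude a = 0.03 (class 0) vs 0.12 (class 1) so adenomas are more
  irregular (lower solidity, excess perimeter). The boundary is star-shaped
  by construction, hence always a simple polygon.
- **Appearance** — a piecewise-constant echogenicity map (background level
  60, lesion echo targets 88 vs 103 on the compressed scale, matching the
  clinical within-lesion intensity means) is softened (σ = 1.5 px),
  multiplied by correlated Rayleigh-type speckle (smoothing σ = 2.2 px,
  contrast 0.10) and by a large-scale shading field (σ = 14 px, amplitude
  0.12) that emulates depth-gain and beam inhomogeneity, then
  log-compressed to 8 bits (the echo targets are inverted through the
  compression so they land where configured).
- **Foci** — class 0 additionally receives Poisson(8) Gaussian bright
  blobs (amplitude U(12, 30), σ U(1, 2) px) placed at a uniform fraction
  of at most 0.7 of the local boundary radius, i.e. clustered toward the
  centroid. These punctate pseudo-echoes raise GLCM contrast/entropy,
  lower homogeneity/energy, and pull the high-intensity mask into a tight
  cluster (lower DD) — the direction pattern observed clinically. At the
  defaults, the generated cohort's AR/CDD/DD and intensity means land
  close to the clinical summary values, while GLCM magnitudes remain
  scale-proxies rather than matches.

Reproducibility: each lesion draws from a substream keyed by
(master seed, class, within-class index), so identical seeds give
bit-identical cohorts and growing one class never reshuffles the other.
Three class-0 patients carry two lesions each (58 lesions in 55 patients),
mirroring the clinical cohort.

**What the generator does not emulate:** no beamforming, attenuation,
acoustic shadowing behind the lesion, probe geometry, or scanner-to-scanner
variation; contours are exact rather than observer-drawn; class difficulty
is controlled by a handful of parameters rather than biology. Passing
tests therefore demonstrate the correctness and stability of the pipeline
machinery and the recoverability of the encoded group structure — not
clinical performance. The published clinical test metrics
(Acc 0.875 / Sen 0.885 / Spc 0.857 / AUC 0.898) are properties of the
original image set and are not reproduction targets here; only internal
identities (e.g. Youden) and the selection/statistic replays are checked
against print.

## Problem sizes and tolerances

The default test suite uses cohorts of 100 + 100 lesions for
direction-recovery and separability checks (20 seeds for the median-AUC
property), 50 + 50 for the null cohort, and 2000 replicates at n = 30 per
group for the type-I-error calibration of the univariate router
(rate 0.05 ± 0.02). Closed-form oracles use disks of radius up to 60 px
and rasterization tolerances of O(1/R) as stated inline. Printed-value
replays use ±0.01, the precision implied by 3-decimal published inputs.

## Known limitations

- GLCM gray-level count, direction handling, entropy base and homogeneity
  kernel are conventions; other software may differ systematically.
- The CDD/DD normalization constant (equivalent radius) is one defensible
  reading of "normalized distance"; values are comparable within this
  package, not across implementations.
- Count-based perimeter is anisotropic (up to √2 at 45°); orientation of
  near-isotropic shapes is numerically fragile by nature.
- Whether the GLCM representative should be chosen among significant
  members only (implemented) or all 15 offsets is ambiguous in prose;
  the choice is exposed implicitly via the stage-1 API.
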