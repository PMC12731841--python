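# Methods

This note documents the models, conventions, numerical choices and known
limitations of `histotex`. It describes what the code does and why; every
empirical statement here is one the test suite or `scripts/acceptance.py`
computes.

## Preprocessing and gray-level quantization

High-magnification H&E scans are block-mean downsampled (default factor
10; trailing partial blocks dropped), converted to grayscale with ITU-R
BT.601 luminance weights (0.2989/0.5870/0.1140 — note these sum to 0.9999,
so the gray fixed point holds to ~1e-4), min–max rescaled to [0, 255] per
image, and quantized.

Quantization uses a fixed **bin count** (`ng`, default 32) of equal-width
bins spanning the in-ROI intensity min–max, per image. Levels are 1-based
inside the ROI; 0 marks outside. A constant ROI maps to level 1 with `ng`
kept as metadata so downstream matrix shapes stay nominal. Equal-width
binning over the observed range makes features comparable across images
whose staining intensity varies; stain deconvolution or reference-based
normalization is out of scope.

Pixel spacing is a required input (default fixture value 5 µm/pixel at
analysis resolution); the physical block geometry below depends on it.

## Texture matrices and the 59-feature set

The four families follow the standard published (IBSI-aligned) formula
sets whose cardinalities are exactly 24 GLCM + 16 GLSZM + 14 GLDM +
5 NGTDM. Conventions:

- **GLCM**: distance 1; four 2D directions (0°, 45°, 90°, 135°);
  symmetric accumulation (matrix equals its transpose); features computed
  per direction on that direction's normalized matrix and then averaged.
  Directions with no valid pixel pair are skipped; a single-pixel ROI
  falls back to constant-image limits. With this direction set,
  angle-averaged features are exactly invariant under 90° rotations.
  Degenerate definitions: Correlation is 1 when a marginal variance is 0;
  the informational measures return 0 when their denominators vanish; the
  maximal correlation coefficient is 1 when fewer than two gray levels are
  present (the eigenvalue problem is restricted to levels with positive
  marginal mass).
- **GLSZM**: zones are 8-connected components of equal-level in-ROI
  pixels (`scipy.ndimage.label` with a full 3×3 structuring element).
- **GLDM**: a neighbor within Chebyshev distance 1 is *dependent* when
  its level differs from the center by at most α = 0. The matrix stores
  neighbor-only dependence counts d (a lone pixel has d = 0, matching the
  matrix-level convention that the center is excluded); feature formulas
  use the dependence size k = d + 1 (center included) so the
  small-dependence emphases 1/k² stay finite. Dependence Variance and
  Entropy are shift-invariant, so this choice does not affect them.
- **NGTDM**: the 8-neighborhood mean uses only in-ROI neighbors; pixels
  with no in-ROI neighbor are skipped. Degenerate denominators: a
  constant region returns contrast = busyness = strength = 0 and the
  documented coarseness cap 1e6.

Entropy terms use masked logarithms (only positive probabilities enter),
so constant-image limits (Contrast 0, Joint Energy 1, Difference Entropy
0, NGTDM contrast 0, single-zone GLSZM) are exact rather than
epsilon-polluted.

All four matrix builders are validated exactly against brute-force
per-pixel oracles in the test suite, and GLCM counts additionally against
`skimage.feature.graycomatrix`.

## Texture maps

The ROI bounding box is tiled with non-overlapping square blocks of
physical size `block_mm` (default 0.5 mm; block_px = round(block_mm ·
1000 / pixel_spacing) must be ≥ 2). Blocks inherit the whole-ROI
quantization — re-quantizing per block would decouple gray levels across
the map. A block enters a map when its in-ROI coverage is ≥
`min_coverage` (default 0.5; with threshold 0 any intersecting block is
kept). The grid is anchored at the bounding-box top-left, without
sub-pixel alignment. Maps are summarized by the median over valid blocks.

## Texture derivatives (second pass)

Each map is treated as an image (block = pixel, unit spacing),
re-quantized into `ng2` equal-width bins (default 16, coarser than the
first pass because maps have few samples), and run through the texture
extractors again. Names join the first-pass map and second-pass feature
with an en dash ("Cluster Prominence–Sum Entropy"); programmatic keys
prefix the map's family because some first-pass names repeat across
families.

The default enumeration is all 59 maps × a 13-feature GLCM+GLDM
second-pass set (767 per image), chosen to cover the second-pass features
reported in this line of analysis (Cluster Prominence, Sum Entropy,
Informational Measure of Correlation 2, Contrast, Difference Variance,
the inverse-difference homogeneities; GLDM High/Low Gray-Level Emphasis,
Dependence Variance/Entropy, Small Dependence Low/High Gray-Level
Emphasis). The enumeration is config-controlled
(`AnalysisConfig.second_pass_features`); no published enumeration pins a
unique product, so the total count is a configuration property, not a
validation target. Maps with fewer than 2×2 valid blocks emit NaN entries
(logged, never silently dropped), keeping the vector length exactly
|maps| × |second-pass set|.

## DCE-MRI perfusion targeting

Percentage enhancement is 100 (S(t) − S₀)/S₀ with S₀ the mean over
baseline frames. The initial AUC integrates the baseline-subtracted
signal with the trapezoidal rule over [injection, injection + 120 s]
(truncated to the last frame with a warning when the series is shorter);
the normalized AUC divides by the mean AUC of a muscle ROI and is
invariant under global rescaling of the series. The MIP takes the
per-(x, y) maximum over transverse slices of the normalized AUC when
available, else the raw AUC.

Tertile exclusion sorts the tumor-footprint MIP values with a stable
(value, voxel index) order; low-perfusion targeting excludes the top
⌈n/3⌉ voxels (treating ⌊2n/3⌋ — a floor of 66% for n divisible by 3),
high-perfusion targeting mirrors it. Exclusion is computed on the 2D MIP
and lifted back to all slices of each column. The treatment-cell lattice
is round(18 mm / 1.2 mm) = 15 cells per axis over the square bounding the
analysis region, centered on it; cells fully outside the disc are
dropped, every in-region voxel belongs to exactly one cell, and any cell
containing an excluded voxel is removed (so the cell-level treated volume
can only be at or below the voxel-level one; both are reported).

## Synthetic phantoms

Histology phantoms emulate three regimes at analysis resolution inside an
elliptical tumor (semi-axes 0.46/0.42 of the image):

- *viable tumor*: binarized smoothed Gaussian noise (grain 1.5 px ≈
  nuclear scale at 5 µm/px, 40% dark fraction), dark nuclei ~70 on light
  cytoplasm ~200, plus mild intensity noise;
- *necrosis*: a heavily smoothed low-variance field centered at 190 —
  near cytoplasm brightness, since necrotic tissue loses
  hematoxylin-stained nuclei and appears homogeneously eosinophilic;
- *early apoptosis*: the necrotic field salted with small dark condensed
  foci (default 3% area fraction).

Damage is placed as random discs (default radius 60 px) unioned inside
the tumor until the damaged-area fraction reaches its target; the disc
radius shrinks near the target so the realized fraction lands within ±2
percentage points (enforced, else an error). Per-group targets follow the
reported treatment-arm means and SDs (11.2 ± 5.1% control, 11.8 ± 0.6%
XRT, 29.4 ± 3.5% USMB, 29.1 ± 2.2% USMB+XRT, 36.9 ± 4.8% low-perfusion
targeted, 35.1 ± 3.9% high-perfusion targeted), drawn from a truncated
normal per subject; group sizes default to the reported 5/4/5/5/5/5.
Cohorts are bit-reproducible from a base seed via per-subject
`SeedSequence` spawning.

The DCE phantom is S(t) = S₀(1 + k · perfusion · g(t)) + noise with a
linear 30 s ramp to plateau after injection (frame spacing 5 s, so the
ramp kink lies on a frame and trapezoidal integration is exact up to
rounding), a smooth random perfusion field in [0.2, 1], and optional
white noise. The analytic ground-truth AUC is returned alongside.

What the phantoms are *not*: stain-realistic renderings. They carry the
statistical contrasts the analysis is sensitive to (speckle grain and
contrast, zone structure, damage fraction and patchiness, perfusion
heterogeneity) but no color, glandular architecture, vasculature, motion
or arterial-input physiology. Passing tests therefore demonstrate that
the pipeline recovers known structure of this class — not performance on
real slides or scans.

## Statistics

One-way ANOVA per feature (scipy), with R² = SS_between/SS_total — the
interpretation used for reported group-effect sizes. A zero-variance
table reports F = 0 with a warning instead of erroring, so feature sweeps
do not abort. Post hoc: pooled-variance two-sample t tests for every
group pair (a restricted pair list is supported), with Bonferroni
adjustment p_adj = min(1, p · #pairs) at α = 0.05. Features with missing
values (NaN derivative entries) are skipped with a warning. Report CSVs
are deterministically ordered, so identical inputs yield byte-identical
files.

## Problem sizes used in validation

Tests and the acceptance script scale phantom sizes to the property being
checked: matrix-oracle equivalence uses 50 random 8×8 images (exhaustive
oracles are quadratic), direction-of-effect suites use 20-seed cohorts of
256 px phantoms, the derivative-pattern suite uses 1000 px phantoms
(10×10 block grids), the full-pipeline determinism check runs 12 subjects
at 400 px, and cohort damage statistics use the default 29-subject cohort
at 256–512 px. These sizes are the package's validation design; all
pipeline parameters keep their defaults.

## Known limitations

- 2D only; no 3D texture matrices, wavelet/filtered feature classes, or
  first-order/shape features.
- Quantization and normalization are simple global schemes; no stain
  normalization or deconvolution.
- The second-pass enumeration is a documented default, not a canonical
  set.
- Perfusion analysis is semi-quantitative (no pharmacokinetic modelling,
  registration, or acquisition effects).
- Degenerate-case conventions (coarseness cap, F = 0 reporting, tie
  handling in tertile splits) are pragmatic choices documented above.
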