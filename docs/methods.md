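# Methods

This note documents the models, parameter choices and numerical decisions
behind plaquekit, and what the synthetic-data tests do and do not
demonstrate about real histology.

## Calibration and units

Every raster carries a physical pixel size in µm; all size filters,
dilation radii and reported areas are in physical units, so results are
comparable across magnifications. The µm²→pixel conversion for minimum
object sizes uses `ceil(min_size_um2 / pixel_area)`: an object strictly
below the physical cutoff can never survive through favourable rounding.

## Fluorescence segmentation

The pipeline is white top-hat → local mean threshold → opening/closing
(1-px disk) → 8-connected components → size and shape exclusion.

- **Top-hat structuring element**: disk, default radius 25 µm. The element
  must be larger than the largest object of interest (plaque halos here
  reach ~16 µm radius); structures wider than the element are treated as
  background.
- **Local threshold**: mean filter over a 75 µm window plus an additive
  offset (default 0). The offset is the knob that sets the operating point
  against noise: at offset 0 a symmetric-noise background puts half its
  pixels above the local mean, so for noisy images an offset of about 3×
  the background noise SD is the intended setting (the recovery analyses
  in the tests and the acceptance script use `3 × noise_sd`). Foreground
  is strict (`>`), so an all-zero image cleanly yields zero objects.
- **Size cutoffs**: 34 µm² for costained channels, 9 µm² for X-34 — the
  physical exclusion limits for small staining specks.
- **Shape filtering** eliminates elongated objects (vessel fragments,
  processes) from the Lamp1 and X-34 channels. The features are shape
  factor 4πA/P², roundness 4A/(πL²) and solidity; default lower bounds are
  solidity ≥ 0.5 and roundness ≥ 0.2. The exact formula behind a vendor's
  "shape factor" and the cutoffs used in any one study are rarely
  published, so these are declared, config-exposed defaults, not inferred
  constants. Rasterized features can exceed 1 slightly; a +0.05 band is
  tolerated. Note solidity alone does not remove straight bars (a bar is
  its own convex hull); the roundness bound does.
- **Connectivity**: 8-connected in 2D, 26-connected in 3D — conventional
  for blob detection.

Colour-classifier segmentation for brightfield stains combines inclusive
boxes in RGB and HSV (hue in degrees [0, 360), S and V in [0, 1]; the
units are fixed to avoid dialect ambiguity): a pixel is positive iff it is
inside ≥ 1 positive box and no negative box.

## Peri-plaque microenvironment

The watershed surface is the Euclidean distance transform to the nearest
plaque pixel, seeded at plaque labels and keeping watershed lines; its
zones are the plaques' geodesic influence zones. The ring of plaque *i* is
every pixel within 17 µm of plaque *i*, inside zone *i*, excluding all
plaque pixels and line pixels — rings are disjoint by construction and
dilation can never merge close neighbours. Watershed-line pixels belong to
no ring. Plaques touching the frame border are retained and flagged
(`LabelMap.border_touching`); their rings are truncated by the frame.

Normalization modes: Lamp1/Iba1 fractions are signal∩ring / ring
(ring-exclusive: the "dilated area around plaque" is read as excluding the
plaque interior, and the choice is recorded in the output's `mode` tag);
ApoE is signal∩(plaque∪ring) / plaque and may exceed 1. Section-level
values are pooled-pixel ratios (area-weighted) by default, with the
unweighted per-plaque mean available (`aggregation: mean`); animal-level
values are unweighted means over sections.

## Diffuseness index

All images of a batch (a cohort stained and analyzed together) share three
thresholds: the background threshold exceeding 99.99% of pooled
control-image intensities, and the 80th/50th percentiles of the
within-mask intensities pooled across the batch's positive images.
Percentiles are defined by linear interpolation between order statistics
throughout the package — the common default and directly checkable
against a sort-based oracle. Re-thresholding uses `>=` and is restricted
to the initial mask, so the percentile-0 threshold reproduces the initial
mask exactly and a batch of halo-free plaques yields index 0. Mask cleanup
(opening/closing with a 1-px disk, then the 9 µm² exclusion) is fixed and
recorded per run. Since all cleanup steps are monotone, the compact mask
is always a subset of the diffuse+compact mask. The per-image index is
computed from total areas; per-animal values are means over that animal's
images. Whether the percentiles should be recomputed per cohort is an
analysis-design question; here they are recomputed per batch, and the
batch is a grouping key in the manifest.

## Mander's colocalization

Thresholded M1/M2 (both channels thresholded), computed over every voxel
of the full stack without projection. "Above threshold" is strict, so an
all-zero channel gives a missing coefficient rather than 0/0. Voxel sums
use `math.fsum` (correctly rounded, order-independent), which makes
equality against the brute-force loop oracle exact rather than
ulp-approximate. No automatic threshold selection is provided; thresholds
are config inputs recorded per run, used consistently across samples.

## Gene-module scoring

"Detected" means nRPKM > 0. The imputation rule operates on the unfloored
log2 of detected values: an undetected entry receives the gene's minimum
detected log2 minus 1.0 ("one log2 step"). The max(log2, −4) floor belongs
to the heat-map display transform and is therefore off by default in
scoring, available as a config switch (`log2_floor: -4`); the two
transforms are distinct procedures and only genes that actually hit the
floor are affected by the choice (a regression test documents this).
Z-scores use the sample SD (n − 1); zero-variance genes map to all-zero
rows rather than NaN. Scores of one set sum to zero across samples by
construction, including when imputation fires. Genes absent from the
matrix are dropped with a warning (annotations drift); genes undetected in
every sample are dropped from the set, logged. Welch t tests are two-tailed
with Welch–Satterthwaite degrees of freedom; no multiple-testing
correction is applied across sets by default (per-set tests are reported
as-is; Benjamini–Hochberg is available).

## Synthetic data

The scene generator renders plaques as a piecewise-constant core plateau
(default radius 8 µm, intensity 200) inside a halo plateau (default radius
14 µm, intensity 100) on background 10, with additive Gaussian noise
(default SD 10, i.e. core SNR 19) clipped at zero. The two-plateau profile
is deliberate: compact and diffuse truth areas are exactly πr², so
percentile-mask recovery is analytic — a core-area fraction strictly
between 20% and 50% of plaque pixels guarantees that the pooled 80th
percentile isolates the core plateau and the 50th the full plaque, which
is why the recovery settings sweep halo radii 12–16 µm at core 8 µm.
Plaque cores are placed by rejection sampling and may never overlap; halos
may (mirroring the watershed-separation use case), and scenes for
object-count recovery request full separation via `min_center_distance_um`.
Placement failure beyond the retry budget raises an error naming the
density limit. Lamp1 blobs sit within 3 µm of plaque rims, microglia are
soma disks with 1-px processes, ApoE puncta are ≤ 1 µm disks.

The expression generator produces 2^(baseline + module effect for group B
+ N(0, σ)) with independent dropout zeros applied at the nRPKM scale —
exact zeros, exercising the imputation rule verbatim. Defaults mirror the
sorted-microglia setting the scorer targets: 7 samples per group, log2
noise SD 0.5, 50-gene modules, planted effects in log2 units.

What passing these tests shows: the measurement chain — segmentation,
territory assignment, percentile masking, scoring — recovers known truth
under controlled noise. What it does not show: robustness to off-plateau
intensity falloff, uneven illumination, staining artifacts, anisotropic
PSFs, or RNA-seq count noise; the generators model none of these
(piecewise-constant profiles, i.i.d. Gaussian noise, i.i.d. dropout), so
real-data performance still requires the usual visual QC of segmentation
overlays.

## Problem sizes and degenerate inputs

Tests and the acceptance script run on scenes of 150–500 µm at 0.5–1 µm
pixels with 2–25 plaques, 50-scene property sweeps, 100 random stacks for
the colocalization oracle, and 100 simulated matrices for planted-effect
recovery — sizes chosen so the whole suite runs in a couple of minutes on
one core while keeping every estimate's Monte-Carlo error far below its
tolerance. Degenerate inputs follow one rule: where a biological image
could legitimately be blank (no staining, no plaques), operations return
empty results; where a request is unanswerable (empty tissue mask, no
positive pixels in a batch, no control images, a group of one sample),
they raise.
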