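# Methods

This note documents the measurement model, the synthetic-data model, the
numerical choices, and the design decisions taken where the underlying
procedure was described only loosely in the clinical literature this package
follows.

## Measurement model

An en-face OCT-A slab image is a 2-D grid of decorrelation intensities over
a 4.5 × 4.5 mm field centred on the optic disc. The package measures binary
pixel densities, not flow indices: a pixel either carries perfusion signal
or it does not, and a density is `100 · |signal ∩ region| / |region|`.

**Binarization.** The perfusion mask is `intensity ≥ T` with `T` a local
mean over a window of 150 µm plus an offset of 0.15 of the image dynamic
range, OR-combined with the global Otsu threshold. The local term adapts to
illumination gradients; the Otsu term is needed because the interior of a
wide, uniformly bright vessel exceeds the global threshold but not its own
neighbourhood mean. The offset suppresses speckle false-positives in
signal-poor areas (at an offset of 0.15 and speckle SD of 0.1 of the
dynamic range, the background false-positive rate in a 15%-perfused
neighbourhood is below 1%). The image is normalized to [0, 1] first; the
thresholds actually applied are recorded in the mask provenance.
Degenerate input: a constant image has no histogram structure and yields an
empty perfusion mask, logged as a fallback. A global-Otsu-only mode is
available in the configuration.

**Large-vessel removal.** The local caliber at a perfusion pixel is twice
its Euclidean distance-transform (EDT) value times the pixel pitch. Pixels
whose caliber exceeds the cutoff (default 32 µm) are vessel *cores*; the
large-vessel mask is the union of disks of radius `EDT(c)` around every
core pixel `c`, clipped to the perfusion mask, then dilated by 1 px
(again clipped) to absorb partial-volume rim pixels. Disk radii are binned
to integers (ceil), which can over-cover by under one pixel — always inside
the perfusion mask and typically inside the rim dilation anyway. This
construction propagates the ridge caliber across the vessel cross-section
without flooding into capillaries that merely touch a vessel (a plain
connected-component rule would delete the entire capillary mesh wherever it
contacts a vessel). The capillary mask is defined as
`perfusion ∧ ¬large`, so the partition identity is exact by construction;
the operation depends only on the perfusion mask, hence is idempotent, and
raising the cutoff shrinks the core set, hence the large-vessel mask, so
the operation is monotone in the cutoff.

*Why 32 µm:* radial peripapillary capillaries are ≤ ~15 µm; peripapillary
arterioles and venules are ≥ ~60 µm. At the 14.8 µm/px pitch of a
4.5 mm / 304 px raster, 32 µm ≈ 2.2 px sits between the discrete caliber of
a thin (1–2 px) capillary strand (29.6 µm) and that of the thinnest
rendered vessel. The cutoff is configurable.

**Geometry.** Two concentric circles of 1.95 and 3.45 mm diameter are
placed on the disc centre (from metadata, or the image centre; no automatic
disc detection). The inner disk is the "disc area"; the annulus is the
peripapillary ring (analytic area π(1.725² − 0.975²) = 6.362 mm²;
pixel-counting reproduces it to ~0.05%, the circle-rasterisation floor).
Quadrants are bounded by the ±45° diagonals. Sextants follow the
Garway-Heath map (temporal 311–41°, superotemporal 41–81°, superonasal
81–121°, nasal 121–231°, inferonasal 231–271°, inferotemporal 271–311°,
angles from the temporal horizontal meridian towards superior); the
literature names the sextants without angles, so the canonical map of the
commercial device was adopted. Sector bins are half-open, so the sectors
partition the annulus bit-exactly for every centre and laterality.
Orientation convention: row 0 is superior and the nasal side of an OD image
is the right half (configurable); OS mirrors nasal↔temporal.

**Densities.** Custom capillary mode reports whole-image density over the
full frame *including* the disc, whole-PCD over the annulus, and the four
quadrants, all from the capillary mask. Commercial-style mode reports the
same regions from the raw perfusion mask with the six sextants. The same
1.95/3.45 mm ring is reused for the commercial-style mode (the commercial
ring placement is not published; flagged in config). Default denominator
convention is `include_large`: removed vessel pixels stay in the
denominator as non-capillary tissue. This is what makes capillary densities
(~25–35%) sit far below total densities (~55–65%) with a large positive
commercial-minus-custom bias, matching the reported agreement structure;
`exclude_large` (denominator `region \ large`) is provided for sensitivity
analysis. Whole-ring density equals the denominator-weighted mean of the
sector densities by construction (the report carries the weights), and an
empty region raises an error rather than returning 0. Values are stored at
full precision and displayed to 0.1%.

## Cohort statistics

**Group contrasts.** For each pair of groups, `value ~ group` is fit with a
per-subject random intercept (statsmodels MixedLM, REML); the Wald
statistic for the group effect is referred to a t distribution on the
between-subject degrees of freedom (#subjects − 2), the standard two-level
approximation (MixedLM provides no Satterthwaite df; the plain normal
reference is measurably anticonservative at a few dozen clusters).
Bonferroni multiplies raw p-values by the number of pairwise contrasts.
When every subject contributes one eye the random intercept is
unidentified and the contrast degrades to OLS, with a note in the result.
Displayed p-values follow the clinical convention ("<0.001", ">0.99");
raw values are always stored.

**Bland–Altman.** Difference = commercial − custom per eye (so the bias is
positive). Bias = mean difference; limits of agreement = bias ± 1.96 SD;
LoA confidence intervals use the standard `√(3/n)·SD` standard error;
proportional bias is the Pearson correlation of differences with pair
means. The midpoint of the limits equals the bias exactly, by construction.
Per-eye (not per-subject-averaged) pairs are used.

**ROC.** The empirical AUC (equal to Mann–Whitney `U/(n₁n₂)`, ties ½) is
oriented by a stated direction so AUC ≥ 0.5 when the direction is correct;
the CI is DeLong's, computed from midrank structural components.
Cutoff operating points use strict inequality in the disease direction for
sensitivity. Eye-level ROC ignores intra-subject clustering, as is
conventional in this literature; every result object says so.

## Synthetic data

**Angiograms.** The generator emulates: a 304 × 304 px, 4.5 mm field
(14.8 µm/px; the raster resolution is a convention, flagged in config); a
signal-free disc interior of default radius 0.975 mm (coinciding with the
inner ring, the only disc-scale boundary defined); `n` large-vessel trunks
(default 8) drawn as random-walk polylines from the disc centre, stroked
with disks of sampled caliber 60–120 µm, with occasional branches; a
capillary plexus drawn as a soup of curvilinear 1–2 px strands; intensity
levels background 0.08, capillary 0.75, vessel 1.0; additive Gaussian
speckle (default SD 0.05) clipped to [0, 1].

Two constructions make the ground truth *exact*:

* every capillary pixel is thinned (sequential, random order, with
  rechecks) until it retains a 4-connected background neighbour, so its
  EDT is exactly 1 and its discrete caliber 29.6 µm — strictly below the
  32 µm cutoff. The generator then trims random capillary pixels to hit
  the requested capillary fraction *exactly* (fraction of the
  non-disc, non-vessel area). Fractions above ~0.60 are unreachable under
  this constraint and raise an error.
* capillaries keep a 2-px clearance around vessels (the periarteriolar
  capillary-free zone of real retinas), so the segmentation's 1-px rim
  dilation cannot absorb ground-truth capillary pixels.

What the generator does **not** emulate: SSADA decorrelation physics,
projection and motion artifacts, vessel-intensity heterogeneity, capillary
dropout patterns, or disc-margin segmentation error. Passing recovery tests
therefore demonstrates correctness of the measurement chain on images whose
classes are separable by caliber — not robustness to real-device artifacts.

**Cohorts.** Per-eye values are `group mean + subject intercept +
residual`, intercept ~ N(0, τ), residual ~ N(0, √(σ² − τ²)), so the
marginal SD is the requested σ and two eyes of a subject correlate at
τ²/σ². Defaults take the published three-group summaries (41/27/44 eyes of
21/15/44 subjects) with τ chosen for an intraclass correlation of 0.5 at
the smallest group SD. SSI is drawn N(65, 6) per eye.

## Problem sizes used by the test suite

Recovery is tested on 20 seeded 304-px angiograms spanning annulus
densities ~15–45% (noise SD 0.08); generator moment checks use 10,000
subjects and intereye-correlation checks 5,000; null calibration of the
clustered contrast uses 1000 replicates of 20+20 subjects with two eyes
each; AUC reproduction uses 1000 binormal replicates at the published group
sizes. The full suite runs in about a minute on one CPU.

## Known limitations

* The original thresholding software is unpublished; equivalence is at the
  level of measured-density behaviour, not pixel identity.
* Whether the original pipeline kept removed vessel pixels in the density
  denominator is unstated; both conventions are implemented and the default
  is the one consistent with the reported density ranges and bias.
* AUC confidence intervals do not account for two-eye clustering.
* Disc centre comes from metadata; there is no disc segmentation.
* The commercial sextant angles and ring placement are conventions, not
  published values.
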