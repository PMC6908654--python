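# Methods

## Coordinate frame and scan geometry

All region geometry lives in a fundus coordinate frame: millimetres, origin at
the fovea, x rightward on the image, y upward; image row 0 is the top row.
Laterality fixes anatomy: temporal is −x for OD and +x for OS. Pixels are
0-based `(row, col)`, positions refer to pixel centres, and pixel area is the
squared pitch (24 µm for a 12-mm field over 500 px). `fundus_to_pixel` rounds
to the nearest pixel centre; an exact half-pitch tie rounds toward the lower
index so the inverse mapping is deterministic.

Cross-gaze registration is deliberately out of scope: the five gaze scans
(central, nasal/temporal × superior/inferior) carry their centre offsets as
metadata. The default offsets are ±3.5 mm diagonally, chosen so that every
peripheral 4.5-mm circle is fully contained in at least one gaze scan of a
12-mm field while preserving generous overlap between tiles.

## Binarization

The Phansalkar threshold is computed per pixel from the mean *m* and standard
deviation *s* of normalized intensities in a circular window:
*t* = *m*(1 + *p*e^(−*q·m*) + *k*(*s*/*r* − 1)). Defaults are the conventional
ones for this method (k = 0.25, r = 0.5, p = 2, q = 10) and assume intensities
in [0, 1], hence the min–max normalization step (a constant image cannot be
normalized and is flagged instead). The window radius defaults to 15 px
(≈ 360 µm at 24 µm/px), in line with common CC-quantification practice; it is
exposed in the configuration and the CLI because reported CC metrics are known
to be sensitive to it.

Numerics: window statistics are FFT convolutions of the binary disk kernel,
with the window **clipped at image borders** (statistics over in-image pixels
only — no padded values are fabricated). Convolution counts are rounded back
to integers, and the variance is clamped at zero before the square root. This
path agrees with a brute-force window enumeration to < 1e−12 in the test
oracle. The flow comparison is strict (`intensity > t`); a pixel exactly at
threshold is void, fixing the boundary case deterministically.

## Vessel exclusion

Large superficial vessels shadow the CC and mimic voids, so their footprint is
excluded. The operator is intentionally simple and reproducible: global Otsu
on the normalized SCP slab, removal of 8-connected components smaller than
`min_component_px` (default 50 px — "major" vessels only; no calibre cutoff is
published), then dilation by `dilation_px` (default 2 px) to cover the shadow
penumbra. Void percentages are always reported against the *analyzable* area
(region minus exclusion), and this denominator convention is recorded in the
report provenance.

## Regions

Membership is by pixel centre with half-open radial intervals (inner boundary
exclusive, outer inclusive), which makes the foveal/parafoveal/perifoveal
subfields an exact pixel-level partition of the 6-mm macular disc. The
peripapillary region is a 500-µm-wide annulus outside the disc margin. The
three peripheral circles (radius 2.25 mm) are externally tangent to the 6-mm
macular circle, centres 5.25 mm from the fovea on the vertical meridian
(superior/inferior) and the temporal horizontal meridian; the source figure
shows but does not coordinate them, so this placement is a design choice here.
An alternative published description of the near/mid periphery as 1.5-mm and
3.0-mm annuli is internally inconsistent with the per-circle result tables and
is not implemented.

Each region is measured on exactly one scan: the central scan when it fully
contains the region, otherwise the scan whose centre is nearest the region
centre (distance ties broken lexicographically by gaze name). With the default
gaze offsets the macular subfields and peripapillary annulus land on the
central scan and each peripheral circle on an adjacent gaze scan.

## Void metrics

Voids are 8-connected components (the ImageJ Analyze-Particles default for
this use) of void ∧ region ∧ ¬excluded. No minimum void size is applied by
default — none is published — but the knob exists for sensitivity analyses.
Components are clipped, not rejected, at region boundaries, so the macular
partition conserves area: flow% + void% = 100% of analyzable pixels in every
region, and the whole-macula (and whole-periphery) totals equal the
analyzable-area-weighted combination of their subfields.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *statistical* structure the pipeline must resolve,
not OCT physics:

* CC slab: flow texture at mean 0.75 with dark elliptical voids at mean 0.25,
  additive Gaussian noise (σ = 0.05), clipped to [0, 1]. Void semi-minor axis
  starts at 2.5 px at the fovea and grows by 12%/mm of eccentricity, with mild
  elongation also growing peripherally — mirroring the histological widening
  of inter-capillary spaces toward the periphery. Intensity levels are chosen
  for plausibility (no intensity statistics are published for real scans) and
  so that binarization recovers known void fractions within ±0.03 across the
  0.05–0.35 range.
* Void placement is seeded rejection sampling: ellipse centres are drawn
  uniformly over a zone until the zone's void pixel count reaches
  `round(target · zone_px)`; the final ellipse is trimmed (nearest-to-centre
  pixels kept) so the ground-truth fraction lands exactly on target, well
  inside the ±0.01 contract. An iteration budget turns unreachable targets
  into a generation error.
* SCP slab: bright random-walk vessel branches (widths 3–5 px) entering from
  the image edges on a dark background; the rasterized tree is the
  ground-truth shadow mask, and the CC intensity under it is attenuated.
  Voids keep a 2-px standoff from vessels, matching the default exclusion
  dilation, so the ground-truth fraction and the vessel-excluded measurement
  refer to the same analyzable area. (Without the standoff, boundary clipping
  depresses void density next to vessels and the dilated exclusion removes
  exactly those pixels, biasing measurements high by ~0.3–0.5 pp.)
* Cohorts: per-region true void fractions are drawn per eye from log-normal
  distributions parameterized by published medians and IQRs (log-normal keeps
  fractions positive and right-skewed). The fit matches the median exactly
  and the quartile *ratio* q3/q1; a two-parameter log-normal cannot also match
  both absolute quartiles of an asymmetric IQR. Axial length is Gaussian per
  group (26.6 ± 0.6 mm myopic, 23.9 ± 1.1 mm control); choroidal thickness is
  Gaussian (250 ± 50 µm) with a weak negative coupling (ρ = −0.3) to the void
  draw, reproducing the reported weak, mostly non-significant inverse
  correlation. Each scan's regional zones are filled to that eye's drawn
  fractions; the scan area outside any region is filled at the eye's mean
  fraction.

Not emulated: speckle statistics and the OCT forward model, motion and eyelash
artifacts, projection artifacts beyond a hard shadow, disc tissue appearance,
axial-length magnification (explicitly out of scope upstream). Passing tests
therefore show that the *algorithmic chain* is unbiased and correctly
calibrated on images with known truth — not that it is robust to every device
artifact of real angiograms.

## Statistics

Void percentages are right-skewed, so the battery is nonparametric: two-sided
Mann-Whitney U for group comparisons (exact permutation null when the pooled
sample is ≤ 12 without ties, otherwise the tie-corrected normal
approximation; all-identical data returns p = 1), Shapiro-Wilk as the
normality gate, Spearman (midranks) for correlations, and a one-way ANOVA
with session as the factor for repeat-measurement reproducibility (the
repeated-measures alternative is unpublished; the one-way choice is labelled
in the output). No multiple-testing correction is applied, matching the
source analysis; this is recorded in the report provenance. Power for the
30-vs-50 design is estimated by Monte-Carlo simulation of the Mann-Whitney
test at a 10-percentage-point group difference, with the spread derived from
the log-normal IQR fit.

## Problem sizes

Unit tests run on 10–250-px toy geometries; end-to-end validation uses the
study conditions themselves: 500 × 500-px scans, five gazes per eye, 30 myopic
and 50 control eyes. A full cohort generation plus analysis takes roughly one
minute on a single CPU; `scripts/acceptance.py` repeats it from scratch for
any seed.

## Known limitations

* The vessel segmentation is an intensity/size rule, not a tubularity filter;
  it is adequate for the synthetic SCP contrast but would need revisiting for
  low-contrast clinical slabs.
* Region-to-scan assignment assumes the metadata gaze offsets are accurate;
  no image-based registration is attempted.
* The published "slight modification" of the upstream thresholding algorithm
  is unspecified; all parameters are exposed rather than guessing it.
* Ground-truth void fractions are defined on the vessel-standoff area; with a
  non-default exclusion dilation the generator margin should be changed to
  match (`CohortGenParams.vessel_margin_px`).
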