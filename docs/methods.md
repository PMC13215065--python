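# Methods

This note documents the measurement model, the conventions and defaults,
the synthetic phantom that backs the test suite, and the design decisions
taken where the underlying protocol was open. It states no empirical result
that the tests or `scripts/acceptance.py` do not themselves compute.

## Coordinates, calibration, units

All geometry uses pixel-center coordinates: origin at the top-left pixel
center, x rightward (columns), y downward (rows), 0-based; pixel centers at
integer coordinates. The single physical input is the calibration
`nm_per_px` (required, no default — magnification metadata is not parsed).
All lengths leave the measurement modules in nanometres; exports use the
conventional units per quantity (gaps in nm, contact lengths in µm,
density per 100 µm²).

## Shape measurement

**Area** is the foreground pixel count × `nm_per_px`². For convex shapes of
radius ≥ 100 px the digitization error is ≲ 0.1 %.

**Perimeter** is the arc length of the 0.5 iso-level contour of the binary
footprint (marching squares, sub-pixel), simplified with Douglas–Peucker at
a 1 px tolerance. The raw iso-contour carries a staircase oscillation that
inflates the arc length of smooth shapes by ~5 %; the 1 px simplification
removes that wiggle (ellipse error ≲ 0.3 %) while preserving true corners
(rectangle error ≲ 2 %, the inherent corner cut of the 0.5-level contour).
Footprints of ≤ 10 px are flagged `sub_resolution` and measured on the raw
contour, since simplification degenerates there.

**Circularity** is 4πA/P², clamped to ≤ 1 with a `circularity_clamped` flag
when digitization pushes the raw value above 1. **Centroids** are
foreground centers of mass, exported normalized by the field dimensions so
they are comparable across magnifications; raw pixel centroids are retained
as debug columns.

**Reference area** for the area fraction and density is the `cell` ROI when
one is annotated, else the full field. The "single-cell" reading of density
is therefore honored exactly when a cell boundary exists; most TEM fields
have none, and the field-area fallback is the default.

**Matrix-to-cristae (MRC) ratio** is (mito area − cristae area within the
mito) / (cristae area within the mito), with cristae footprints clipped to
the mitochondrion first. No intersecting cristae annotation ⇒ the value is
missing (not zero); cristae area ≥ mito area ⇒ an annotation-inconsistency
error.

## Contact geometry

The **gap map** is the exact Euclidean distance transform of the pooled ER
foreground, in nm (distances are to ER pixel centers, per the EDT
contract). A field without ER yields a distinguished no-ER result, never an
error: minimum gaps are reported missing and contact lengths zero.

Each mitochondrial contour is resampled at ≤ 1 px arc spacing and the gap
map is sampled there with bilinear interpolation. The **minimum gap** is
the smallest sample — the nearest-approach reading of "shortest vertical
distance", which is well-defined for arbitrary orientations, rather than a
projection onto an axis. **MAMs positivity** is `min_gap < threshold` with
strict inequality at the default threshold of 30 nm (`--mam-threshold-nm`
exposes the 10–50 nm variants used elsewhere in the contact-site
literature). **Contact length** sums the closed-contour segments whose both
endpoints lie strictly below the threshold; segments are not merged across
interruptions and no site count is attempted. Contact is measured along the
mitochondrial membrane (not the ER side): the choice is arbitrary for
parallel runs and the mitochondrial side is the biologically anchored one.

Accuracy at these conventions, verified by the suite: the positivity switch
is exact at 30 nm on calibrated membrane pairs; minimum gaps recover
constructed gaps within 1 px; contact lengths recover analytic parallel-run
and offset-arc constructions within 5 %.

## Feature aggregation

Per image, each per-instance parameter (area, perimeter, circularity,
centroid x/y, MRC ratio, minimum gap, contact length) is summarized by
mean, standard deviation, minimum and maximum over the mitochondria in the
image; values are sorted before reduction so the aggregates are exactly
permutation-invariant. The standard deviation uses the n denominator, which
makes a singleton image's sd exactly 0 with no special case (and matches
the hand value sd({1,3}) = 1). Aggregates over zero instances are stored as
explicit NaN; imputation happens only at model-fitting time, from training
rows, and the fitted medians are frozen into the model manifest.

Two column schemas ship: `full` (8 parameters × 4 statistics + MAF +
density + MAMs-positive % + age + sex = 37 columns) and `paper7` (the seven
selected morphology/contact features — area, perimeter, circularity, MRC
ratio, MAMs positivity, minimum gap, contact length — with the 4 statistics
where applicable = 27 columns). The schema manifest records the realized
dimension and any all-missing columns dropped; the literature's occasionally
quoted higher dimensionalities cannot be reconstructed from the enumerated
inputs, so dimensionality is config, not a constant. Sex is encoded
female = 0 / male = 1; age stays in raw years (standardization happens in
the model pipeline anyway).

## Grading protocol

The split unit is the **patient**, not the image: a 7:3 stratified split is
drawn over patients within each grade (deterministic under the seed), so no
patient's images straddle train and test — image-level splits of
multi-image patients inflate AUC through within-patient correlation. A
grade carried by a single patient goes to train with a warning. The 4:1
variant is available via `train_fraction=0.8`.

Training preprocessing: median imputation (train rows only) → **SMOTE** →
standardization (fitted on training-derived rows). SMOTE is implemented
here: every class is brought up to the majority count with synthetic rows
`x + u·(x′ − x)`, `u ∼ U[0,1)`, where x′ is one of the k = 5 nearest
same-class neighbors (k reduced adaptively for classes of ≤ 5); originals
are preserved verbatim; a one-sample class is duplicated with a warning;
balanced input passes through unchanged. Imputation-before-SMOTE is the
implemented order.

Three families are screened with identical preprocessing: Random Forest
(200 trees, balanced class weights), RBF-kernel SVM (built-in probability
calibration), and an MLP with hidden layers (100, 50) and a 600-iteration
cap with convergence reporting. RF hyperparameters are grid-searched with
stratified 5-fold CV over max depth {5, 10} × min samples per leaf {1, 2} ×
min samples per split {2, 5} — the grid contains the configuration depth
10 / leaf 1 / split 5 / balanced / 200 trees — selecting on mean CV macro
one-vs-rest AUC and refitting on the full balanced training split.

Multiclass AUC is reported as **macro-averaged one-vs-rest** on predicted
probabilities (the standard single-scalar choice for a 4-class problem);
micro-average is also reported. Classes absent from an evaluation set have
their per-class AUC reported missing with a reason, not silently skipped.
External validation deploys the frozen model and manifest (columns, medians,
scaler) with no refitting; a column mismatch is a hard error.

## Segmentation evaluation

COCO-convention instance matching: detections sorted by descending score,
greedy assignment, each reference claimed once, a match requiring IoU ≥
threshold; AP is the all-points interpolated area under the PR curve; mAP
averages over the IoU grid 0.50:0.05:0.95 and classes. Precision at zero
predictions is 1 by convention (logged). Pixel-level Dice is reported next
to matched-pair Dice because cross-domain mitochondria benchmarks are
semantic. The bundled classical segmenter (Otsu + opening + hole filling +
connected components, elongation-based class heuristic) exists so phantom
demos run end-to-end without a trained network; its quality is explicitly
not a goal.

## The phantom model

Fields are built in continuous nm coordinates with exact polygon geometry,
then rasterized: non-overlapping elliptical mitochondria; cristae as
parallel lamellae (period max(90 nm, 6 px), duty cycle = the requested area
fraction) clipped to the ellipse, so the cristae fraction is known
analytically; ER as constant-width (30 nm) ribbons whose centerline is an
arc of the partner ellipse's outward offset curve at distance gap + width/2
— making the intended gap the analytic minimum by construction. Placement
uses bounded rejection sampling; an unplaceable spec raises an explicit
infeasibility error rather than ever overlapping silently. Truths recorded
per field: exact ellipse area/perimeter/circularity (complete elliptic
integral), cristae areas, intended gaps and runs, and a
measurement-independent contact length evaluated with exact polygon
distances on a dense boundary sampling. Rendering is flat intensity levels
+ Gaussian blur + additive Gaussian noise; everything is bit-reproducible
from the seed.

Grade-structured cohorts draw per-field generative parameters from
per-grade normal distributions. The directions follow the qualitative
high-grade findings — smaller, rounder mitochondria; more MAMs-positive
mitochondria; narrower gaps; longer contact runs — but the magnitudes are
synthetic, parameterized by an effect size in within-grade SD units
(default separable profile: 3 SD between extreme grades; 0 gives the null,
non-separable cohort, flagged in the log). Age and sex are sampled
independently of grade so clinical covariates cannot leak label
information. Defaults: 4 fields per patient, 448 px fields at 8 nm/px, 4–7
mitochondria per field, 0.32 µm² mean mitochondrial area, 26 nm mean gap,
500 nm mean run, 30 % cristae coverage — values a TEM morphometry study
would call plausible, chosen once and not tuned.

What the phantoms do **not** emulate: staining texture and shot noise,
membrane thickness and partial-volume effects, touching or overlapping
organelles, irregular (non-elliptical) mitochondrial profiles, section
compression. Passing tests therefore demonstrate correctness of the
*measurement and modeling machinery* under known geometry, not performance
on real TEM tissue; segmentation quality on real data is a property of the
upstream segmenter, which is a pluggable input here.

## Problem sizes and numerics

The cohort-level checks run at 200 fields (50 patients × 4), where the
full pipeline completes in a few minutes on one CPU; the chance-level
control permutes patient labels of the measured cohort over 20 seeds. Ties
in greedy detection matching resolve by stable score order; gap-map
interpolation uses nearest-edge padding; degenerate inputs (empty fields,
no-ER fields, singleton classes, single-class test sets) all have defined,
tested behavior rather than exceptions, except where the input is
inconsistent (cristae exceeding their mitochondrion, conflicting
patient labels, manifest mismatches), which fail loudly.

## Known limitations

* 2-D sections only: no stereology correction toward 3-D contact surface
  areas or volumes.
* The gap is measured mask-to-mask; if masks include membrane thickness,
  the biological inter-membrane cleft is narrower by roughly one membrane.
* Contact length is a thresholded arc sum, not a count or size distribution
  of discrete contact sites.
* The baseline segmenter assumes phantom-like contrast and is not meant for
  real micrographs.
* Feature aggregation treats images as independent given the patient split;
  no hierarchical (patient-level random effect) modeling is attempted.
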