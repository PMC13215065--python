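# mams-quant

Quantification of **mitochondria-associated membranes (MAMs)** and
mitochondrial ultrastructure in calibrated transmission electron microscopy
(TEM) images, with machine-learning classification of glioma WHO grade from
the resulting per-image feature vectors.

MAMs are the regions where the endoplasmic reticulum (ER) membrane runs
within a nanometre-scale gap of the mitochondrial outer membrane — by the
criterion used here, strictly less than **30 nm**. Their extent and geometry
change with tumor malignancy, which makes them a candidate ultrastructural
biomarker. This package takes calibrated TEM rasters plus organelle instance
masks (mitochondrion, ER, cristae, from any segmentation source) and
computes the standard eleven-parameter ultrastructural profile, aggregates
it per image, and trains/evaluates grade classifiers. It is aimed at
quantitative EM labs and at anyone benchmarking organelle segmentation
models.

## What it computes

Per mitochondrion *i* with area *A* and perimeter *P* (all lengths
calibrated to nm via the pixel size):

1. area *A* (nm²) — foreground pixel count × (nm/px)²
2. perimeter *P* (nm) — arc length of the simplified sub-pixel iso-contour
3. circularity 4π*A*/*P*² (1 for a circle)
4–5. centroid (x, y), field-normalized
6. mitochondrial area fraction MAF = Σ*Aᵢ* / reference area
7. mitochondrial density (per 100 µm² of reference area)
8. matrix-to-cristae (MRC) ratio = (*A* − *A*₍cristae₎)/*A*₍cristae₎
9. MAMs positivity: min membrane gap < 30 nm (strict)
10. shortest membrane-to-membrane distance (nm) — minimum over the
    mitochondrial contour of the Euclidean distance transform of the ER mask
11. MAMs contact length (µm) — summed contour arc running within the gap
    threshold of ER

Grading: per-image feature vectors (mean/sd/min/max of the per-instance
parameters + field scalars + age/sex), patient-grouped stratified 7:3 split,
SMOTE balancing of the training split, screening of RF / RBF-SVM /
MLP(100-50), RF grid search with stratified 5-fold CV, one-vs-rest macro
AUC reporting, and a frozen-manifest external-validation harness.

A synthetic **phantom generator** (elliptical mitochondria with cristae
lamellae, constant-width ER ribbons placed at analytically controlled gaps,
grade-structured cohorts) provides exact ground truth for every stage, and a
`seg_eval` module scores any external instance segmentation (COCO-style
AP/mAP, IoU, Dice, precision/recall).

## Worked example

```python
from mams_quant.phantom import PhantomSpec, generate_field
from mams_quant.pipeline import measure_field

spec = PhantomSpec(
    field_size_px=(768, 768), nm_per_px=4.0, n_mitochondria=4,
    cristae_fraction=0.4, er_gap_nm=(25.0, 40.0), er_overlap_nm=(800.0, 500.0),
    er_partner=(0, 1), seed=7,
)
field, instances, truth = generate_field(spec)
records, metrics = measure_field(field, instances, mam_threshold_nm=30.0)
for r in records:
    print(f"{r.instance_id}: area={r.area_nm2/1e6:.3f} um2  circ={r.circularity:.3f}  "
          f"mrc_ratio={r.matrix_to_mrc_ratio:.2f}  min_gap={r.min_gap_nm:.1f} nm  "
          f"contact={r.contact_length_nm/1000:.2f} um  MAM+={r.mam_positive}")
print(f"MAF={metrics.mito_area_fraction:.3f}  "
      f"density={metrics.mito_density_per_100um2:.1f}/100um2  "
      f"MAM-positive={metrics.mam_positive_percent:.0f}%")
```

Output:

```
mito_00: area=0.246 um2  circ=0.819  mrc_ratio=1.48  min_gap=23.5 nm  contact=0.75 um  MAM+=True
mito_01: area=0.539 um2  circ=0.983  mrc_ratio=1.49  min_gap=38.4 nm  contact=0.00 um  MAM+=False
mito_02: area=0.247 um2  circ=0.940  mrc_ratio=1.49  min_gap=1080.6 nm  contact=0.00 um  MAM+=False
mito_03: area=0.331 um2  circ=0.875  mrc_ratio=1.48  min_gap=226.0 nm  contact=0.00 um  MAM+=False
MAF=0.144  density=42.4/100um2  MAM-positive=25%
```

The two ER ribbons were constructed at 25 nm and 40 nm gaps: the 25 nm
partner (`mito_00`) is MAMs-positive with a measured minimum gap of 23.5 nm
(within one 4 nm pixel of the construction) and 0.75 µm of contact; the
40 nm partner is negative. The matrix-to-cristae ratio recovers
0.6/0.4 = 1.5 from the 40 % cristae coverage.

The same flow runs from the shell:

```bash
mams-quant phantom --spec spec.yaml --out demo/ --seed 7
mams-quant measure --images demo/ --masks demo/masks/ \
    --clinical clinical.csv --nm-per-px 4.0 --out run/
mams-quant grade --design run/design_matrix.csv --seed 17 --out run/grading/
mams-quant run --config run.yaml          # full pipeline from one YAML
```

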