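"""Per-image feature vectors and the grading design matrix.

Each image contributes one row: for every per-instance parameter (area,
perimeter, circularity, centroid coordinates, matrix-to-cristae ratio,
minimal ER gap, contact length) the mean, standard deviation (n denominator,
hence exactly 0 for a single instance), minimum and maximum over the
mitochondria in the image; plus the three field-level scalars (area fraction, density,
MAMs-positive percentage) and the clinical covariates (age; sex encoded
female=0 / male=1). Aggregates over zero instances are stored as explicit
NaN — missingness is data here, imputation happens at model-fitting time on
training rows only.

Two column schemas ship: ``full`` (all 8 parameters × 4 statistics + 3 field
scalars + age + sex = 37 columns) and ``paper7`` (the seven selected
morphology/contact features × 4 statistics where applicable + the
MAMs-positive percentage + age + sex = 27 columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import ClinicalRecord, FieldMetrics, MamsQuantError, MitoRecord

#: Per-instance parameters aggregated with mean/sd/min/max.
INSTANCE_PARAMS = (
    "area_nm2",
    "perimeter_nm",
    "circularity",
    "centroid_x_norm",
    "centroid_y_norm",
    "matrix_to_mrc_ratio",
    "min_gap_nm",
    "contact_length_nm",
)

STATS = ("mean", "sd", "min", "max")

FIELD_SCALARS = ("mito_area_fraction", "mito_density_per_100um2", "mam_positive_percent")

#: The seven selected morphology + contact features (per-instance ones get
#: the 4 statistics; MAMs positivity is a field-level percentage).
PAPER7_PARAMS = (
    "area_nm2",
    "perimeter_nm",
    "circularity",
    "matrix_to_mrc_ratio",
    "min_gap_nm",
    "contact_length_nm",
)


def _schema_columns(params: Sequence[str], scalars: Sequence[str]) -> list[str]:
    cols = [f"{p}_{s}" for p in params for s in STATS]
    cols.extend(scalars)
    cols.extend(["age", "sex"])
    return cols


SCHEMAS: dict[str, list[str]] = {
    "full": _schema_columns(INSTANCE_PARAMS, FIELD_SCALARS),
    "paper7": _schema_columns(PAPER7_PARAMS, ("mam_positive_percent",)),
}

ID_COLUMNS = ("image_id", "patient_id")
LABEL_COLUMN = "who_grade"


def aggregate_image(
    mito_records: Sequence[MitoRecord],
    metrics: FieldMetrics,
    clinical: ClinicalRecord,
) -> dict:
    """One feature row for one image.

    Statistics run over available (non-missing) instance values; the sd of a
    single value is 0; aggregates over zero values are NaN.
    """
    row: dict = {
        "image_id": metrics.image_id,
        "patient_id": clinical.patient_id,
    }
    for param in INSTANCE_PARAMS:
        values = np.array(
            [
                getattr(r, param)
                for r in mito_records
                if getattr(r, param) is not None and np.isfinite(getattr(r, param))
            ],
            dtype=float,
        )
        if values.size == 0:
            stats = dict.fromkeys(STATS, np.nan)
        else:
            # sorting makes the aggregates exactly permutation-invariant
            values = np.sort(values)
            stats = {
                "mean": float(values.mean()),
                "sd": float(values.std()),
                "min": float(values[0]),
                "max": float(values[-1]),
            }
        for s in STATS:
            row[f"{param}_{s}"] = stats[s]
    row["mito_area_fraction"] = metrics.mito_area_fraction
    row["mito_density_per_100um2"] = metrics.mito_density_per_100um2
    row["mam_positive_percent"] = (
        np.nan if metrics.mam_positive_percent is None else metrics.mam_positive_percent
    )
    row["age"] = clinical.age
    row["sex"] = 1.0 if clinical.sex == "male" else 0.0
    row["who_grade"] = np.nan if clinical.who_grade is None else clinical.who_grade
    return row


def vectors_to_frame(rows: Sequence[dict]) -> pd.DataFrame:
    """Stack feature rows into a tidy frame with a deterministic column order."""
    cols = list(ID_COLUMNS) + SCHEMAS["full"] + [LABEL_COLUMN]
    return pd.DataFrame(list(rows), columns=cols)


@dataclass
class DesignMatrix:
    """Feature matrix + labels + patient groups + schema manifest.

    ``X`` keeps explicit NaN for missing entries; the imputation medians are
    fitted downstream on training rows only and recorded in the model
    manifest. The schema manifest records the realized dimension and any
    all-missing columns that had to be dropped.
    """

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray
    image_ids: np.ndarray
    manifest: dict = dc_field(default_factory=dict)


def build_design_matrix(vectors: pd.DataFrame, schema: str = "full") -> DesignMatrix:
    """Select schema columns, attach labels and patient groups.

    All-missing columns are dropped with a warning recorded in the manifest;
    an empty cohort or missing labels are errors.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; available: {sorted(SCHEMAS)}")
    if len(vectors) == 0:
        raise MamsQuantError("no rows: cannot build a design matrix from an empty cohort")
    if vectors[LABEL_COLUMN].isna().any():
        bad = vectors.loc[vectors[LABEL_COLUMN].isna(), "image_id"].tolist()
        raise MamsQuantError(f"labels missing for images: {bad}")

    columns = list(SCHEMAS[schema])
    dropped = [c for c in columns if vectors[c].isna().all()]
    kept = [c for c in columns if c not in dropped]
    X = vectors[kept].astype(float).reset_index(drop=True)
    manifest = {
        "schema": schema,
        "columns": kept,
        "dropped_all_missing_columns": dropped,
        "n_rows": int(len(X)),
        "n_features": int(X.shape[1]),
    }
    return DesignMatrix(
        X=X,
        y=vectors[LABEL_COLUMN].to_numpy(dtype=int),
        groups=vectors["patient_id"].to_numpy(dtype=object),
        image_ids=vectors["image_id"].to_numpy(dtype=object),
        manifest=manifest,
    )
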