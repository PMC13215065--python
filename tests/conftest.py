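"""Shared fixtures: simple digital shapes and a measured phantom cohort."""

from __future__ import annotations

import numpy as np
import pytest

from mams_quant import features as feat
from mams_quant import phantom
from mams_quant.pipeline import measure_field
from mams_quant.types import CalibratedField, OrganelleInstance


def disc_mask(radius: int, shape: tuple[int, int], center=None) -> np.ndarray:
    """Digital disc: pixels whose centers lie within the radius."""
    h, w = shape
    cy, cx = center if center is not None else (h / 2, w / 2)
    yy, xx = np.mgrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def ellipse_mask(a: int, b: int, shape: tuple[int, int], center=None) -> np.ndarray:
    """Digital axis-aligned ellipse (a along x, b along y)."""
    h, w = shape
    cy, cx = center if center is not None else (h / 2, w / 2)
    yy, xx = np.mgrid[:h, :w]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def rect_mask(r0: int, c0: int, height: int, width: int, shape: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[r0 : r0 + height, c0 : c0 + width] = True
    return m


def make_field(shape=(64, 64), nm_per_px=2.0, image_id="img", patient_id="P0"):
    return CalibratedField(
        image_id=image_id,
        patient_id=patient_id,
        raster=np.zeros(shape, dtype=np.uint8),
        nm_per_px=nm_per_px,
    )


def mito(footprint: np.ndarray, iid: str = "m0") -> OrganelleInstance:
    return OrganelleInstance(iid, "mitochondrion", footprint)


@pytest.fixture(scope="session")
def phantom_field():
    """One mid-size phantom with cristae and two ER ribbons (gap 25 / 40 nm)."""
    spec = phantom.PhantomSpec(
        field_size_px=(768, 768),
        nm_per_px=4.0,
        n_mitochondria=4,
        cristae_fraction=0.4,
        er_gap_nm=(25.0, 40.0),
        er_overlap_nm=(800.0, 500.0),
        er_partner=(0, 1),
        seed=7,
    )
    return spec, *phantom.generate_field(spec)


@pytest.fixture(scope="session")
def separable_design():
    """Design matrix of a measured, strongly grade-separable synthetic cohort.

    50 patients x 4 fields = 200 images; per-grade generative means of the
    key parameters separated by 3 within-grade SDs between extreme grades.
    """
    bundle = phantom.generate_cohort(
        n_patients=50,
        effect=phantom.effect_profile(3.0),
        seed=11,
        fields_per_patient=4,
    )
    clinical = {row.patient_id: row for row in bundle.clinical.itertuples()}
    rows = []
    for fld in bundle.fields:
        records, metrics = measure_field(fld, bundle.instances[fld.image_id])
        from mams_quant.types import ClinicalRecord

        c = clinical[fld.patient_id]
        rows.append(
            feat.aggregate_image(
                records,
                metrics,
                ClinicalRecord(c.patient_id, c.age, c.sex, int(c.who_grade)),
            )
        )
    vectors = feat.vectors_to_frame(rows)
    return feat.build_design_matrix(vectors, schema="full")
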