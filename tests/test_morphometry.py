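"""Shape metrics: analytic recovery, invariances, matrix-to-cristae ratio."""

import math

import numpy as np
import pytest

from mams_quant import morphometry as mm
from mams_quant.types import MamsQuantError, OrganelleInstance

from conftest import disc_mask, ellipse_mask, make_field, mito, rect_mask


def ramanujan_perimeter(a: float, b: float) -> float:
    """Ramanujan's second ellipse-perimeter approximation (independent oracle)."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


def test_digital_disc_recovers_circle_metrics():
    shape = (256, 256)
    field = make_field(shape, nm_per_px=2.0)
    rec = mm.instance_shape_metrics(mito(disc_mask(100, shape)), field)
    assert rec.area_nm2 == pytest.approx(math.pi * 200.0**2, rel=0.01)
    assert 0.95 <= rec.circularity <= 1.0
    assert rec.centroid_x_norm == pytest.approx(0.5, abs=0.01)
    assert rec.centroid_y_norm == pytest.approx(0.5, abs=0.01)


def test_rectangle_area_exact_and_circularity_near_analytic():
    shape = (64, 64)
    field = make_field(shape, nm_per_px=3.0)
    rec = mm.instance_shape_metrics(mito(rect_mask(20, 10, 10, 40, shape)), field)
    assert rec.area_nm2 == 400 * 3.0**2
    # analytic: 4*pi*400/100^2 = 0.503
    assert rec.circularity == pytest.approx(0.503, rel=0.05)


def test_ellipse_perimeter_within_two_percent_of_oracle():
    # semi-axes 600 x 300 nm at 2 nm/px (300 x 150 px, field large enough)
    shape = (400, 680)
    field = make_field(shape, nm_per_px=2.0)
    rec = mm.instance_shape_metrics(mito(ellipse_mask(300, 150, shape)), field)
    assert rec.perimeter_nm == pytest.approx(ramanujan_perimeter(600, 300), rel=0.02)


def test_scale_equivariance_is_exact():
    shape = (256, 256)
    fp = ellipse_mask(80, 50, shape)
    r2 = mm.instance_shape_metrics(mito(fp), make_field(shape, nm_per_px=2.0))
    r4 = mm.instance_shape_metrics(mito(fp), make_field(shape, nm_per_px=4.0))
    assert r4.perimeter_nm == pytest.approx(2 * r2.perimeter_nm, rel=1e-12)
    assert r4.area_nm2 == pytest.approx(4 * r2.area_nm2, rel=1e-12)
    assert r4.circularity == r2.circularity
    assert r4.centroid_x_norm == r2.centroid_x_norm
    assert r4.centroid_y_norm == r2.centroid_y_norm


def test_rotation_by_90_degrees_preserves_metrics():
    shape = (256, 256)
    fp = ellipse_mask(90, 40, shape)
    field = make_field(shape, nm_per_px=2.0)
    a = mm.instance_shape_metrics(mito(fp), field)
    b = mm.instance_shape_metrics(mito(np.rot90(fp)), field)
    assert b.area_nm2 == a.area_nm2  # pixel count is exact under rot90
    assert b.circularity == pytest.approx(a.circularity, rel=0.02)


def test_circularity_ordering_circle_beats_elongated_ellipses():
    shape = (400, 400)
    field = make_field(shape, nm_per_px=2.0)
    # equal-area shapes: r=100; 2:1 ellipse (141.4, 70.7); 4:1 (200, 50)
    circ = mm.instance_shape_metrics(mito(disc_mask(100, shape)), field).circularity
    e2 = mm.instance_shape_metrics(mito(ellipse_mask(141, 71, shape)), field).circularity
    e4 = mm.instance_shape_metrics(mito(ellipse_mask(200, 50, shape)), field).circularity
    assert circ > e2 > e4


def test_circularity_recomputable_from_stored_fields(phantom_field):
    spec, field, instances, _ = phantom_field
    for inst in instances:
        if inst.organelle_class != "mitochondrion":
            continue
        rec = mm.instance_shape_metrics(inst, field)
        if not rec.circularity_clamped:
            expected = 4 * math.pi * rec.area_nm2 / rec.perimeter_nm**2
            assert rec.circularity == pytest.approx(expected, rel=1e-9)


def test_single_pixel_instance_flagged_sub_resolution():
    shape = (16, 16)
    rec = mm.instance_shape_metrics(
        mito(rect_mask(8, 8, 1, 1, shape)), make_field(shape)
    )
    assert rec.sub_resolution
    assert rec.perimeter_nm > 0


def test_wrong_class_rejected():
    shape = (16, 16)
    er = OrganelleInstance("e", "ER", rect_mask(2, 2, 4, 4, shape))
    with pytest.raises(ValueError, match="mitochondria"):
        mm.instance_shape_metrics(er, make_field(shape))


# -- field metrics ----------------------------------------------------------


def test_quarter_field_mito_gives_maf_quarter():
    shape = (64, 64)
    field = make_field(shape, nm_per_px=2.0)
    fp = rect_mask(0, 0, 32, 64, shape)  # half the rows
    fp[:, 32:] = False  # half the cols -> exactly 1/4 of the field
    metrics = mm.field_metrics([mito(fp)], field)
    assert metrics.mito_area_fraction == pytest.approx(0.25)
    assert metrics.n_mitochondria == 1


def test_empty_field_metrics():
    field = make_field((32, 32))
    metrics = mm.field_metrics([], field)
    assert metrics.mito_area_fraction == 0.0
    assert metrics.mito_density_per_100um2 == 0.0
    assert metrics.mam_positive_percent is None


def test_cell_roi_shrinks_reference_area():
    shape = (64, 64)
    field = make_field(shape, nm_per_px=10.0)
    cell = OrganelleInstance("c", "cell", rect_mask(0, 0, 32, 64, shape))
    m = mito(rect_mask(8, 8, 16, 16, shape))
    with_roi = mm.field_metrics([m], field, cell_roi=cell)
    without = mm.field_metrics([m], field)
    assert with_roi.mito_area_fraction == pytest.approx(2 * without.mito_area_fraction)
    assert with_roi.mito_density_per_100um2 == pytest.approx(
        2 * without.mito_density_per_100um2
    )


def test_phantom_maf_matches_truth_within_digitization(phantom_field):
    spec, field, instances, truth = phantom_field
    metrics = mm.field_metrics(instances, field)
    assert metrics.mito_area_fraction == pytest.approx(truth.mito_area_fraction, rel=0.02)


# -- matrix-to-MRC ratio ----------------------------------------------------


@pytest.mark.parametrize("cr_cols,expected", [(8, 1.0), (4, 3.0)])
def test_matrix_to_mrc_simple_fractions(cr_cols, expected):
    shape = (32, 32)
    m = mito(rect_mask(4, 4, 16, 16, shape))
    cr = OrganelleInstance("cr", "cristae", rect_mask(4, 4, 16, cr_cols, shape))
    assert mm.matrix_to_mrc_ratio(m, [cr]) == pytest.approx(expected)


def test_matrix_to_mrc_missing_without_cristae():
    m = mito(rect_mask(4, 4, 8, 8, (32, 32)))
    assert mm.matrix_to_mrc_ratio(m, []) is None


def test_matrix_to_mrc_inconsistent_annotation_errors():
    shape = (32, 32)
    m = mito(rect_mask(4, 4, 8, 8, shape))
    cr = OrganelleInstance("cr", "cristae", rect_mask(4, 4, 8, 8, shape))
    with pytest.raises(MamsQuantError, match="inconsistent"):
        mm.matrix_to_mrc_ratio(m, [cr])


def test_phantom_cristae_fraction_recovers_ratio(phantom_field):
    # cristae_fraction 0.4 -> matrix:cristae = 0.6/0.4 = 1.5
    spec, field, instances, _ = phantom_field
    cristae = [i for i in instances if i.organelle_class == "cristae"]
    for inst in instances:
        if inst.organelle_class != "mitochondrion":
            continue
        ratio = mm.matrix_to_mrc_ratio(inst, cristae)
        assert ratio == pytest.approx(1.5, rel=0.10)


# -- property tests ---------------------------------------------------------

from hypothesis import given, settings, strategies as st  # noqa: E402


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    height=st.integers(min_value=3, max_value=40),
    width=st.integers(min_value=3, max_value=40),
    nm=st.floats(min_value=0.5, max_value=20.0, allow_nan=False),
)
def test_rectangle_property_area_exact_circularity_bounded(height, width, nm):
    """Any digital rectangle: area is exact in nm², circularity lies in
    (0, 1], and the centroid normalizes into the unit square."""
    shape = (64, 64)
    rec = mm.instance_shape_metrics(
        mito(rect_mask(5, 5, height, width, shape)), make_field(shape, nm_per_px=nm)
    )
    assert rec.area_nm2 == pytest.approx(height * width * nm**2, rel=1e-12)
    assert 0.0 < rec.circularity <= 1.0
    assert 0.0 <= rec.centroid_x_norm <= 1.0
    assert 0.0 <= rec.centroid_y_norm <= 1.0
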