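"""Grading pipeline: splits, SMOTE, screening, grid search, external harness."""

import numpy as np
import pandas as pd
import pytest

from mams_quant import grading
from mams_quant.grading import SplitSpec
from mams_quant.types import MamsQuantError


def _gaussian_cohort(n_patients=40, images_per_patient=2, n_features=5,
                     shift=2.0, seed=0):
    """Patient-grouped 4-class gaussian feature table (fast stand-in for a
    full phantom cohort)."""
    rng = np.random.default_rng(seed)
    rows, y, groups = [], [], []
    for p in range(n_patients):
        grade = p % 4 + 1
        mu = shift * (grade - 2.5) * np.linspace(0.5, 1.5, n_features)
        for i in range(images_per_patient):
            rows.append(rng.normal(mu, 1.0))
            y.append(grade)
            groups.append(f"P{p:03d}")
    X = pd.DataFrame(np.asarray(rows), columns=[f"f{j}" for j in range(n_features)])
    return X, np.asarray(y), np.asarray(groups, dtype=object)


# -- stratified group split -------------------------------------------------


def test_split_keeps_patients_whole():
    X, y, groups = _gaussian_cohort(n_patients=20, images_per_patient=5)
    tr, te, _ = grading.stratified_group_split(y, groups, SplitSpec(0.7, 0))
    assert set(groups[tr]) & set(groups[te]) == set()
    assert len(tr) + len(te) == len(y)


def test_split_stratifies_within_one_group_of_target():
    X, y, groups = _gaussian_cohort(n_patients=40, images_per_patient=1)
    tr, te, _ = grading.stratified_group_split(y, groups, SplitSpec(0.7, 1))
    for grade in (1, 2, 3, 4):
        n_train = (y[tr] == grade).sum()
        assert abs(n_train - 0.7 * 10) <= 1


def test_split_deterministic_and_fraction_calibrated():
    X, y, groups = _gaussian_cohort(n_patients=100, images_per_patient=1)
    fractions = []
    for seed in range(20):
        tr1, te1, _ = grading.stratified_group_split(y, groups, SplitSpec(0.7, seed))
        tr2, te2, _ = grading.stratified_group_split(y, groups, SplitSpec(0.7, seed))
        assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)
        fractions.append(len(tr1) / len(y))
    assert 0.65 <= np.mean(fractions) <= 0.75


def test_single_patient_grade_goes_to_train_with_warning():
    y = np.array([1, 1, 2, 2, 2, 2])
    groups = np.array(["A", "A", "B", "B", "C", "C"], dtype=object)
    tr, te, warnings = grading.stratified_group_split(y, groups, SplitSpec(0.7, 0))
    assert any("single patient" in w for w in warnings)
    assert set(np.flatnonzero(groups == "A")).issubset(set(tr))


def test_split_rejects_conflicting_group_labels():
    with pytest.raises(MamsQuantError, match="conflicting"):
        grading.stratified_group_split(
            [1, 2], ["A", "A"], SplitSpec(0.7, 0)
        )


# -- SMOTE ------------------------------------------------------------------


def test_smote_balances_counts_and_preserves_originals():
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(5, 1, (4, 3))])
    y = np.array([0] * 10 + [1] * 4)
    Xa, ya, _ = grading.smote_balance(X, y, seed=1)
    assert (ya == 0).sum() == (ya == 1).sum() == 10
    assert np.array_equal(Xa[: len(X)], X)  # originals verbatim, first


def test_smote_identity_when_balanced():
    X = np.arange(12, dtype=float).reshape(6, 2)
    y = np.array([0, 0, 0, 1, 1, 1])
    Xa, ya, warnings = grading.smote_balance(X, y, seed=0)
    assert np.array_equal(Xa, X) and np.array_equal(ya, y)
    assert warnings == []


def test_smote_synthetic_rows_are_convex_combinations():
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(0, 1, (12, 4)), rng.normal(3, 1, (5, 4))])
    y = np.array([0] * 12 + [1] * 5)
    Xa, ya, _ = grading.smote_balance(X, y, seed=3)
    minority = X[y == 1]
    for s in Xa[len(X):]:
        best = np.inf
        for i in range(len(minority)):
            for j in range(len(minority)):
                if i == j:
                    continue
                d = minority[j] - minority[i]
                t = np.dot(s - minority[i], d) / np.dot(d, d)
                if -1e-9 <= t <= 1 + 1e-9:
                    best = min(best, np.linalg.norm(s - (minority[i] + t * d)))
        assert best < 1e-6


def test_smote_single_sample_class_duplicated_with_warning():
    X = np.vstack([np.zeros((4, 2)), np.ones((1, 2))])
    y = np.array([0, 0, 0, 0, 1])
    Xa, ya, warnings = grading.smote_balance(X, y, seed=0)
    assert (ya == 1).sum() == 4
    assert np.array_equal(Xa[ya == 1], np.ones((4, 2)))
    assert any("single sample" in w for w in warnings)


# -- classifier screening ---------------------------------------------------


def test_screen_separable_cohort_high_auc_all_probabilities_normalized():
    X, y, groups = _gaussian_cohort(shift=2.0, seed=2)
    tr, te, _ = grading.stratified_group_split(y, groups, SplitSpec(0.7, 2))
    reports = grading.screen_classifiers(X, y, tr, te, families=("RF", "SVM"), seed=2)
    for family, rep in reports.items():
        assert rep.macro_auc is not None and rep.macro_auc > 0.85
        probs = rep.probabilities[[c for c in rep.probabilities if c.startswith("p_")]]
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)


def test_screen_null_labels_chance_level():
    X, y, groups = _gaussian_cohort(shift=0.0, n_patients=60, seed=3)
    tr, te, _ = grading.stratified_group_split(y, groups, SplitSpec(0.7, 3))
    reports = grading.screen_classifiers(X, y, tr, te, families=("RF",), seed=3)
    assert 0.3 <= reports["RF"].macro_auc <= 0.7


def test_single_class_test_set_reports_missing_auc():
    X, y, groups = _gaussian_cohort(n_patients=12, seed=4)
    model = grading.fit_grade_model(X, y, family="RF", seed=0)
    mask = y == 2
    rep = grading.evaluate_model(model, X[mask], y[mask])
    assert rep.macro_auc is None
    assert any("undefined" in n for n in rep.notes)


def test_imputation_medians_come_from_training_rows_only():
    X = pd.DataFrame({"a": [1.0, 3.0, 100.0, np.nan], "b": [0.0, 1.0, 2.0, 3.0]})
    y = np.array([1, 2, 1, 2])
    model = grading.fit_grade_model(X.iloc[:2], y[:2], family="RF", seed=0)
    assert model.medians["a"] == 2.0  # median of {1, 3}, not of all rows


# -- RF grid search ---------------------------------------------------------


def test_rf_grid_size_one_returns_that_config():
    X, y, groups = _gaussian_cohort(seed=5)
    model, cv = grading.rf_grid_search(
        X, y, grid={"max_depth": [10]}, seed=5
    )
    assert model.hyperparameters["max_depth"] == 10
    assert len(cv) == 1
    assert sum(c.startswith("split") for c in cv.columns) == 5  # 5 folds


def test_rf_grid_deterministic_and_prefers_depth_over_stump():
    X, y, groups = _gaussian_cohort(shift=2.0, seed=6)
    m1, _ = grading.rf_grid_search(X, y, grid={"max_depth": [1, 5]}, seed=6)
    m2, _ = grading.rf_grid_search(X, y, grid={"max_depth": [1, 5]}, seed=6)
    assert m1.hyperparameters == m2.hyperparameters
    assert m1.hyperparameters["max_depth"] >= 2


def test_rf_grid_includes_reported_optimum_as_grid_point():
    assert 10 in grading.DEFAULT_RF_GRID["max_depth"]
    assert 1 in grading.DEFAULT_RF_GRID["min_samples_leaf"]
    assert 5 in grading.DEFAULT_RF_GRID["min_samples_split"]


def test_rf_grid_tiny_cohort_instructs_larger():
    X = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 2)))
    X.columns = ["a", "b"]
    y = np.array([1, 1, 1, 2, 2, 2])
    with pytest.raises(MamsQuantError, match="larger cohort"):
        grading.rf_grid_search(X, y, grid={"max_depth": [2]}, seed=0)


# -- external validation ----------------------------------------------------


def test_external_validation_self_consistency():
    X, y, groups = _gaussian_cohort(seed=7)
    tr, te, _ = grading.stratified_group_split(y, groups, SplitSpec(0.7, 7))
    model = grading.fit_grade_model(X.iloc[tr], y[tr], family="RF", seed=7)
    internal = grading.evaluate_model(model, X.iloc[te], y[te])
    external = grading.external_validate(model, X.iloc[te], y[te])
    assert external.macro_auc == internal.macro_auc
    assert external.confusion == internal.confusion


def test_external_validation_column_mismatch_is_fatal():
    X, y, groups = _gaussian_cohort(seed=8)
    model = grading.fit_grade_model(X, y, family="RF", seed=8)
    with pytest.raises(MamsQuantError, match="missing"):
        grading.external_validate(model, X.drop(columns=["f0"]), y)


def test_report_saves_artifacts(tmp_path):
    X, y, groups = _gaussian_cohort(n_patients=16, seed=9)
    tr, te, _ = grading.stratified_group_split(y, groups, SplitSpec(0.7, 9))
    rep = grading.screen_classifiers(X, y, tr, te, families=("RF",), seed=9)["RF"]
    rep.save(tmp_path)
    assert (tmp_path / "report_RF.json").exists()
    assert (tmp_path / "probabilities_RF.csv").exists()
    assert (tmp_path / "roc_RF.png").exists()


# -- property tests ---------------------------------------------------------

from hypothesis import given, settings, strategies as st  # noqa: E402


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    counts=st.lists(st.integers(min_value=2, max_value=12), min_size=2, max_size=4),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_smote_property_balances_any_class_profile(counts, seed):
    """For arbitrary class-count profiles, SMOTE output is exactly balanced
    and keeps every original row verbatim at the front."""
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(3.0 * c, 1.0, (n, 3)) for c, n in enumerate(counts)])
    y = np.concatenate([np.full(n, c) for c, n in enumerate(counts)])
    Xa, ya, _ = grading.smote_balance(X, y, seed=seed)
    _, out_counts = np.unique(ya, return_counts=True)
    assert (out_counts == max(counts)).all()
    assert np.array_equal(Xa[: len(X)], X)
    assert np.array_equal(ya[: len(y)], y)
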