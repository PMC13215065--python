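"""WHO-grade classification on per-image feature vectors.

The modeling protocol: patient-grouped stratified split (default 7:3) so no
patient's images straddle train and test; median imputation fitted on
training rows only; SMOTE balancing of the training split (synthetic rows
are convex combinations of same-class neighbor pairs — implemented here);
standardization fitted on training-derived rows; screening of three
classifier families (Random Forest, RBF-kernel SVM, MLP with hidden layers
100-50); Random-Forest hyperparameter grid search with stratified 5-fold
cross-validation; and one-vs-rest ROC/AUC reporting (macro average as the
headline, micro also reported). A frozen model + manifest can be deployed
unchanged to an external cohort.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler, label_binarize
from sklearn.svm import SVC

from .types import MamsQuantError

FAMILIES = ("RF", "SVM", "MLP")

#: Grid searched for the Random Forest; includes the reported optimum
#: (depth 10, leaf 1, split 5, balanced class weights, 200 trees).
DEFAULT_RF_GRID = {
    "max_depth": [5, 10],
    "min_samples_leaf": [1, 2],
    "min_samples_split": [2, 5],
}


@dataclass(frozen=True)
class SplitSpec:
    """Patient-grouped stratified split definition."""

    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def stratified_group_split(
    labels: Sequence[int],
    groups: Sequence,
    spec: SplitSpec,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split row indices so grade proportions are preserved and no group
    (patient) straddles the split.

    Returns ``(train_idx, test_idx, warnings)``. A grade represented by a
    single patient goes entirely to train, with a warning.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups, dtype=object)
    rng = np.random.default_rng(spec.seed)
    warnings: list[str] = []

    group_label: dict = {}
    for g, y in zip(groups, labels):
        if g in group_label and group_label[g] != y:
            raise MamsQuantError(
                f"group {g!r} carries conflicting labels {group_label[g]} and {y}"
            )
        group_label[g] = y

    train_groups: set = set()
    for grade in sorted(set(group_label.values())):
        members = sorted(g for g, y in group_label.items() if y == grade)
        if len(members) == 1:
            warnings.append(
                f"grade {grade} has a single patient {members[0]!r}: assigned to train"
            )
            train_groups.update(members)
            continue
        perm = rng.permutation(len(members))
        n_train = int(round(spec.train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train_groups.update(members[i] for i in perm[:n_train])

    in_train = np.array([g in train_groups for g in groups])
    return np.flatnonzero(in_train), np.flatnonzero(~in_train), warnings


def smote_balance(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    k_neighbors: int = 5,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Synthetic minority over-sampling to the majority-class count.

    Original rows are preserved verbatim (and come first); each synthetic
    row is ``x + u·(x' − x)`` for a uniform u in [0, 1) and x' one of the
    k nearest same-class neighbors of x (k reduced adaptively for small
    classes). A class with a single sample is duplicated, with a warning.
    Already-balanced input is returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    warnings: list[str] = []
    if (counts == target).all():
        return X, y, warnings

    new_rows = [X]
    new_labels = [y]
    for cls, count in zip(classes, counts):
        need = int(target - count)
        if need == 0:
            continue
        Xc = X[y == cls]
        if count == 1:
            warnings.append(
                f"class {cls} has a single sample: duplicated {need}x (SMOTE undefined)"
            )
            synth = np.repeat(Xc, need, axis=0)
        else:
            k = min(k_neighbors, count - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
            _, idx = nn.kneighbors(Xc)  # idx[:, 0] is the point itself
            base = rng.integers(0, count, size=need)
            pick = rng.integers(1, k + 1, size=need)
            neighbor = idx[base, pick]
            u = rng.random(need)[:, None]
            synth = Xc[base] + u * (Xc[neighbor] - Xc[base])
        new_rows.append(synth)
        new_labels.append(np.full(need, cls, dtype=y.dtype))
    return np.vstack(new_rows), np.concatenate(new_labels), warnings


# --------------------------------------------------------------------------
# Fitting and evaluation


@dataclass
class FittedGradeModel:
    """A trained classifier frozen together with its preprocessing manifest:
    column order, training-split imputation medians and scaler statistics."""

    family: str
    estimator: object
    columns: list[str]
    medians: pd.Series
    scaler: StandardScaler
    classes_: np.ndarray
    seed: int
    hyperparameters: dict = dc_field(default_factory=dict)
    notes: list[str] = dc_field(default_factory=list)
    cv_table: Optional[pd.DataFrame] = None

    def manifest(self) -> dict:
        return {
            "family": self.family,
            "columns": list(self.columns),
            "imputation_medians": {c: float(self.medians[c]) for c in self.columns},
            "scaler_mean": self.scaler.mean_.tolist(),
            "scaler_scale": self.scaler.scale_.tolist(),
            "classes": self.classes_.tolist(),
            "seed": self.seed,
            "hyperparameters": self.hyperparameters,
            "notes": self.notes,
        }


@dataclass
class GradeModelReport:
    """Evaluation artifacts for one fitted model on one evaluation set."""

    family: str
    hyperparameters: dict
    n_train: int
    n_test: int
    auc_per_class: dict
    macro_auc: Optional[float]
    micro_auc: Optional[float]
    roc_curves: dict
    confusion: list
    probabilities: pd.DataFrame
    notes: list[str] = dc_field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "family": self.family,
            "hyperparameters": self.hyperparameters,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "auc_per_class": self.auc_per_class,
            "macro_auc": self.macro_auc,
            "micro_auc": self.micro_auc,
            "confusion": self.confusion,
            "notes": self.notes,
        }

    def save(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"report_{self.family}.json").write_text(
            json.dumps(self.to_json_dict(), indent=2)
        )
        self.probabilities.to_csv(out / f"probabilities_{self.family}.csv", index=False)
        self._plot_roc(out / f"roc_{self.family}.png")

    def _plot_roc(self, path: Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        for cls, (fpr, tpr) in self.roc_curves.items():
            auc = self.auc_per_class.get(str(cls))
            label = f"grade {cls}" + (f" (AUC {auc:.2f})" if auc is not None else "")
            ax.plot(fpr, tpr, label=label)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"{self.family}: one-vs-rest ROC")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _make_estimator(family: str, seed: int, rf_params: Optional[dict] = None):
    if family == "RF":
        params = dict(
            n_estimators=200,
            max_depth=10,
            min_samples_leaf=1,
            min_samples_split=5,
            class_weight="balanced",
            random_state=seed,
        )
        if rf_params:
            params.update(rf_params)
        return RandomForestClassifier(**params)
    if family == "SVM":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if family == "MLP":
        return MLPClassifier(
            hidden_layer_sizes=(100, 50), max_iter=600, random_state=seed
        )
    raise KeyError(f"unknown classifier family {family!r}; expected one of {FAMILIES}")


def fit_grade_model(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    family: str = "RF",
    seed: int = 0,
    rf_params: Optional[dict] = None,
) -> FittedGradeModel:
    """Impute (train medians) → SMOTE → scale → fit one classifier family."""
    medians = X_train.median()
    Xi = X_train.fillna(medians).to_numpy(dtype=float)
    Xa, ya, smote_notes = smote_balance(Xi, np.asarray(y_train), seed=seed)
    scaler = StandardScaler().fit(Xa)
    Xs = scaler.transform(Xa)

    est = _make_estimator(family, seed, rf_params)
    notes = list(smote_notes)
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always", ConvergenceWarning)
        est.fit(Xs, ya)
    for wmsg in caught:
        if issubclass(wmsg.category, ConvergenceWarning):
            notes.append(f"convergence warning: {wmsg.message}")

    hyper = {k: v for k, v in est.get_params().items()
             if k in ("n_estimators", "max_depth", "min_samples_leaf",
                      "min_samples_split", "class_weight", "kernel", "C",
                      "gamma", "hidden_layer_sizes", "max_iter")}
    return FittedGradeModel(
        family=family,
        estimator=est,
        columns=list(X_train.columns),
        medians=medians,
        scaler=scaler,
        classes_=est.classes_,
        seed=seed,
        hyperparameters={k: (list(v) if isinstance(v, tuple) else v) for k, v in hyper.items()},
        notes=notes,
    )


def _apply_preprocess(model: FittedGradeModel, X: pd.DataFrame) -> np.ndarray:
    if list(X.columns) != model.columns:
        missing = [c for c in model.columns if c not in X.columns]
        extra = [c for c in X.columns if c not in model.columns]
        raise MamsQuantError(
            f"design-matrix columns do not match the frozen manifest "
            f"(missing: {missing}, unexpected: {extra}, order must match)"
        )
    Xi = X.fillna(model.medians).to_numpy(dtype=float)
    return model.scaler.transform(Xi)


def predict_probabilities(model: FittedGradeModel, X: pd.DataFrame) -> np.ndarray:
    proba = model.estimator.predict_proba(_apply_preprocess(model, X))
    sums = proba.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9):  # pragma: no cover - sklearn contract
        raise MamsQuantError("predicted probability rows do not sum to 1")
    return proba


def _ovr_aucs(
    y: np.ndarray, proba: np.ndarray, classes: np.ndarray
) -> tuple[dict, Optional[float], Optional[float], list[str]]:
    notes: list[str] = []
    per_class: dict = {}
    defined = []
    for j, cls in enumerate(classes):
        pos = y == cls
        if pos.all() or not pos.any():
            per_class[str(cls)] = None
            notes.append(
                f"AUC undefined for grade {cls}: evaluation set lacks both "
                f"positive and negative examples"
            )
            continue
        auc = float(roc_auc_score(pos.astype(int), proba[:, j]))
        per_class[str(cls)] = auc
        defined.append(auc)
    macro = float(np.mean(defined)) if defined else None
    if len(np.unique(y)) > 1:
        Y = label_binarize(y, classes=classes)
        if Y.shape[1] == 1:  # binary edge case
            Y = np.column_stack([1 - Y, Y])
        micro = float(roc_auc_score(Y.ravel(), proba.ravel()))
    else:
        micro = None
        notes.append("micro AUC undefined: single-class evaluation set")
    return per_class, macro, micro, notes


def evaluate_model(
    model: FittedGradeModel,
    X: pd.DataFrame,
    y: Sequence[int],
    image_ids: Optional[Sequence] = None,
    n_train: int = 0,
) -> GradeModelReport:
    """Score a frozen model on rows never seen in training or SMOTE."""
    y = np.asarray(y)
    proba = predict_probabilities(model, X)
    classes = model.classes_
    per_class, macro, micro, notes = _ovr_aucs(y, proba, classes)

    curves = {}
    for j, cls in enumerate(classes):
        pos = y == cls
        if pos.any() and not pos.all():
            fpr, tpr, _ = roc_curve(pos.astype(int), proba[:, j])
            curves[str(cls)] = (fpr.tolist(), tpr.tolist())

    pred = classes[np.argmax(proba, axis=1)]
    conf = confusion_matrix(y, pred, labels=classes).tolist()
    prob_table = pd.DataFrame(proba, columns=[f"p_grade{c}" for c in classes])
    prob_table.insert(0, "true_grade", y)
    prob_table.insert(0, "image_id", image_ids if image_ids is not None else np.arange(len(y)))
    return GradeModelReport(
        family=model.family,
        hyperparameters=model.hyperparameters,
        n_train=n_train,
        n_test=len(y),
        auc_per_class=per_class,
        macro_auc=macro,
        micro_auc=micro,
        roc_curves=curves,
        confusion=conf,
        probabilities=prob_table,
        notes=model.notes + notes,
    )


def screen_classifiers(
    X: pd.DataFrame,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    families: Sequence[str] = FAMILIES,
    seed: int = 0,
    image_ids: Optional[Sequence] = None,
) -> dict[str, GradeModelReport]:
    """Fit each family with identical preprocessing; report test metrics."""
    ids = np.asarray(image_ids, dtype=object) if image_ids is not None else np.arange(len(y))
    out: dict[str, GradeModelReport] = {}
    for family in families:
        model = fit_grade_model(X.iloc[train_idx], y[train_idx], family=family, seed=seed)
        out[family] = evaluate_model(
            model, X.iloc[test_idx], y[test_idx], ids[test_idx], n_train=len(train_idx)
        )
    return out


def rf_grid_search(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    grid: Optional[dict] = None,
    seed: int = 0,
) -> tuple[FittedGradeModel, pd.DataFrame]:
    """5-fold stratified grid search for the Random Forest.

    Selection metric is the mean cross-validated macro one-vs-rest AUC; the
    winning configuration is refit on the full (SMOTE-balanced) training
    split. Returns the fitted model and the full CV table.
    """
    grid = dict(grid) if grid is not None else dict(DEFAULT_RF_GRID)
    medians = X_train.median()
    Xi = X_train.fillna(medians).to_numpy(dtype=float)
    Xa, ya, smote_notes = smote_balance(Xi, np.asarray(y_train), seed=seed)
    scaler = StandardScaler().fit(Xa)
    Xs = scaler.transform(Xa)

    _, counts = np.unique(ya, return_counts=True)
    if counts.min() < 5:
        raise MamsQuantError(
            "fewer than 5 training samples in a class even after balancing: "
            "5-fold stratified CV is not possible; supply a larger cohort"
        )
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    base = RandomForestClassifier(
        n_estimators=200, class_weight="balanced", random_state=seed
    )
    search = GridSearchCV(base, grid, scoring="roc_auc_ovr", cv=cv, refit=True)
    search.fit(Xs, ya)

    cv_table = pd.DataFrame(search.cv_results_)
    keep = [c for c in cv_table.columns if c.startswith(("param_", "split", "mean_test", "std_test", "rank"))]
    cv_table = cv_table[keep]

    best = search.best_estimator_
    hyper = dict(search.best_params_)
    hyper.update(n_estimators=200, class_weight="balanced")
    model = FittedGradeModel(
        family="RF",
        estimator=best,
        columns=list(X_train.columns),
        medians=medians,
        scaler=scaler,
        classes_=best.classes_,
        seed=seed,
        hyperparameters=hyper,
        notes=list(smote_notes),
        cv_table=cv_table,
    )
    return model, cv_table


def external_validate(
    model: FittedGradeModel,
    X_ext: pd.DataFrame,
    y_ext: Sequence[int],
    image_ids: Optional[Sequence] = None,
) -> GradeModelReport:
    """Deploy a frozen model to an external cohort: no refitting, no
    re-imputation fitting; a column mismatch against the manifest is fatal."""
    return evaluate_model(model, X_ext, np.asarray(y_ext), image_ids)
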