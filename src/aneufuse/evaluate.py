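"""Nested stratified 8-fold cross-validation and the metric suite.

Outer loop: stratified 8-fold; per fold the scaler, the consensus feature
selection and the hyperparameter grid search are fitted on the training
split only, then the refit winner is scored on the held-out fold.  Inner
loop: exhaustive grid search by stratified 7-fold CV, scored by mean F2
(ties go to the first grid point).  Reported metrics per fold and averaged:
F2, accuracy, AUC, precision, recall, plus a mean ROC curve interpolated
onto a common 101-point FPR grid.

F2 = 5·P·R / (4·P + R): recall weighted twice as heavily as precision, the
natural headline metric when missing a ruptured aneurysm costs more than a
false alarm.  AUC is the Mann–Whitney pair-count statistic (ties count ½),
identical to the trapezoidal area under the empirical ROC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .selection import FeatureTable, select_features, standardize
from .types import ValidationError

log = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("svm", "lr", "rf", "xgboost", "knn")

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "svm": {"C": [0.1, 1, 10, 100], "gamma": ["scale", 0.01, 0.1]},
    "lr": {"C": [0.01, 0.1, 1, 10]},
    "rf": {"n_estimators": [100, 300], "max_depth": [None, 3, 5]},
    "xgboost": {
        "n_estimators": [100, 300],
        "max_depth": [2, 3, 4],
        "learning_rate": [0.05, 0.1, 0.3],
    },
    "knn": {"n_neighbors": [1, 3, 5, 7, 9, 11, 13, 15], "weights": ["uniform", "distance"]},
}


@dataclass
class ClassifierSpec:
    """One of the five benchmark classifiers plus its hyperparameter grid."""

    name: str
    grid: dict = None

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValidationError(f"unknown classifier {self.name!r}; want one of {CLASSIFIER_NAMES}")
        if self.grid is None:
            self.grid = DEFAULT_GRIDS[self.name]
        if not self.grid:
            raise ValidationError("empty hyperparameter grid")

    def build(self, params: dict, seed: int):
        if self.name == "svm":
            return SVC(kernel="rbf", probability=True, random_state=seed, **params)
        if self.name == "lr":
            return LogisticRegression(penalty="l2", max_iter=2000, random_state=seed, **params)
        if self.name == "rf":
            return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        if self.name == "xgboost":
            return XGBClassifier(
                random_state=seed, verbosity=0, n_jobs=1, eval_metric="logloss", **params
            )
        return KNeighborsClassifier(**params)


def stratified_folds(labels, k: int = 8, seed: int = 0) -> np.ndarray:
    """Seeded shuffle within each class, then round-robin fold assignment.

    Per-fold class counts differ from exact proportionality by at most one
    case.  Raises :class:`ValidationError` when a class has fewer than k
    members.
    """
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    assignment = np.full(len(y), -1, dtype=int)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        if len(idx) < k:
            raise ValidationError(f"class {cls} has {len(idx)} members, fewer than k={k}")
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % k
    return assignment


def f2_score(tp: int, fp: int, fn: int) -> float:
    """F2 from confusion counts; 0 when precision and recall are both 0.
    Requires positive ground truth (tp + fn > 0)."""
    if tp + fn == 0:
        raise ValidationError("F2 undefined without positive ground truth")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn)
    if precision + recall == 0:
        return 0.0
    return 5.0 * precision * recall / (4.0 * precision + recall)


def auc_score(y_true, y_score) -> float:
    """Mann–Whitney AUC: fraction of positive–negative pairs ranked
    correctly, ties counted 1/2."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(y_score, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC undefined for single-class ground truth")
    r = rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def metric_suite(y_true, y_pred, y_score) -> dict[str, float]:
    """ACC, AUC, precision, recall and F2 with ruptured (1) as the positive
    class; also returns the confusion counts the F2 came from."""
    y = np.asarray(y_true, dtype=int)
    yhat = np.asarray(y_pred, dtype=int)
    if len(y) == 0 or len(y) != len(yhat):
        raise ValidationError("y_true and y_pred must be equal-length and non-empty")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return {
        "f2": f2_score(tp, fp, fn),
        "acc": (tp + tn) / len(y),
        "auc": auc_score(y, y_score),
        "precision": precision,
        "recall": recall,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


def inner_grid_search(
    spec: ClassifierSpec, features: np.ndarray, labels: np.ndarray,
    k_inner: int = 7, seed: int = 0,
):
    """Exhaustive grid search by stratified ``k_inner``-fold CV on the outer
    training split, scored by mean F2; first grid point wins ties.  Returns
    (best_params, model refit on the full split)."""
    y = np.asarray(labels, dtype=int)
    grid = list(ParameterGrid(spec.grid))
    if len(grid) == 1:
        best = grid[0]
    else:
        folds = stratified_folds(y, k=k_inner, seed=seed)
        best, best_score = None, -np.inf
        for params in grid:
            scores = []
            for f in range(k_inner):
                tr, te = folds != f, folds == f
                if len(np.unique(y[te])) < 1 or y[te].sum() == 0:
                    continue  # no positives to score F2 against
                model = spec.build(params, seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(features[tr], y[tr])
                yhat = model.predict(features[te])
                tp = int(np.sum((y[te] == 1) & (yhat == 1)))
                fp = int(np.sum((y[te] == 0) & (yhat == 1)))
                fn = int(np.sum((y[te] == 1) & (yhat == 0)))
                scores.append(f2_score(tp, fp, fn))
            mean_f2 = float(np.mean(scores)) if scores else 0.0
            if mean_f2 > best_score:  # strict: earlier grid points win ties
                best, best_score = params, mean_f2
    model = spec.build(best, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(features, y)
    return best, model


def _scores(model, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)[:, 1]


def mean_roc(fold_scores: list[tuple[np.ndarray, np.ndarray]], n_points: int = 101):
    """Average per-fold empirical ROC curves on a common FPR grid.

    Each fold's curve is linearly interpolated onto ``n_points`` FPR values;
    single-class folds are skipped with a warning.  Endpoints are forced to
    (0, 0) and (1, 1).
    """
    from sklearn.metrics import roc_curve

    grid = np.linspace(0.0, 1.0, n_points)
    tprs = []
    for y_true, y_score in fold_scores:
        y = np.asarray(y_true, dtype=int)
        if len(np.unique(y)) < 2:
            log.warning("mean ROC: skipping single-class fold")
            continue
        fpr, tpr, _ = roc_curve(y, y_score)
        interp = np.interp(grid, fpr, tpr)
        interp[0] = 0.0
        tprs.append(interp)
    if not tprs:
        raise ValidationError("no multi-class folds available for the mean ROC")
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    return grid, mean_tpr


@dataclass
class CVReport:
    """Per-fold and mean metrics for one classifier."""

    classifier: str
    per_fold: list[dict] = field(default_factory=list)
    chosen_params: list[dict] = field(default_factory=list)
    selected_features: list[list] = field(default_factory=list)
    mean: dict = field(default_factory=dict)
    roc_fpr: np.ndarray | None = None
    roc_tpr: np.ndarray | None = None

    def finalize(self, fold_scores) -> None:
        keys = ("f2", "acc", "auc", "precision", "recall")
        self.mean = {k: float(np.mean([m[k] for m in self.per_fold])) for k in keys}
        self.roc_fpr, self.roc_tpr = mean_roc(fold_scores)

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "per_fold": self.per_fold,
            "chosen_params": [
                {k: (None if v is None else v) for k, v in p.items()} for p in self.chosen_params
            ],
            "selected_features": self.selected_features,
            "mean": self.mean,
            "roc": {"fpr": list(map(float, self.roc_fpr)), "tpr": list(map(float, self.roc_tpr))},
        }


def nested_cv(
    table: FeatureTable,
    specs: list[ClassifierSpec],
    seed: int = 0,
    k_outer: int = 8,
    k_inner: int = 7,
    do_selection: bool = True,
    global_selection: bool = False,
) -> dict[str, CVReport]:
    """Nested stratified cross-validation over the given classifiers.

    Per outer fold: standardize on the training split, run the two-step
    consensus selection on it (unless ``global_selection``, which runs
    selection once over the outer folds and reuses the subset — the
    single-subset protocol), restrict columns, grid-search the inner loop,
    refit, and score the held-out fold.  Fully deterministic given the seed.
    """
    y = table.labels.to_numpy()
    folds = stratified_folds(y, k=k_outer, seed=seed)

    global_subset = None
    if do_selection and global_selection:
        global_subset = sorted(select_features(table, folds, seed=seed).N)

    reports = {spec.name: CVReport(classifier=spec.name) for spec in specs}
    fold_scores: dict[str, list] = {spec.name: [] for spec in specs}

    for f in range(k_outer):
        tr, te = folds != f, folds == f
        train_tab = table.subset_rows(tr)
        if do_selection:
            if global_selection:
                subset = global_subset
            else:
                inner_assign = stratified_folds(train_tab.labels.to_numpy(), k=8, seed=seed * 1000 + f)
                subset = sorted(select_features(train_tab, inner_assign, seed=seed * 1000 + f).N)
        else:
            subset = list(table.features.columns)
        log.info("outer fold %d: %d training cases, %d selected features", f, tr.sum(), len(subset))

        X_train_raw = table.features.loc[tr, subset]
        X_test_raw = table.features.loc[te, subset]
        X_train_std, scaler = standardize(X_train_raw)
        X_test_std = scaler.transform(X_test_raw)
        Xtr, Xte = X_train_std.values, X_test_std.values
        ytr, yte = y[tr], y[te]

        for spec in specs:
            params, model = inner_grid_search(
                spec, Xtr, ytr, k_inner=k_inner, seed=seed * 100 + f
            )
            yhat = model.predict(Xte)
            yscore = _scores(model, Xte)
            metrics = metric_suite(yte, yhat, yscore)
            metrics["fold"] = f
            rep = reports[spec.name]
            rep.per_fold.append(metrics)
            rep.chosen_params.append(params)
            rep.selected_features.append(list(subset))
            fold_scores[spec.name].append((yte, yscore))
            log.info("fold %d %s: params=%s f2=%.3f auc=%.3f", f, spec.name, params, metrics["f2"], metrics["auc"])

    for spec in specs:
        reports[spec.name].finalize(fold_scores[spec.name])
    return reports
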