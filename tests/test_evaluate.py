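"""Metric closed forms, stratification arithmetic, grid-search tie rules,
mean ROC and nested-CV determinism/leakage."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from aneufuse.evaluate import (
    ClassifierSpec,
    CVReport,
    auc_score,
    f2_score,
    inner_grid_search,
    mean_roc,
    metric_suite,
    nested_cv,
    stratified_folds,
)
from aneufuse.selection import FeatureTable
from aneufuse.types import ValidationError


class TestStratifiedFolds:
    def test_balanced_divisible(self):
        y = np.array([0] * 64 + [1] * 64)
        folds = stratified_folds(y, k=8, seed=0)
        for f in range(8):
            assert (y[folds == f] == 1).sum() == 8
            assert (y[folds == f] == 0).sum() == 8

    def test_round_robin_arithmetic(self):
        y = np.array([0] * 65 + [1] * 60)
        folds = stratified_folds(y, k=8, seed=1)
        pos_counts = [(y[folds == f] == 1).sum() for f in range(8)]
        assert set(pos_counts) <= {7, 8}
        assert np.bincount(folds).sum() == 125

    def test_small_class_rejected(self):
        y = np.array([0] * 20 + [1] * 5)
        with pytest.raises(ValidationError):
            stratified_folds(y, k=8, seed=0)


class TestF2:
    def test_closed_form_p_half_r_one(self):
        assert f2_score(tp=2, fp=2, fn=0) == pytest.approx(5 / 6)

    @pytest.mark.parametrize("tp,fp,fn", [(3, 1, 1), (1, 3, 3), (10, 0, 0)])
    def test_equal_precision_recall_gives_f2_equal_p(self, tp, fp, fn):
        # when P == R == p, F2 collapses to p
        if fp == fn:
            p = tp / (tp + fp)
            assert f2_score(tp, fp, fn) == pytest.approx(p)

    def test_zero_predictions(self):
        assert f2_score(tp=0, fp=0, fn=3) == 0.0

    def test_no_positive_truth_rejected(self):
        with pytest.raises(ValidationError):
            f2_score(tp=0, fp=2, fn=0)


class TestAUC:
    def test_pair_enumeration_example(self):
        # pairs: (0.9>0.6), (0.9>0.1), (0.4<0.6), (0.4>0.1) -> 3/4
        assert auc_score([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1]) == pytest.approx(0.75)

    def test_reversal_antisymmetry(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.normal(size=50)
        assert auc_score(y, -s) == pytest.approx(1 - auc_score(y, s))

    def test_matches_trapezoid_oracle(self):
        """Pair counting equals sklearn's trapezoidal ROC area, ties included."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            y = rng.integers(0, 2, 40)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.normal(size=40), 1)  # rounding forces ties
            assert auc_score(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-9)


class TestMetricSuite:
    def test_perfect_prediction(self):
        m = metric_suite([1, 0, 1, 0], [1, 0, 1, 0], [0.9, 0.1, 0.8, 0.2])
        assert (m["f2"], m["acc"], m["auc"], m["precision"], m["recall"]) == (1, 1, 1, 1, 1)

    def test_f2_consistent_with_own_confusion_table(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        yhat = rng.integers(0, 2, 30)
        m = metric_suite(y, yhat, rng.normal(size=30))
        assert m["f2"] == pytest.approx(f2_score(m["tp"], m["fp"], m["fn"]), abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValidationError):
            metric_suite([1, 1], [1, 0], [0.5, 0.5])


class TestInnerGridSearch:
    @staticmethod
    def _separable(n=56):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, 3)) + 3.0 * y[:, None]
        return X, y

    def test_single_point_grid(self):
        X, y = self._separable()
        spec = ClassifierSpec("knn", grid={"n_neighbors": [3]})
        best, model = inner_grid_search(spec, X, y, seed=0)
        assert best == {"n_neighbors": 3}
        assert model.predict(X).shape == y.shape

    def test_tie_goes_to_first_grid_point(self):
        X, y = self._separable()
        # both points perfectly separate the data -> identical mean F2
        spec = ClassifierSpec("knn", grid={"n_neighbors": [3, 5]})
        best, _ = inner_grid_search(spec, X, y, seed=0)
        assert best == {"n_neighbors": 3}

    def test_winner_is_argmax_of_exhaustive_grid(self):
        """Re-scoring every grid point exactly reproduces the chosen one."""
        rng = np.random.default_rng(9)
        n = 56
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, 4)) + 0.8 * y[:, None]
        spec = ClassifierSpec("knn", grid={"n_neighbors": [1, 3, 5, 7], "weights": ["uniform"]})
        best, _ = inner_grid_search(spec, X, y, k_inner=7, seed=5)

        from sklearn.model_selection import ParameterGrid

        def score(params):
            folds = stratified_folds(y, k=7, seed=5)
            out = []
            for f in range(7):
                tr, te = folds != f, folds == f
                m = spec.build(params, 5)
                m.fit(X[tr], y[tr])
                yh = m.predict(X[te])
                tp = int(((y[te] == 1) & (yh == 1)).sum())
                fp = int(((y[te] == 0) & (yh == 1)).sum())
                fn = int(((y[te] == 1) & (yh == 0)).sum())
                out.append(f2_score(tp, fp, fn))
            return np.mean(out)

        scores = [score(p) for p in ParameterGrid(spec.grid)]
        assert score(best) >= max(scores) - 1e-12


class TestMeanROC:
    def test_perfect_folds(self):
        folds = [(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9]))] * 8
        fpr, tpr = mean_roc(folds)
        assert fpr[0] == 0 and tpr[-1] == 1
        assert np.all(tpr[1:] == 1.0)

    def test_random_scores_near_diagonal(self):
        rng = np.random.default_rng(0)
        folds = [
            (rng.integers(0, 2, 200), rng.normal(size=200))
            for _ in range(8)
        ]
        fpr, tpr = mean_roc(folds)
        assert np.max(np.abs(tpr - fpr)) < 0.15

    def test_single_class_fold_skipped(self):
        good = (np.array([0, 1, 1, 0]), np.array([0.2, 0.7, 0.9, 0.4]))
        bad = (np.array([1, 1, 1, 1]), np.array([0.5, 0.5, 0.5, 0.5]))
        fpr, tpr = mean_roc([good] * 7 + [bad])
        fpr2, tpr2 = mean_roc([good] * 7)
        np.testing.assert_allclose(tpr, tpr2)


@pytest.fixture(scope="module")
def toy_cohort():
    """Separable toy cohort big enough for nested 8-fold CV."""
    rng = np.random.default_rng(21)
    n = 64
    ids = [f"c{i}" for i in range(n)]
    y = pd.Series([0, 1] * (n // 2), index=ids)
    X = pd.DataFrame(
        rng.normal(size=(n, 12)), index=ids, columns=[f"f{i:02d}" for i in range(12)]
    )
    X["f00"] += 2.5 * y
    X["f01"] -= 2.0 * y
    return FeatureTable(features=X, labels=y)


class TestNestedCV:
    def test_determinism(self, toy_cohort):
        spec = [ClassifierSpec("knn", grid={"n_neighbors": [3, 5]})]
        r1 = nested_cv(toy_cohort, spec, seed=4, do_selection=False)
        r2 = nested_cv(toy_cohort, spec, seed=4, do_selection=False)
        assert r1["knn"].mean == r2["knn"].mean
        assert r1["knn"].chosen_params == r2["knn"].chosen_params

    def test_separable_cohort_high_auc(self, toy_cohort):
        rep = nested_cv(
            toy_cohort, [ClassifierSpec("knn", grid={"n_neighbors": [3, 5]})],
            seed=4, do_selection=False,
        )["knn"]
        assert rep.mean["auc"] >= 0.9
        assert len(rep.per_fold) == 8
        # reported mean is the arithmetic mean of the folds
        assert rep.mean["f2"] == pytest.approx(np.mean([m["f2"] for m in rep.per_fold]))

    def test_no_leakage_from_held_out_fold(self, toy_cohort):
        """Perturbing fold 3's held-out rows must not change anything fitted
        for fold 3 (scaler, grid choice): its training split is untouched.
        Other folds legitimately change, since fold 3's rows sit in their
        training splits."""
        spec = [ClassifierSpec("knn", grid={"n_neighbors": [3, 5, 7]})]
        r1 = nested_cv(toy_cohort, spec, seed=4, do_selection=False)
        folds = stratified_folds(toy_cohort.labels.to_numpy(), k=8, seed=4)
        perturbed = toy_cohort.features.copy()
        perturbed.loc[folds == 3] += 100.0
        r2 = nested_cv(
            FeatureTable(features=perturbed, labels=toy_cohort.labels), spec,
            seed=4, do_selection=False,
        )
        assert r1["knn"].chosen_params[3] == r2["knn"].chosen_params[3]
        assert r1["knn"].selected_features[3] == r2["knn"].selected_features[3]

    def test_report_serializes(self, toy_cohort, tmp_path):
        from aneufuse import io_core

        rep = nested_cv(
            toy_cohort, [ClassifierSpec("lr", grid={"C": [1.0]})], seed=0, do_selection=False
        )["lr"]
        path = str(tmp_path / "r.json")
        io_core.write_report({"lr": rep.to_dict()}, path)
        back = io_core.read_report(path)
        assert back["lr"]["mean"]["f2"] == rep.mean["f2"]
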