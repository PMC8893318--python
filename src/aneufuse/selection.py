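"""Feature fusion, standardization and two-step consensus feature selection.

The fused table has 136 columns: 25 morphological + 107 radiomics + 2 deep
+ 2 clinical (sex encoded female=0/male=1, age in years).

Selection runs over an 8-fold split of the rows it is given:

* Step 1 — on each fold's training split, fit a random forest and a
  gradient-boosted-tree model on standardized features; each method
  "selects" the features whose importance exceeds that method's mean
  importance; the fold keeps the features selected by BOTH methods; M is
  the union of the 8 per-fold intersections.
* Step 2 — accumulate each method's importances over the 8 folds, rank the
  features of M by the accumulated score, keep the top ceil(|M|/2) per
  method (M_r for the forest, M_x for boosting; ties broken by feature name)
  and return N = M_r ∩ M_x.

Degenerate fallbacks, each with a loud warning: empty M falls back to all
features; empty N falls back to M_r ∪ M_x.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .types import ValidationError

log = logging.getLogger(__name__)

EXPECTED_GROUP_SIZES = {"morph": 25, "radiomics": 107, "deep": 2, "clinical": 2}
N_FUSED_FEATURES = 136


@dataclass
class FeatureTable:
    """Per-case feature matrix plus binary labels, indexed by case id."""

    features: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValidationError("features and labels must share the same case index")
        if self.features.columns.duplicated().any():
            dup = self.features.columns[self.features.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate feature names: {dup}")
        if self.features.isna().any().any():
            bad = self.features.columns[self.features.isna().any()].tolist()
            raise ValidationError(f"missing values in features: {bad}")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValidationError("labels must be binary 0/1")

    @property
    def case_ids(self) -> list[str]:
        return list(self.features.index)

    def subset_rows(self, row_mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.features.loc[row_mask], self.labels.loc[row_mask])

    def subset_columns(self, names) -> "FeatureTable":
        return FeatureTable(self.features[list(names)], self.labels)


@dataclass
class ImportanceLedger:
    """Per-fold, per-method importance vectors and selected sets."""

    importances: dict = field(default_factory=dict)  # (fold, method) -> pd.Series
    selected: dict = field(default_factory=dict)  # (fold, method) -> set[str]

    def accumulated(self, method: str) -> pd.Series:
        series = [v for (f, m), v in self.importances.items() if m == method]
        if not series:
            raise ValidationError(f"no importances recorded for {method}")
        return sum(series[1:], series[0].copy())


@dataclass
class SelectionResult:
    M: set
    M_r: set
    M_x: set
    N: set
    ledger: ImportanceLedger | None = None


def fuse_features(
    morph: pd.DataFrame,
    radiomics: pd.DataFrame,
    deep: pd.DataFrame,
    clinical: pd.DataFrame,
    labels: pd.Series,
    strict: bool = True,
) -> FeatureTable:
    """Column-wise concatenation of the four groups with group-prefixed names.

    All groups must cover the same case ids.  With ``strict`` (default) the
    group widths must be 25/107/2/2 so the fused table has exactly 136
    columns.
    """
    groups = {"morph": morph, "radiomics": radiomics, "deep": deep, "clinical": clinical}
    ids = None
    for name, df in groups.items():
        if strict and df.shape[1] != EXPECTED_GROUP_SIZES[name]:
            raise ValidationError(
                f"group {name!r} has {df.shape[1]} features, expected "
                f"{EXPECTED_GROUP_SIZES[name]}"
            )
        cur = set(df.index)
        if ids is None:
            ids = cur
        elif cur != ids:
            missing = sorted(ids ^ cur)
            raise ValidationError(f"case-id mismatch in group {name!r}: {missing[:10]}")
    if set(labels.index) != ids:
        raise ValidationError("label case ids do not match feature groups")
    order = list(morph.index)
    parts = [
        groups[name].loc[order].add_prefix(f"{name}_") for name in ("morph", "radiomics", "deep", "clinical")
    ]
    fused = pd.concat(parts, axis=1)
    if strict:
        assert fused.shape[1] == N_FUSED_FEATURES
    return FeatureTable(features=fused, labels=labels.loc[order].astype(int))


@dataclass
class Standardizer:
    """Train-fitted per-feature z-scoring; constant columns map to 0."""

    mean: pd.Series
    scale: pd.Series
    constant_columns: list

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        return (features - self.mean) / self.scale


def standardize(train: pd.DataFrame, apply_to: pd.DataFrame | None = None):
    """Fit (x − μ_train)/σ_train (population σ) on ``train`` and apply it to
    ``apply_to`` (default: train itself).  σ = 0 columns are mapped to 0 and
    flagged on the returned scaler.  No information flows from ``apply_to``."""
    if train.shape[0] == 0:
        raise ValidationError("cannot standardize an empty training table")
    scaler = StandardScaler().fit(train.values)
    scale = pd.Series(scaler.scale_, index=train.columns)
    constant = list(train.columns[scaler.var_ == 0])
    if constant:
        log.info("constant columns mapped to 0 after standardization: %s", constant)
    std = Standardizer(
        mean=pd.Series(scaler.mean_, index=train.columns),
        scale=scale,
        constant_columns=constant,
    )
    target = train if apply_to is None else apply_to
    return std.transform(target), std


def _fit_importances(X: np.ndarray, y: np.ndarray, seed: int) -> dict[str, np.ndarray]:
    rf = RandomForestClassifier(n_estimators=300, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    xgb = XGBClassifier(
        n_estimators=100,
        max_depth=3,
        learning_rate=0.1,
        importance_type="total_gain",
        random_state=seed,
        verbosity=0,
        n_jobs=1,
        eval_metric="logloss",
    )
    xgb.fit(X, y)
    return {"rf": rf.feature_importances_, "xgb": xgb.feature_importances_}


def per_fold_select(
    train_features: pd.DataFrame, train_labels: pd.Series, fold_seed: int
) -> tuple[set, set, dict[str, pd.Series]]:
    """Fit RF and gradient boosting on one standardized training fold; each
    method selects the features with importance strictly above its mean
    importance.  Returns (S_rf, S_xgb, raw importance vectors)."""
    y = np.asarray(train_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("training fold contains a single class")
    Xstd, _ = standardize(train_features)
    imps = _fit_importances(Xstd.values, y, fold_seed)
    out_sets = {}
    out_imp = {}
    for method, vec in imps.items():
        s = pd.Series(vec, index=train_features.columns, dtype=float)
        thresh = float(s.mean())
        chosen = set(s.index[s > thresh])
        if not chosen:
            log.warning("method %s selected no features (all importances equal)", method)
        out_sets[method] = chosen
        out_imp[method] = s
    return out_sets["rf"], out_sets["xgb"], out_imp


def step1_union(per_fold_pairs: list[tuple[set, set]]) -> set:
    """Per fold keep S_rf ∩ S_xgb; M is the union over folds.  An empty M
    triggers the documented all-features fallback downstream."""
    m: set = set()
    for s_rf, s_xgb in per_fold_pairs:
        m |= s_rf & s_xgb
    if not m:
        log.warning("step 1 produced an empty M; caller will fall back to all features")
    return m


def _top_half(scores: pd.Series, members: set) -> set:
    k = math.ceil(len(members) / 2)
    sub = scores.loc[sorted(members)]  # lexicographic order breaks ties
    ranked = sub.sort_values(ascending=False, kind="stable")
    return set(ranked.index[:k])


def step2_intersect(M: set, ledger: ImportanceLedger) -> SelectionResult:
    """Rank M by accumulated importances; keep the top ceil(|M|/2) per method
    and intersect.  Empty N falls back to M_r ∪ M_x with a warning."""
    if not M:
        raise ValidationError("step 2 requires a non-empty M")
    acc_rf = ledger.accumulated("rf")
    acc_xgb = ledger.accumulated("xgb")
    m_r = _top_half(acc_rf, M)
    m_x = _top_half(acc_xgb, M)
    n = m_r & m_x
    if not n:
        log.warning("N = M_r ∩ M_x is empty; falling back to M_r ∪ M_x")
        n = m_r | m_x
    return SelectionResult(M=set(M), M_r=m_r, M_x=m_x, N=n, ledger=ledger)


def select_features(
    table: FeatureTable, fold_assignment: np.ndarray, seed: int
) -> SelectionResult:
    """Full two-step consensus selection over the given 8-fold assignment.

    For fold f the selection models see only rows with ``fold_assignment != f``
    (the fold's training split).  Deterministic given the seed.
    """
    folds = np.asarray(fold_assignment)
    fold_ids = np.unique(folds)
    ledger = ImportanceLedger()
    pairs = []
    for f in fold_ids:
        train = folds != f
        s_rf, s_xgb, imps = per_fold_select(
            table.features.loc[train], table.labels.loc[train], int(seed) + int(f)
        )
        ledger.importances[(int(f), "rf")] = imps["rf"]
        ledger.importances[(int(f), "xgb")] = imps["xgb"]
        ledger.selected[(int(f), "rf")] = s_rf
        ledger.selected[(int(f), "xgb")] = s_xgb
        pairs.append((s_rf, s_xgb))
    m = step1_union(pairs)
    if not m:
        m = set(table.features.columns)
    return step2_intersect(m, ledger)
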