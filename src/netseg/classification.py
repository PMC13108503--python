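"""Does system segregation add predictive value beyond cognition?

Two L2-regularized logistic regressions — one on cognitive composites alone,
one on cognition plus global SS across the sparsity grid — are compared for
their ability to distinguish the age groups. Both feature sets share one
stratified 70/30 train/test split and identical outer folds of a nested
five-fold cross-validation; the inner loop tunes the penalty strength on
validation AUC. Outer-fold metrics (AUC, accuracy, balanced accuracy) are
compared with paired t tests across the shared folds, and a final model per
feature set is refit on the full training portion and evaluated once on the
held-out 30%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from ._rng import substream
from .stats import TestResult

__all__ = [
    "ClassifierComparison",
    "NestedCVComparison",
    "nested_cv_logistic",
    "compare_feature_sets",
    "DEFAULT_PENALTY_GRID",
]

#: inverse regularization strengths searched in the inner loop
DEFAULT_PENALTY_GRID: tuple[float, ...] = tuple(np.logspace(-3, 3, 13))

METRICS = ("auc", "acc", "bacc")


@dataclass
class ClassifierComparison:
    """Fold-wise and held-out metrics for the compared feature sets."""

    fold_metrics: pd.DataFrame   # feature_set, fold, auc, acc, bacc, C
    test_metrics: pd.DataFrame   # feature_set, auc, acc, bacc, C
    paired_tests: pd.DataFrame   # metric, t, df, p (first vs second set)
    feature_sets: tuple[str, ...]
    fold_assignments: np.ndarray  # outer-fold id per training row
    train_indices: np.ndarray     # row positions of the training portion
    test_indices: np.ndarray      # row positions of the held-out portion


def _pipe(C: float) -> Pipeline:
    # scaling is fit inside each training portion only — no leakage
    return Pipeline(
        [
            ("scale", StandardScaler()),
            # default penalty is the L2 (ridge) norm; C is its inverse strength
            ("clf", LogisticRegression(C=C, max_iter=5000)),
        ]
    )


def _score(model, X, y) -> dict[str, float]:
    prob = model.predict_proba(X)[:, 1]
    pred = model.predict(X)
    return {
        "auc": float(roc_auc_score(y, prob)),
        "acc": float(np.mean(pred == y)),
        "bacc": float(balanced_accuracy_score(y, pred)),
    }


def _inner_select(X, y, grid, inner_k, rng_seed) -> float:
    """Penalty with the best mean validation AUC over inner folds."""
    inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=rng_seed)
    folds = list(inner.split(X, y))
    best_C, best_auc = grid[0], -np.inf
    for C in grid:
        aucs = []
        for tr, va in folds:
            model = _pipe(C).fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[va], model.predict_proba(X[va])[:, 1]))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best_auc, best_C = mean_auc, C
    return best_C


class NestedCVComparison(BaseEstimator):
    """Nested-CV logistic comparison of feature sets over identical folds.

    Parameters
    ----------
    outer_k, inner_k : int
        Outer and inner fold counts (both stratified, shuffled).
    penalty_grid : sequence of float
        Candidate inverse regularization strengths (L2).
    test_size : float
        Held-out fraction of the stratified initial split.
    seed : int or None
        Master seed; the split and fold assignment derive from its "folds"
        substream and depend only on the labels, never on features.

    After ``fit(frame, feature_sets, label_col)``: ``comparison_`` holds a
    :class:`ClassifierComparison`.
    """

    def __init__(self, outer_k: int = 5, inner_k: int = 5,
                 penalty_grid=DEFAULT_PENALTY_GRID,
                 test_size: float = 0.3, seed: int | None = None):
        self.outer_k = outer_k
        self.inner_k = inner_k
        self.penalty_grid = tuple(penalty_grid)
        self.test_size = test_size
        self.seed = seed

    def fit(self, frame: pd.DataFrame, feature_sets: dict[str, list[str]],
            label_col: str):
        all_cols = sorted({c for cols in feature_sets.values() for c in cols})
        data = frame[[label_col, *all_cols]].dropna()
        y_raw = data[label_col].to_numpy()
        classes = np.unique(y_raw)
        if len(classes) != 2:
            raise ValueError("need exactly 2 classes")
        y = (y_raw == classes[1]).astype(int)

        rng = (substream(self.seed, "folds") if self.seed is not None
               else np.random.default_rng())
        split_seed = int(rng.integers(0, 2**31 - 1))
        fold_seed = int(rng.integers(0, 2**31 - 1))
        inner_seed = int(rng.integers(0, 2**31 - 1))

        idx_train, idx_test = train_test_split(
            np.arange(len(y)), test_size=self.test_size, stratify=y,
            random_state=split_seed,
        )
        y_train, y_test = y[idx_train], y[idx_test]
        outer = StratifiedKFold(self.outer_k, shuffle=True, random_state=fold_seed)
        # folds fixed from labels alone; identical across feature sets
        outer_folds = list(outer.split(np.zeros_like(y_train), y_train))
        assignment = np.empty(len(y_train), dtype=int)
        for f, (_, va) in enumerate(outer_folds):
            assignment[va] = f

        fold_rows, test_rows = [], []
        for name, cols in feature_sets.items():
            X = data[list(cols)].to_numpy(float)
            X_train, X_test = X[idx_train], X[idx_test]
            for f, (tr, va) in enumerate(outer_folds):
                if len(np.unique(y_train[tr])) < 2 or len(np.unique(y_train[va])) < 2:
                    raise ValueError(f"outer fold {f} is missing a class")
                C = _inner_select(X_train[tr], y_train[tr], self.penalty_grid,
                                  self.inner_k, inner_seed)
                model = _pipe(C).fit(X_train[tr], y_train[tr])
                fold_rows.append(
                    {"feature_set": name, "fold": f, "C": C,
                     **_score(model, X_train[va], y_train[va])}
                )
            C_full = _inner_select(X_train, y_train, self.penalty_grid,
                                   self.inner_k, inner_seed)
            final = _pipe(C_full).fit(X_train, y_train)
            test_rows.append(
                {"feature_set": name, "C": C_full,
                 **_score(final, X_test, y_test)}
            )

        fold_metrics = pd.DataFrame(fold_rows)
        names = tuple(feature_sets)
        if len(names) >= 2:
            paired = compare_feature_sets(
                fold_metrics[fold_metrics["feature_set"] == names[0]],
                fold_metrics[fold_metrics["feature_set"] == names[1]],
            )
        else:
            paired = pd.DataFrame(columns=["metric", "t", "df", "p"])
        self.comparison_ = ClassifierComparison(
            fold_metrics=fold_metrics,
            test_metrics=pd.DataFrame(test_rows),
            paired_tests=paired,
            feature_sets=names,
            fold_assignments=assignment,
            train_indices=idx_train,
            test_indices=idx_test,
        )
        return self


def nested_cv_logistic(
    frame: pd.DataFrame,
    feature_sets: dict[str, list[str]],
    label_col: str,
    outer_k: int = 5,
    inner_k: int = 5,
    penalty_grid=DEFAULT_PENALTY_GRID,
    test_size: float = 0.3,
    seed: int | None = None,
) -> ClassifierComparison:
    """Functional wrapper over :class:`NestedCVComparison`."""
    est = NestedCVComparison(
        outer_k=outer_k, inner_k=inner_k, penalty_grid=penalty_grid,
        test_size=test_size, seed=seed,
    )
    return est.fit(frame, feature_sets, label_col).comparison_


def compare_feature_sets(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Two-sided paired t tests on fold-wise metrics of two feature sets.

    Expects frames with a ``fold`` column and the metric columns; rows are
    paired on fold id. Identical metric vectors yield t = 0 with p reported
    as 1 (non-significant by convention for the degenerate zero-variance
    difference).
    """
    a = a.sort_values("fold").reset_index(drop=True)
    b = b.sort_values("fold").reset_index(drop=True)
    if len(a) != len(b):
        raise ValueError("paired metric vectors must have equal length")
    rows = []
    for metric in METRICS:
        if metric not in a.columns or metric not in b.columns:
            continue
        diff = a[metric].to_numpy(float) - b[metric].to_numpy(float)
        dof = len(diff) - 1
        if np.ptp(diff) == 0:
            # zero-variance difference: degenerate paired t. All-zero is a
            # self-comparison (non-significant); an exactly constant nonzero
            # offset is unbounded evidence of a difference.
            if diff[0] == 0:
                t_val, p = 0.0, 1.0
            else:
                t_val, p = float(np.sign(diff[0]) * np.inf), 0.0
        else:
            t_val, p = sps.ttest_rel(a[metric], b[metric])
        rows.append({"metric": metric, "t": float(t_val), "df": dof,
                     "p": float(p)})
    return pd.DataFrame(rows)


def paired_t(a, b) -> TestResult:
    """Paired t test on two equal-length metric vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    t, p = sps.ttest_rel(a, b)
    if np.isnan(p):
        t, p = 0.0, 1.0
    return TestResult("t", float(t), (float(len(a) - 1),), float(p),
                      direction=float(np.sign(np.mean(a - b))))
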