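"""Linear-SVM phenotype stratification on the 11-metric battery.

The workflow mirrors the reference classification: per-feature min-max scaling
to [0, 1], a stratified 80/20 train/test split, a linear soft-margin SVM with
squared hinge loss and l2 penalty at C = 1, confusion-matrix rates with the
clinical group (ASD) as the positive class, and percentual feature-weight
contributions.

Scaling is fit on the training rows only by default (no test-set leakage);
``fit_scaling_on`` lets callers scale on the pooled sample instead, which is
what a whole-sample "rescaled (0 to 1)" preprocessing amounts to.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from .errors import ConvergenceError, HeadmorphError
from .phantom import METRIC_COLUMNS

__all__ = [
    "FeatureMatrix",
    "LinearModel",
    "ClassificationReport",
    "stratified_split",
    "prepare_features",
    "fit_linear_svm",
    "evaluate",
    "weight_contributions",
]

POSITIVE_CLASS = "ASD"


@dataclass
class FeatureMatrix:
    """Scaled feature rows with labels; scaling parameters retained."""

    X: np.ndarray
    y: np.ndarray  # +1 for the positive (ASD) class, -1 otherwise
    feature_names: tuple[str, ...]
    scale_min: np.ndarray
    scale_range: np.ndarray


@dataclass(frozen=True)
class LinearModel:
    weights: np.ndarray
    bias: float
    objective: float
    feature_names: tuple[str, ...]

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision(X) >= 0, 1, -1)


@dataclass(frozen=True)
class ClassificationReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float  # NaN when the test set has no positives
    specificity: float  # NaN when the test set has no negatives


def stratified_split(
    table: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    group_col: str = "group",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class proportional train/test split, deterministic given ``seed``.

    The total test size is ceil((1 - f) * n); per-class test counts are
    allocated by largest remainder, so 120 ASD + 136 HC at 0.8 gives exactly
    204 training and 52 test subjects.
    """
    if not 0 < train_fraction < 1:
        raise HeadmorphError("train_fraction must be in (0, 1)")
    groups = table[group_col]
    classes = list(pd.unique(groups))
    counts = {c: int((groups == c).sum()) for c in classes}
    if len(classes) < 2:
        raise HeadmorphError("need two classes to split")
    for c, n in counts.items():
        if n < 2:
            raise HeadmorphError(f"class '{c}' has fewer than 2 members")
    n_total = len(table)
    n_test = int(math.ceil((1.0 - train_fraction) * n_total))
    ideal = {c: (1.0 - train_fraction) * counts[c] for c in classes}
    test_counts = {c: int(math.floor(ideal[c])) for c in classes}
    short = n_test - sum(test_counts.values())
    for c in sorted(classes, key=lambda c: ideal[c] - math.floor(ideal[c]), reverse=True)[:short]:
        test_counts[c] += 1
    rng = np.random.default_rng(seed)
    test_idx = []
    for c in classes:
        members = np.flatnonzero((groups == c).to_numpy())
        test_idx.extend(members[rng.permutation(len(members))[: test_counts[c]]])
    test_mask = np.zeros(n_total, dtype=bool)
    test_mask[test_idx] = True
    return table.iloc[~test_mask].copy(), table.iloc[test_mask].copy()


def prepare_features(
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature_cols=METRIC_COLUMNS,
    group_col: str = "group",
    fit_scaling_on: str = "train",
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Min-max scale the feature columns and attach +-1 labels.

    Scaling parameters come from the training rows (default) or the pooled
    sample (``fit_scaling_on="all"``).  Test values are transformed with the
    training parameters and may fall outside [0, 1].  A constant scaling
    feature maps to zero everywhere, with a warning.
    """
    feature_cols = tuple(feature_cols)
    for df in (train, test):
        missing = [c for c in feature_cols if c not in df.columns]
        if missing:
            raise HeadmorphError(f"missing feature columns: {missing}")
    Xtr = train[list(feature_cols)].to_numpy(dtype=float)
    Xte = test[list(feature_cols)].to_numpy(dtype=float)
    if np.isnan(Xtr).any() or np.isnan(Xte).any():
        raise HeadmorphError("feature columns must be complete-case")
    basis = Xtr if fit_scaling_on == "train" else np.vstack([Xtr, Xte])
    lo = basis.min(axis=0)
    rng = basis.max(axis=0) - lo
    constant = rng == 0
    if constant.any():
        warnings.warn(
            f"constant features scaled to zero: {[feature_cols[i] for i in np.flatnonzero(constant)]}",
            stacklevel=2,
        )
    safe = np.where(constant, 1.0, rng)

    def build(df, X):
        y = np.where(df[group_col].to_numpy() == POSITIVE_CLASS, 1, -1)
        Xs = (X - lo) / safe
        Xs[:, constant] = 0.0
        return FeatureMatrix(
            X=Xs, y=y, feature_names=feature_cols, scale_min=lo, scale_range=rng
        )

    return build(train, Xtr), build(test, Xte)


def fit_linear_svm(train: FeatureMatrix, C: float = 1.0, tol: float = 1e-6) -> LinearModel:
    """Fit the linear soft-margin SVM: min 1/2 ||w||^2 + C sum max(0, 1 - y f)^2.

    Solved in the primal (deterministic for fixed data); refuses to return a
    model that did not reach the convergence tolerance within the iteration cap.
    """
    if len(np.unique(train.y)) < 2:
        raise HeadmorphError("training data must contain both classes")
    svc = LinearSVC(
        C=C,
        loss="squared_hinge",
        penalty="l2",
        dual=False,
        tol=tol,
        max_iter=100_000,
        fit_intercept=True,
        intercept_scaling=10.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            svc.fit(train.X, train.y)
        except UserWarning as exc:  # liblinear ConvergenceWarning subclasses UserWarning
            raise ConvergenceError(f"linear SVM did not converge: {exc}") from exc
    w = svc.coef_.ravel().astype(float)
    b = float(svc.intercept_[0])
    margins = 1.0 - train.y * (train.X @ w + b)
    objective = 0.5 * float(w @ w) + C * float(np.clip(margins, 0, None) ** 2 @ np.ones(len(margins)))
    return LinearModel(weights=w, bias=b, objective=objective, feature_names=train.feature_names)


def evaluate(model: LinearModel, test: FeatureMatrix) -> ClassificationReport:
    """Confusion counts and accuracy/sensitivity/specificity on the test set."""
    if len(test.y) == 0:
        raise HeadmorphError("test set is empty")
    pred = model.predict(test.X)
    tp = int(np.sum((pred == 1) & (test.y == 1)))
    fp = int(np.sum((pred == 1) & (test.y == -1)))
    tn = int(np.sum((pred == -1) & (test.y == -1)))
    fn = int(np.sum((pred == -1) & (test.y == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    return ClassificationReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=(tp + tn) / len(test.y),
        sensitivity=tp / n_pos if n_pos else float("nan"),
        specificity=tn / n_neg if n_neg else float("nan"),
    )


def weight_contributions(model: LinearModel) -> dict[str, float]:
    """Percentual contribution 100 |w_i| / sum |w_j| per feature; sums to 100."""
    total = float(np.abs(model.weights).sum())
    if total == 0:
        warnings.warn("all SVM weights are zero; contributions undefined", stacklevel=2)
        return {name: float("nan") for name in model.feature_names}
    return {
        name: 100.0 * abs(float(w)) / total
        for name, w in zip(model.feature_names, model.weights)
    }
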