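"""Feature scaling, RBF-SVM training with grid search, and evaluation.

All descriptors are min-max normalized to [0, 1] with
``(value - minimum) / (maximum - minimum)`` using the training split's
minima/maxima; values outside the training range at prediction time are
clipped, and zero-range features map to 0.  The classifier is an RBF-kernel
SVM tuned by grid search over (C, gamma), scored by mean accuracy under
stratified k-fold cross-validation, and refit on the full training data
with the winning pair.

Six evaluation indices are reported: overall accuracy (Acc), area under
the ROC curve (AUC, computed from decision values), F-score, sensitivity
(Sen), specificity (Sp) and Matthews correlation coefficient (MCC):

    Acc  = (TP + TN) / (TP + TN + FP + FN)
    F    = 2 TP / (2 TP + FP + FN)
    Sen  = TP / (TP + FN)
    Sp   = TN / (TN + FP)
    MCC  = (TP*TN - FN*FP) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))

Cross-validated results are reported as the average of the per-fold
metrics (pooling the fold confusions instead is available by flag).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .exceptions import SchemaError, ValidationError

logger = logging.getLogger(__name__)

METRIC_NAMES = ("Acc", "AUC", "F-score", "Sen", "Sp", "MCC")


# ---------------------------------------------------------------------------
# scaling

@dataclass
class MinMaxScaler01:
    """Per-feature [0, 1] min-max scaling with clipping at apply time."""

    feature_names: tuple[str, ...]
    mins: np.ndarray = field(repr=False)
    maxs: np.ndarray = field(repr=False)


def fit_scaler(X: pd.DataFrame) -> MinMaxScaler01:
    """Fit scaling parameters on the training split only."""
    return MinMaxScaler01(
        feature_names=tuple(X.columns),
        mins=X.to_numpy(dtype=float).min(axis=0),
        maxs=X.to_numpy(dtype=float).max(axis=0),
    )


def apply_scaler(scaler: MinMaxScaler01, X: pd.DataFrame) -> pd.DataFrame:
    """Scale to [0, 1]; out-of-range values are clipped, zero-range features
    map to 0.  Column schema must match the fitted scaler exactly."""
    if tuple(X.columns) != scaler.feature_names:
        missing = set(scaler.feature_names) - set(X.columns)
        extra = set(X.columns) - set(scaler.feature_names)
        raise SchemaError(
            f"feature schema mismatch at apply time "
            f"(missing: {sorted(missing)[:3]}..., unexpected: {sorted(extra)[:3]}...)"
            if missing or extra
            else "feature order differs from the fitted scaler"
        )
    arr = X.to_numpy(dtype=float)
    span = scaler.maxs - scaler.mins
    safe = np.where(span > 0, span, 1.0)
    scaled = np.clip((arr - scaler.mins) / safe, 0.0, 1.0)
    scaled[:, span == 0] = 0.0
    return pd.DataFrame(scaled, index=X.index, columns=X.columns)


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvalReport:
    """Confusion counts plus the six evaluation indices."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    auc: float
    fscore: float
    sen: float
    sp: float
    mcc: float

    @classmethod
    def from_counts(cls, tp: int, tn: int, fp: int, fn: int, auc: float = float("nan")) -> "EvalReport":
        """Compute the metric formulas from a confusion table."""
        n = tp + tn + fp + fn
        if n == 0:
            raise ValidationError("empty confusion table")
        acc = (tp + tn) / n
        sen = tp / (tp + fn) if tp + fn else 0.0
        sp = tn / (tn + fp) if tn + fp else 0.0
        fscore = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
        if denom == 0:
            logger.warning("MCC denominator has a zero factor; reporting MCC = 0")
            mcc = 0.0
        else:
            mcc = (tp * tn - fn * fp) / math.sqrt(denom)
        return cls(tp, tn, fp, fn, acc, auc, fscore, sen, sp, mcc)

    @classmethod
    def from_predictions(
        cls,
        y_true: np.ndarray,
        y_pred: np.ndarray,
        decision_values: np.ndarray | None = None,
    ) -> "EvalReport":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        if y_true.shape != y_pred.shape:
            raise ValidationError("prediction/label vectors differ in length")
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        tn = int(np.sum((y_true == 0) & (y_pred == 0)))
        fp = int(np.sum((y_true == 0) & (y_pred == 1)))
        fn = int(np.sum((y_true == 1) & (y_pred == 0)))
        auc = float("nan")
        if decision_values is not None and len(np.unique(y_true)) == 2:
            auc = float(roc_auc_score(y_true, decision_values))
        return cls.from_counts(tp, tn, fp, fn, auc)

    def as_dict(self) -> dict[str, float]:
        return {
            "Acc": self.acc,
            "AUC": self.auc,
            "F-score": self.fscore,
            "Sen": self.sen,
            "Sp": self.sp,
            "MCC": self.mcc,
        }


evaluate = EvalReport.from_predictions


def average_reports(reports: Sequence[EvalReport]) -> dict[str, float]:
    """Average per-fold metrics (the default CV reporting convention)."""
    out: dict[str, float] = {}
    for key in METRIC_NAMES:
        vals = [v for r in reports if not math.isnan(v := r.as_dict()[key])]
        out[key] = float(np.mean(vals)) if vals else float("nan")
    return out


def pool_reports(reports: Sequence[EvalReport]) -> EvalReport:
    """Alternative CV reporting: pool the fold confusion counts."""
    aucs = [r.auc for r in reports if not math.isnan(r.auc)]
    return EvalReport.from_counts(
        tp=sum(r.tp for r in reports),
        tn=sum(r.tn for r in reports),
        fp=sum(r.fp for r in reports),
        fn=sum(r.fn for r in reports),
        auc=float(np.mean(aucs)) if aucs else float("nan"),
    )


# ---------------------------------------------------------------------------
# SVM training

def default_grid() -> list[tuple[float, float]]:
    """The practical-guide search grid: C = 2^-5..2^15, gamma = 2^-15..2^3,
    both in steps of 2^2."""
    cs = 2.0 ** np.arange(-5, 16, 2)
    gammas = 2.0 ** np.arange(-15, 4, 2)
    return [(float(c), float(g)) for c in cs for g in gammas]


def fast_grid() -> list[tuple[float, float]]:
    """A coarse 2x2 sub-grid for quick runs and simulations."""
    return [(float(c), float(g)) for c in (1.0, 32.0) for g in (2.0**-5, 0.5)]


@dataclass
class TrainedModel:
    """A fitted scaler + RBF-SVM with everything needed to reproduce
    predictions: selected feature names, scaling parameters, (C, gamma)
    and metadata."""

    feature_names: tuple[str, ...]
    scaler: MinMaxScaler01
    C: float
    gamma: float
    svc: SVC = field(repr=False)
    seed: int = 0
    cv_report: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def _prepare(self, X: pd.DataFrame) -> pd.DataFrame:
        try:
            sub = X[list(self.feature_names)]
        except KeyError as exc:
            raise SchemaError(f"input matrix is missing model feature(s): {exc}") from None
        return apply_scaler(self.scaler, sub)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.svc.predict(self._prepare(X)).astype(int)

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return self.svc.decision_function(self._prepare(X))


@dataclass
class GridSearchResult:
    C: float
    gamma: float
    cv_report: dict[str, float]
    fold_reports: list[EvalReport] = field(default_factory=list)


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValidationError(f"need binary 0/1 labels with both classes, got {classes}")
    return y


def grid_search_svm(
    X: pd.DataFrame,
    y: np.ndarray,
    grid: Iterable[tuple[float, float]] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Choose (C, gamma) by highest mean CV accuracy over the grid.

    Scaling is refit inside every fold on that fold's training part, so no
    test-fold statistics leak into the model.  Ties go to the earlier grid
    pair.  Returns the winning pair with its per-fold and averaged metrics.
    """
    y = _check_labels(y)
    pairs = list(grid) if grid is not None else default_grid()
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(y)), y))
    reports: dict[int, list[EvalReport]] = {i: [] for i in range(len(pairs))}
    for train_idx, test_idx in folds:
        scaler = fit_scaler(X.iloc[train_idx])
        Xtr = apply_scaler(scaler, X.iloc[train_idx])
        Xte = apply_scaler(scaler, X.iloc[test_idx])
        ytr, yte = y[train_idx], y[test_idx]
        for i, (c, g) in enumerate(pairs):
            svc = SVC(C=c, gamma=g, kernel="rbf")
            svc.fit(Xtr, ytr)
            reports[i].append(
                EvalReport.from_predictions(yte, svc.predict(Xte), svc.decision_function(Xte))
            )
    mean_acc = [average_reports(reports[i])["Acc"] for i in range(len(pairs))]
    best = int(np.argmax(mean_acc))
    c, g = pairs[best]
    return GridSearchResult(
        C=c, gamma=g, cv_report=average_reports(reports[best]), fold_reports=reports[best]
    )


def train_svm(
    X: pd.DataFrame,
    y: np.ndarray,
    grid: Iterable[tuple[float, float]] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    metadata: dict | None = None,
) -> TrainedModel:
    """Grid-search (C, gamma) by CV accuracy, then refit scaler + SVM on the
    full training data with the winning pair."""
    y = _check_labels(y)
    search = grid_search_svm(X, y, grid=grid, cv_folds=cv_folds, seed=seed)
    scaler = fit_scaler(X)
    svc = SVC(C=search.C, gamma=search.gamma, kernel="rbf")
    svc.fit(apply_scaler(scaler, X), y)
    return TrainedModel(
        feature_names=tuple(X.columns),
        scaler=scaler,
        C=search.C,
        gamma=search.gamma,
        svc=svc,
        seed=seed,
        cv_report=search.cv_report,
        metadata=metadata or {},
    )
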