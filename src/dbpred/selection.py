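"""mRMR feature ranking and MCC-driven incremental feature selection (IFS).

The ranking discretizes each feature into three states at mean +/- t*std
(t = 1 by default, population standard deviation), measures relevance and
redundancy with plug-in mutual information (log base 2) on the discretized
states, and greedily builds the ranking with the MID ("difference")
criterion: step m+1 picks the feature maximizing

    I(f; class) - (1/m) * sum_{s in selected} I(f; f_s)

with deterministic ties broken toward the smaller original column index.
Because discretization uses each feature's own mean and standard deviation,
the ranking is invariant to affine rescaling of any feature.

IFS then evaluates growing prefixes of the ranking with a cross-validated
SVM and keeps the smallest prefix attaining the peak mean MCC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


def discretize(values: np.ndarray, t: float = 1.0, ddof: int = 0) -> np.ndarray:
    """Discretize one feature into 3 states: 0 if v < mean - t*std, 2 if
    v > mean + t*std, else 1.  Zero-variance features are all state 1."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValidationError("discretize expects a vector of >= 2 samples")
    return _discretize_matrix(values[:, None], t, ddof)[:, 0]


def _discretize_matrix(X: np.ndarray, t: float, ddof: int = 0) -> np.ndarray:
    """Column-wise 3-state discretization of an n x d matrix."""
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=ddof)
    states = np.ones(X.shape, dtype=np.int8)
    states[X < mean - t * std] = 0
    states[X > mean + t * std] = 2
    return states


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two discrete label vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("mutual_information expects two equal-length vectors")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    return _mi_from_counts(joint)


def _mi_from_counts(joint: np.ndarray) -> float:
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def _mi_columns_vs(states: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """MI (bits) of every column of a 3-state matrix against one 3-state
    reference vector, vectorized over columns."""
    n, d = states.shape
    counts = np.zeros((3, 3, d))
    for b in range(3):
        rows = ref == b
        if not rows.any():
            continue
        sub = states[rows]
        for a in range(3):
            counts[a, b] = (sub == a).sum(axis=0)
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return np.nansum(terms, axis=(0, 1))


@dataclass
class MRMRRanking:
    """Ordered mRMR feature ranking with per-step relevance/redundancy and
    the discretization parameters used."""

    indices: np.ndarray
    feature_names: tuple[str, ...]
    relevance: np.ndarray  # I(f; class) at each ranked position
    redundancy: np.ndarray  # mean MI vs previously selected, 0 for the first
    t: float
    means: np.ndarray = field(repr=False, default=None)
    stds: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.indices)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "feature_name": list(self.feature_names),
                "relevance": self.relevance,
                "redundancy": self.redundancy,
            }
        )


def mrmr_rank(
    X: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    top_k: int = 1000,
    t: float = 1.0,
    ddof: int = 0,
) -> MRMRRanking:
    """Greedy mRMR (MID) ranking of the first ``top_k`` features.

    The first feature maximizes relevance I(f; class); every later step
    maximizes relevance minus the mean MI against already-selected features.
    Deterministic: ties go to the smaller original column index.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(arr.shape[1])]
    labels = np.asarray(labels)
    n, d = arr.shape
    if len(labels) != n:
        raise ValidationError("labels length does not match sample count")
    if len(np.unique(labels)) < 2:
        raise ValidationError("mrmr_rank requires both classes present")
    if top_k > d:
        logger.warning("top_k=%d exceeds %d features; truncating", top_k, d)
        top_k = d

    states = _discretize_matrix(arr, t, ddof)
    _, y = np.unique(labels, return_inverse=True)
    y = y.astype(np.int8)

    relevance = _mi_columns_vs(states, y)
    selected: list[int] = []
    rel_out: list[float] = []
    red_out: list[float] = []
    red_sum = np.zeros(d)
    score = relevance.copy()
    for step in range(top_k):
        j = int(np.argmax(score))  # argmax takes the first (smallest) index on ties
        selected.append(j)
        rel_out.append(float(relevance[j]))
        red_out.append(float(red_sum[j] / step) if step else 0.0)
        score[j] = -np.inf
        if step + 1 < top_k:
            red_sum += _mi_columns_vs(states, states[:, j])
            active = np.isfinite(score)
            score[active] = relevance[active] - red_sum[active] / (step + 1)

    idx = np.array(selected)
    return MRMRRanking(
        indices=idx,
        feature_names=tuple(names[i] for i in selected),
        relevance=np.array(rel_out),
        redundancy=np.array(red_out),
        t=t,
        means=arr.mean(axis=0),
        stds=arr.std(axis=0, ddof=ddof),
    )


@dataclass
class IFSResult:
    """IFS curve: mean CV MCC per evaluated prefix size, and its peak."""

    counts: np.ndarray
    mcc_curve: np.ndarray
    optimal_count: int
    optimal_features: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_features": self.counts, "mean_mcc": self.mcc_curve})


def ifs(
    X: pd.DataFrame,
    labels: np.ndarray,
    ranking: MRMRRanking,
    cv_folds: int = 5,
    step: int = 1,
    seed: int = 0,
    grid: "object | None" = None,
    max_features: int | None = None,
) -> IFSResult:
    """Incremental feature selection along an mRMR ranking.

    For each prefix size (1, 1+step, ...) the modeling module's RBF-SVM is
    tuned by grid search and scored by stratified ``cv_folds``-fold CV; the
    mean per-fold MCC forms the IFS curve.  The optimal count is the
    smallest prefix attaining the curve maximum (parsimony tie-break).
    """
    from .modeling import grid_search_svm  # deferred: modeling imports selection types

    labels = np.asarray(labels)
    names = list(ranking.feature_names)
    limit = len(names) if max_features is None else min(max_features, len(names))
    sizes = list(range(1, limit + 1, step))
    if sizes[-1] != limit:
        sizes.append(limit)
    curve = np.empty(len(sizes))
    for i, k in enumerate(sizes):
        sub = X[names[:k]]
        result = grid_search_svm(sub, labels, grid=grid, cv_folds=cv_folds, seed=seed)
        curve[i] = result.cv_report["MCC"]
    best = int(np.argmax(curve))  # first (smallest prefix) on ties
    k_opt = sizes[best]
    return IFSResult(
        counts=np.array(sizes),
        mcc_curve=curve,
        optimal_count=k_opt,
        optimal_features=tuple(names[:k_opt]),
    )
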