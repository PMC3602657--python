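"""Combine the 12 per-block SVM modules by majority voting or stacking.

Each descriptor block (OAAC, DPC, ..., S&F-SAA) gets its own scaled
RBF-SVM.  Two combiners are provided:

* **voting** — a protein is called binding when strictly more than
  ``threshold`` of the 12 modules vote binding (default threshold 6, so a
  6-6 tie resolves to non-binding).
* **stacking** — a meta RBF-SVM is trained on the 12 base decision values.
  Meta-training uses out-of-fold decision values (internal stratified
  5-fold) so the meta-learner never sees a decision value produced by a
  base model trained on the same sample; the base models themselves are
  refit on the full training data afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .exceptions import ValidationError
from .modeling import TrainedModel, train_svm
from .transforms import BLOCK_ORDER

N_MODULES = len(BLOCK_ORDER)  # 12


def vote(votes: Sequence[int], threshold: int = 6, n_models: int = N_MODULES) -> int:
    """Majority vote: binding (1) iff binding votes > ``threshold``.

    With the default threshold of 6 out of 12 modules, a 6-6 tie resolves
    to non-binding (ties were observed to be mostly non-binding proteins).
    """
    votes = list(votes)
    if len(votes) != n_models:
        raise ValidationError(f"expected {n_models} votes, got {len(votes)}")
    if any(v not in (0, 1) for v in votes):
        raise ValidationError("votes must be binary 0/1")
    return int(sum(votes) > threshold)


def out_of_fold_decisions(
    blocks: Mapping[str, pd.DataFrame],
    y: np.ndarray,
    fit_fn: Callable[[pd.DataFrame, np.ndarray], TrainedModel],
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Out-of-fold base-model decision values for stacking.

    For every internal fold, base models are fit per block on the fold's
    training part only, and their decision values are recorded for the
    held-out part.  Returns the n x n_blocks meta-feature frame and, for
    auditing, the fold id that produced each sample's meta-features (sample
    i's features come from models that never saw sample i).
    """
    y = np.asarray(y).astype(int)
    names = list(blocks.keys())
    n = len(y)
    meta = np.full((n, len(names)), np.nan)
    fold_of = np.full(n, -1)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for fold_id, (train_idx, test_idx) in enumerate(skf.split(np.zeros(n), y)):
        for j, name in enumerate(names):
            Xb = blocks[name]
            model = fit_fn(Xb.iloc[train_idx], y[train_idx])
            meta[test_idx, j] = model.decision_function(Xb.iloc[test_idx])
        fold_of[test_idx] = fold_id
    index = next(iter(blocks.values())).index
    return pd.DataFrame(meta, index=index, columns=names), fold_of


@dataclass
class EnsembleModel:
    """12 base models (fixed block order) plus a combiner."""

    base_models: dict[str, TrainedModel]
    combiner: str  # "voting" | "stacking"
    threshold: int = 6
    meta_model: TrainedModel | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if tuple(self.base_models.keys()) != tuple(BLOCK_ORDER):
            raise ValidationError(
                f"ensemble requires exactly the {N_MODULES} blocks in order {BLOCK_ORDER}"
            )
        if self.combiner not in ("voting", "stacking"):
            raise ValidationError(f"unknown combiner {self.combiner!r}")
        if self.combiner == "stacking" and self.meta_model is None:
            raise ValidationError("stacking ensemble requires a meta model")

    def base_decisions(self, blocks: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
        self._check_blocks(blocks)
        cols = {
            name: model.decision_function(blocks[name])
            for name, model in self.base_models.items()
        }
        index = next(iter(blocks.values())).index
        return pd.DataFrame(cols, index=index, columns=list(self.base_models))

    def predict(self, blocks: Mapping[str, pd.DataFrame]) -> np.ndarray:
        self._check_blocks(blocks)
        if self.combiner == "voting":
            votes = np.column_stack(
                [m.predict(blocks[name]) for name, m in self.base_models.items()]
            )
            return np.array([vote(row, self.threshold) for row in votes])
        meta_X = self.base_decisions(blocks)
        return self.meta_model.predict(meta_X)

    def decision_function(self, blocks: Mapping[str, pd.DataFrame]) -> np.ndarray:
        """A real-valued score: vote count margin for voting, meta decision
        values for stacking."""
        if self.combiner == "voting":
            votes = np.column_stack(
                [m.predict(blocks[name]) for name, m in self.base_models.items()]
            )
            return votes.sum(axis=1) - self.threshold
        return self.meta_model.decision_function(self.base_decisions(blocks))

    def _check_blocks(self, blocks: Mapping[str, pd.DataFrame]) -> None:
        missing = [b for b in self.base_models if b not in blocks]
        if missing:
            raise ValidationError(f"missing descriptor block(s): {', '.join(missing)}")


def train_ensemble(
    blocks: Mapping[str, pd.DataFrame],
    y: np.ndarray,
    combiner: str = "stacking",
    threshold: int = 6,
    grid: Iterable[tuple[float, float]] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> EnsembleModel:
    """Train the 12 base SVMs (one per descriptor block) and the combiner.

    ``blocks`` maps block name -> per-block feature frame over the same
    samples, and must contain every block in the fixed order.
    """
    missing = [b for b in BLOCK_ORDER if b not in blocks]
    if missing:
        raise ValidationError(f"missing descriptor block(s): {', '.join(missing)}")
    ordered = {b: blocks[b] for b in BLOCK_ORDER}
    y = np.asarray(y).astype(int)

    def fit_fn(Xb: pd.DataFrame, yb: np.ndarray) -> TrainedModel:
        return train_svm(Xb, yb, grid=grid, cv_folds=cv_folds, seed=seed)

    meta_model = None
    if combiner == "stacking":
        meta_X, _ = out_of_fold_decisions(ordered, y, fit_fn, cv_folds=cv_folds, seed=seed)
        meta_model = train_svm(meta_X, y, grid=grid, cv_folds=cv_folds, seed=seed)
    base_models = {name: fit_fn(Xb, y) for name, Xb in ordered.items()}
    return EnsembleModel(
        base_models=base_models,
        combiner=combiner,
        threshold=threshold,
        meta_model=meta_model,
    )
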