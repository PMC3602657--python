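"""End-to-end orchestration: featurize -> select -> train -> evaluate.

Two final-model strategies are provided as co-equal outputs:

* :func:`run_feature_selection_protocol` — pool all descriptor blocks
  (DPC reduced to its fold-selected 400), rank by mRMR, pick the IFS peak
  prefix and train one RBF-SVM on it;
* :func:`run_ensemble_protocol` — one RBF-SVM per descriptor block,
  combined by majority voting or by stacking on decision values.

Both are evaluated by stratified outer cross-validation in which every
data-dependent step (DPC reduction, scaling, mRMR ranking, IFS, base and
meta model fits) is re-fit inside the training fold only.  Callers can
pass an ``audit`` list to receive ``(stage, fold, train_index)`` events,
which the test suite uses to prove no test-fold sample ever reaches a
fitting step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .composition import dpc_select
from .ensemble import EnsembleModel, train_ensemble
from .exceptions import ValidationError
from .modeling import (
    EvalReport,
    TrainedModel,
    average_reports,
    train_svm,
)
from .selection import IFSResult, ifs, mrmr_rank
from .sequence_io import ProteinRecord
from .track_providers import PropertyTrackSet
from .transforms import BLOCK_ORDER, DEFAULT_CONFIG, TransformConfig, assemble

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# featurization

def featurize(
    records: Iterable[ProteinRecord],
    tracks_by_id: Mapping[str, Mapping[str, PropertyTrackSet]],
    cfg: TransformConfig = DEFAULT_CONFIG,
    require: tuple[str, ...] = ("aaindex", "pssm", "ssf"),
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Build the raw feature matrix: one row per protein, DPC at its full
    1200 dimensions (reduction to 400 happens inside training folds).

    Returns the matrix and the block schema ``{block_name: column_names}``
    (fixed order, identical across proteins).  With all three track
    sources the raw matrix has 2840 columns; 2040 after DPC selection.
    """
    rows = []
    ids = []
    schema: dict[str, list[str]] | None = None
    for record in records:
        tracks = tracks_by_id[record.id]
        blocks = assemble(
            record,
            tracks.get("aaindex"),
            tracks.get("pssm"),
            tracks.get("ssf"),
            cfg,
            require=require,
        )
        this_schema = {b.block_name: list(b.feature_names) for b in blocks}
        if schema is None:
            schema = this_schema
        elif this_schema != schema:
            raise ValidationError(f"{record.id}: descriptor schema differs across proteins")
        rows.append(np.concatenate([b.values for b in blocks]))
        ids.append(record.id)
    if schema is None:
        raise ValidationError("no records to featurize")
    columns = [name for names in schema.values() for name in names]
    return pd.DataFrame(np.vstack(rows), index=ids, columns=columns), schema


def labels_vector(records: Iterable[ProteinRecord]) -> np.ndarray:
    labels = [r.label for r in records]
    if any(l is None for l in labels):
        raise ValidationError("every record needs a 0/1 label for training")
    return np.asarray(labels, dtype=int)


def _select_columns(
    X: pd.DataFrame,
    schema: Mapping[str, list[str]],
    dpc_names: list[str] | None,
) -> list[str]:
    """Column list in block order with DPC replaced by its selected subset."""
    cols: list[str] = []
    for block, names in schema.items():
        if block == "DPC" and dpc_names is not None:
            cols.extend(dpc_names)
        else:
            cols.extend(names)
    return cols


def _blocks_view(
    X: pd.DataFrame,
    schema: Mapping[str, list[str]],
    dpc_names: list[str] | None,
) -> dict[str, pd.DataFrame]:
    out = {}
    for block, names in schema.items():
        use = dpc_names if (block == "DPC" and dpc_names is not None) else names
        out[block] = X[use]
    return out


def _audit_event(audit, stage: str, fold: int, train_idx: np.ndarray) -> None:
    if audit is not None:
        audit.append((stage, fold, tuple(int(i) for i in train_idx)))


# ---------------------------------------------------------------------------
# protocol A: pooled features + mRMR-IFS + single SVM

@dataclass
class SelectionProtocolResult:
    fold_reports: list[EvalReport]
    cv_report: dict[str, float]
    fold_ifs: list[IFSResult]
    final_model: TrainedModel | None
    final_ifs: IFSResult | None
    final_dpc_names: list[str] | None = field(default=None, repr=False)


def _fit_selection_stage(
    X: pd.DataFrame,
    y: np.ndarray,
    schema: Mapping[str, list[str]],
    top_k: int,
    step: int,
    t: float,
    cv_folds: int,
    seed: int,
    grid,
    max_features: int | None,
):
    """dpc_select + mRMR + IFS + final SVM on one training set."""
    dpc_names = None
    if "DPC" in schema:
        dpc_names = dpc_select(X[schema["DPC"]], y, t=t)
    cols = _select_columns(X, schema, dpc_names)
    ranking = mrmr_rank(X[cols], y, top_k=top_k, t=t)
    ifs_result = ifs(
        X[cols], y, ranking, cv_folds=cv_folds, step=step, seed=seed,
        grid=grid, max_features=max_features,
    )
    model = train_svm(
        X[list(ifs_result.optimal_features)], y, grid=grid, cv_folds=cv_folds, seed=seed
    )
    return dpc_names, ranking, ifs_result, model


def run_feature_selection_protocol(
    X: pd.DataFrame,
    y: np.ndarray,
    schema: Mapping[str, list[str]],
    top_k: int = 1000,
    step: int = 1,
    t: float = 1.0,
    outer_folds: int = 5,
    inner_folds: int = 5,
    seed: int = 0,
    grid=None,
    max_features: int | None = None,
    fit_final: bool = True,
    audit: list | None = None,
) -> SelectionProtocolResult:
    """Outer-CV evaluation of the mRMR-IFS single-SVM strategy.

    Every data-dependent step is re-fit per outer training fold; the
    per-fold test metrics are averaged into ``cv_report``.  When
    ``fit_final`` is set, the same stages are re-run on the full data to
    produce a deployable model.
    """
    y = np.asarray(y).astype(int)
    skf = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    fold_reports: list[EvalReport] = []
    fold_ifs: list[IFSResult] = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        Xtr, ytr = X.iloc[tr], y[tr]
        _audit_event(audit, "dpc_select", fold, tr)
        _audit_event(audit, "mrmr", fold, tr)
        _audit_event(audit, "ifs", fold, tr)
        _audit_event(audit, "scaler", fold, tr)
        _, _, ifs_result, model = _fit_selection_stage(
            Xtr, ytr, schema, top_k, step, t, inner_folds, seed, grid, max_features
        )
        fold_ifs.append(ifs_result)
        Xte = X.iloc[te][list(model.feature_names)]
        report = EvalReport.from_predictions(
            y[te], model.predict(Xte), model.decision_function(Xte)
        )
        fold_reports.append(report)
        logger.info(
            "fold %d: %d features, test MCC %.3f", fold, ifs_result.optimal_count, report.mcc
        )
    final_model = final_ifs = final_dpc = None
    if fit_final:
        final_dpc, _, final_ifs, final_model = _fit_selection_stage(
            X, y, schema, top_k, step, t, inner_folds, seed, grid, max_features
        )
    return SelectionProtocolResult(
        fold_reports=fold_reports,
        cv_report=average_reports(fold_reports),
        fold_ifs=fold_ifs,
        final_model=final_model,
        final_ifs=final_ifs,
        final_dpc_names=final_dpc,
    )


# ---------------------------------------------------------------------------
# protocol B: 12 per-block SVMs + voting / stacking

@dataclass
class EnsembleProtocolResult:
    combiner: str
    fold_reports: list[EvalReport]
    cv_report: dict[str, float]
    final_model: EnsembleModel | None


def run_ensemble_protocol(
    X: pd.DataFrame,
    y: np.ndarray,
    schema: Mapping[str, list[str]],
    combiner: str = "stacking",
    threshold: int = 6,
    t: float = 1.0,
    outer_folds: int = 5,
    inner_folds: int = 5,
    seed: int = 0,
    grid=None,
    fit_final: bool = True,
    audit: list | None = None,
) -> EnsembleProtocolResult:
    """Outer-CV evaluation of the 12-module ensemble (voting or stacking)."""
    missing = [b for b in BLOCK_ORDER if b not in schema]
    if missing:
        raise ValidationError(
            f"ensemble protocol needs all 12 blocks; missing: {', '.join(missing)}"
        )
    y = np.asarray(y).astype(int)
    skf = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    fold_reports: list[EvalReport] = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        Xtr, ytr = X.iloc[tr], y[tr]
        dpc_names = dpc_select(Xtr[schema["DPC"]], ytr, t=t)
        _audit_event(audit, "dpc_select", fold, tr)
        _audit_event(audit, "base_models", fold, tr)
        _audit_event(audit, "meta_model", fold, tr)
        blocks_tr = _blocks_view(Xtr, schema, dpc_names)
        model = train_ensemble(
            blocks_tr, ytr, combiner=combiner, threshold=threshold,
            grid=grid, cv_folds=inner_folds, seed=seed,
        )
        blocks_te = _blocks_view(X.iloc[te], schema, dpc_names)
        pred = model.predict(blocks_te)
        decision = model.decision_function(blocks_te)
        fold_reports.append(EvalReport.from_predictions(y[te], pred, decision))
    final_model = None
    if fit_final:
        dpc_names = dpc_select(X[schema["DPC"]], y, t=t)
        final_model = train_ensemble(
            _blocks_view(X, schema, dpc_names), y, combiner=combiner,
            threshold=threshold, grid=grid, cv_folds=inner_folds, seed=seed,
        )
    return EnsembleProtocolResult(
        combiner=combiner,
        fold_reports=fold_reports,
        cv_report=average_reports(fold_reports),
        final_model=final_model,
    )


# ---------------------------------------------------------------------------
# persistence and reporting helpers

def save_model(model, path: str | Path) -> None:
    joblib.dump(model, path)


def load_model(path: str | Path):
    return joblib.load(path)


def write_schema(schema: Mapping[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: list(v) for k, v in schema.items()}, fh, indent=1)


def write_report(report: Mapping[str, float], path: str | Path) -> None:
    path = Path(path)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({k: float(v) for k, v in report.items()}, fh, indent=1)
    with open(path.with_suffix(".tsv"), "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in report.items():
            fh.write(f"{k}\t{v:.4f}\n")


def write_ifs_artifacts(result: IFSResult, out_dir: str | Path, stem: str = "ifs") -> None:
    """Write the IFS curve as TSV and a PNG plot."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(out_dir / f"{stem}_curve.tsv", sep="\t", index=False)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(result.counts, result.mcc_curve, marker="o", ms=3)
    ax.axvline(result.optimal_count, color="crimson", ls="--", lw=1)
    ax.set_xlabel("number of top-ranked features")
    ax.set_ylabel("mean CV MCC")
    ax.set_title(f"IFS curve (peak at {result.optimal_count})")
    fig.tight_layout()
    fig.savefig(out_dir / f"{stem}_curve.png", dpi=120)
    plt.close(fig)
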