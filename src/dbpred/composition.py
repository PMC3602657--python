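"""Composition descriptors: OAAC, skip-dipeptide DPC and SAAC.

* **OAAC** (20 values) — square roots of the residue occurrence
  frequencies, ``f_i = sqrt(n_i / L)``, so that ``sum f_i^2 = 1``.
* **DPC** (1200 raw values) — dipeptide counts at skip distances 0, 1 and 2
  between the pair's residues, each of the three 400-dimensional blocks
  normalized by ``L - 1``.  During training the raw 1200 are reduced to the
  first 400 of an mRMR ranking (:func:`dpc_select`); the selected index set
  is persisted with the model and reused verbatim at prediction time.
* **SAAC** (120 values) — the square-root residue composition computed
  separately within each of the six SAA regions (four N-terminal windows,
  middle, C-terminal tail).

All vectors use the canonical residue order ACDEFGHIKLMNPQRSTVWY and
row-major (first residue, second residue) dipeptide order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DescriptorUndefinedError, ValidationError
from .sequence_io import AMINO_ACIDS, ProteinRecord
from .transforms import (
    DEFAULT_CONFIG,
    DescriptorBlock,
    REGION_NAMES,
    TransformConfig,
    split_regions,
)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Number of DPC descriptors kept after mRMR reduction.
DPC_SELECTED_SIZE = 400

DPC_SKIPS = (0, 1, 2)

#: Ordered names of the 1200 raw skip-dipeptide features.
DPC_RAW_NAMES: tuple[str, ...] = tuple(
    f"DPC:s{s}:{a}{b}" for s in DPC_SKIPS for a in AMINO_ACIDS for b in AMINO_ACIDS
)

OAAC_NAMES: tuple[str, ...] = tuple(f"OAAC:{aa}" for aa in AMINO_ACIDS)

SAAC_NAMES: tuple[str, ...] = tuple(
    f"SAAC:{r}:{aa}" for r in REGION_NAMES for aa in AMINO_ACIDS
)


def _sqrt_composition(seq: str) -> np.ndarray:
    counts = np.zeros(20)
    for aa in seq:
        counts[_AA_INDEX[aa]] += 1
    return np.sqrt(counts / len(seq))


def oaac(record: ProteinRecord) -> DescriptorBlock:
    """Overall amino-acid composition: ``f_i = sqrt(n_i / L)``, 20 values."""
    return DescriptorBlock("OAAC", OAAC_NAMES, _sqrt_composition(record.sequence))


def dpc_raw(record: ProteinRecord) -> DescriptorBlock:
    """Skip-dipeptide composition: DP0, DP1, DP2 concatenated (1200 values).

    ``f_s(i, j) = D_s(i, j) / (L - 1)`` where ``D_s(i, j)`` counts ordered
    pairs (residue i at position p, residue j at position p + s + 1).  The
    denominator is L - 1 for every skip level s, so the block sums satisfy
    ``sum f_s = (L - 1 - s) / (L - 1)``.
    """
    seq = record.sequence
    L = len(seq)
    if L < 3:
        raise DescriptorUndefinedError(
            f"{record.id}: skip-dipeptides undefined for length {L} < 3"
        )
    idx = np.fromiter((_AA_INDEX[aa] for aa in seq), dtype=np.intp, count=L)
    values = np.empty(1200)
    for k, s in enumerate(DPC_SKIPS):
        counts = np.zeros((20, 20))
        np.add.at(counts, (idx[: L - s - 1], idx[s + 1 :]), 1)
        values[k * 400 : (k + 1) * 400] = counts.ravel() / (L - 1)
    return DescriptorBlock("DPC", DPC_RAW_NAMES, values)


def saac(record: ProteinRecord, cfg: TransformConfig = DEFAULT_CONFIG) -> DescriptorBlock:
    """Split amino-acid composition: per-region square-root composition over
    the six SAA regions, 6 x 20 = 120 values (region-major)."""
    regions = split_regions(len(record.sequence), cfg)
    values = np.concatenate(
        [_sqrt_composition(record.sequence[sl]) for sl in regions.slices()]
    )
    return DescriptorBlock("SAAC", SAAC_NAMES, values)


def dpc_select(
    dpc_matrix: pd.DataFrame,
    labels: np.ndarray,
    n_select: int = DPC_SELECTED_SIZE,
    t: float = 1.0,
) -> list[str]:
    """Rank the 1200 raw skip-dipeptide features by mRMR on training data
    and return the first ``n_select`` feature names (ranking order).

    Must be fit on training samples only; the returned name list is stored
    with the model and applied verbatim to new data.
    """
    from .selection import mrmr_rank  # deferred: selection imports nothing from here

    if dpc_matrix.shape[1] < n_select:
        raise ValidationError(
            f"need at least {n_select} dipeptide features, got {dpc_matrix.shape[1]}"
        )
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("dpc_select requires samples from both classes")
    ranking = mrmr_rank(dpc_matrix, labels, top_k=n_select, t=t)
    return list(ranking.feature_names)
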