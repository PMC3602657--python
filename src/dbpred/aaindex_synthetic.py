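"""Synthetic surrogate table for the 28 curated amino-acid property scales.

The pipeline encodes each residue with 28 physicochemical/biochemical
property scales identified by their AAIndex accession numbers (hydropathy,
charge, secondary-structure propensity, bulkiness, ...).  The genuine
AAIndex numeric values are not redistributed with this package; instead this
module ships a SYNTHETIC stand-in: one deterministic standardized value per
(accession, residue) pair, generated once from a fixed pseudo-random stream.

Every downstream transform is invariant to the absolute calibration of a
scale (OCTD min-max normalizes within each protein, the autocovariance
transform mean-centers, and region averaging is linear), so the pipeline's
behaviour, dimensionality and tests are unaffected by the surrogate values;
only the biological interpretation of individual AAIndex-derived features
requires the genuine scales.  Users with an AAIndex download can supply a
real table to :func:`dbpred.track_providers.encode_aaindex`.
"""

from __future__ import annotations

import numpy as np

from .sequence_io import AMINO_ACIDS

#: Accession IDs of the 28 property scales, in the fixed order used for
#: feature naming.
AAINDEX28_IDS: tuple[str, ...] = (
    "CHOP780202",
    "CIDH920103",
    "CIDH920105",
    "FAUJ880109",
    "FAUJ880111",
    "FINA910104",
    "GEIM800104",
    "GEIM800106",
    "KANM800102",
    "KLEP840101",
    "KRIW710101",
    "LIFS790101",
    "MEEJ800101",
    "OOBM770102",
    "PALJ810107",
    "QIAN880123",
    "RACS770103",
    "RADA880108",
    "ROSM880102",
    "SWER830101",
    "ZIMJ680102",
    "ZIMJ680104",
    "AURR980120",
    "MUNV940103",
    "NADH010104",
    "NADH010106",
    "GUYH850105",
    "MIYS990104",
)


def _build_table() -> dict[str, dict[str, float]]:
    rng = np.random.default_rng(28_20)  # fixed: table must never change
    table: dict[str, dict[str, float]] = {}
    for acc in AAINDEX28_IDS:
        vals = np.round(rng.normal(0.0, 1.0, size=len(AMINO_ACIDS)), 3)
        table[acc] = dict(zip(AMINO_ACIDS, vals.tolist()))
    return table


#: Synthetic surrogate values: ``{accession: {residue: value}}``.
AAINDEX28_SYNTHETIC: dict[str, dict[str, float]] = _build_table()
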