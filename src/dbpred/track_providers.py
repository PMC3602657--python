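"""Per-residue property tracks: AAIndex encoding and profile-file readers.

Every feature transform downstream (OCTD / autocovariance / region
averaging) consumes a :class:`PropertyTrackSet` — P named numeric tracks of
length L for one protein.  Three sources are supported:

``aaindex``
    28 physicochemical property scales, one value per residue (pure
    position-wise lookup), P = 28.
``pssm``
    PSI-BLAST ASCII PSSM log-odds, 20 scores per position, P = 20.  Values
    are used raw (integer log-odds); OCTD applies its own per-protein
    normalization.
``ssf``
    Structural & functional tracks: three secondary-structure confidence
    scores (coil, helix, strand — PSIPRED .ss2) plus one disorder score
    (IUPred long mode), P = 4.

Profile files are resolved per protein as ``<id>.pssm`` / ``<id>.ss2`` /
``<id>.iupred`` under a configured directory; this package never runs
PSI-BLAST, PSIPRED or IUPred itself (use :mod:`dbpred.synthetic` to
generate surrogate profiles for testing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .aaindex_synthetic import AAINDEX28_IDS, AAINDEX28_SYNTHETIC
from .exceptions import ConfigError, ParseError, ProfileMismatchError, ValidationError
from .sequence_io import AMINO_ACIDS, ProteinRecord

#: Residue column order of a PSI-BLAST ASCII PSSM.
PSSM_RESIDUE_ORDER = "ARNDCQEGHILKMFPSTVWY"

#: Fixed track order of the combined structural/functional source.
SSF_TRACKS = ("coil", "helix", "strand", "disorder")

_EXPECTED_P = {"aaindex": 28, "pssm": 20, "ssf": 4}


@dataclass
class PropertyTrackSet:
    """P named per-residue numeric tracks of length L for one protein."""

    protein_id: str
    source: str  # one of {"aaindex", "pssm", "ssf"}
    track_names: tuple[str, ...]
    values: np.ndarray = field(repr=False)  # P x L, float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.source not in _EXPECTED_P:
            raise ValidationError(f"unknown track source {self.source!r}")
        p = _EXPECTED_P[self.source]
        if len(self.track_names) != p or self.values.shape[0] != p:
            raise ValidationError(
                f"{self.protein_id}: source {self.source!r} requires {p} tracks, "
                f"got {len(self.track_names)} names / {self.values.shape[0]} rows"
            )
        if self.values.ndim != 2:
            raise ValidationError(f"{self.protein_id}: track values must be a P x L matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.protein_id}: non-finite track value")

    @property
    def length(self) -> int:
        return self.values.shape[1]


def encode_aaindex(
    record: ProteinRecord,
    index_table: Mapping[str, Mapping[str, float]] | None = None,
) -> PropertyTrackSet:
    """Encode a sequence as a 28 x L matrix of property-scale values.

    ``index_table`` maps accession -> residue -> value; by default the
    packaged synthetic surrogate table is used (see
    :mod:`dbpred.aaindex_synthetic`).  Row i, column j is scale i's value
    for residue j — a pure per-position lookup, so concatenating two
    sequences concatenates their matrices.
    """
    if index_table is None:
        index_table = AAINDEX28_SYNTHETIC
    ids = tuple(index_table.keys())
    if index_table is AAINDEX28_SYNTHETIC:
        ids = AAINDEX28_IDS
    mat = np.empty((len(ids), len(record.sequence)), dtype=float)
    for i, acc in enumerate(ids):
        scale = index_table[acc]
        try:
            mat[i] = [scale[aa] for aa in record.sequence]
        except KeyError as exc:
            raise ConfigError(
                f"index {acc!r} has no value for residue {exc.args[0]!r}"
            ) from None
    return PropertyTrackSet(record.id, "aaindex", ids, mat)


def read_pssm(path: str | Path, record: ProteinRecord) -> PropertyTrackSet:
    """Read a PSI-BLAST ASCII PSSM (``-out_ascii_pssm`` dialect).

    The first 20 numeric columns (the log-odds block) are taken, transposed
    to 20 tracks x L positions in the file's residue-column order.  The
    per-row residue letters must match ``record.sequence``.
    """
    path = Path(path)
    header_order: str | None = None
    rows: list[list[int]] = []
    residues: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if header_order is None:
                # The column-header line: >= 20 single residue letters.
                letters = [p for p in parts if len(p) == 1 and p.isalpha()]
                if len(letters) >= 20:
                    header_order = "".join(letters[:20])
                continue
            if not parts[0].isdigit():
                continue  # footer (K/lambda statistics) or blank
            if len(parts) < 22:
                raise ParseError(f"{path}: line {lineno}: truncated PSSM row")
            residues.append(parts[1])
            try:
                rows.append([int(v) for v in parts[2:22]])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer log-odds value"
                ) from None
    if header_order is None or not rows:
        raise ParseError(f"{path}: no PSSM matrix found")
    seq = record.sequence
    if len(rows) != len(seq):
        raise ProfileMismatchError(
            f"{record.id}: PSSM has {len(rows)} rows but sequence length is {len(seq)}"
        )
    found = "".join(residues).upper()
    if found != seq:
        raise ProfileMismatchError(
            f"{record.id}: PSSM residue column does not match the sequence"
        )
    mat = np.array(rows, dtype=float).T  # 20 x L
    return PropertyTrackSet(record.id, "pssm", tuple(header_order), mat)


def read_ss2(path: str | Path) -> tuple[str, np.ndarray]:
    """Read a PSIPRED VFORMAT ``.ss2`` file.

    Returns ``(sequence_letters, 3 x L matrix)`` with rows in the PSIPRED
    column order coil, helix, strand.
    """
    path = Path(path)
    seq: list[str] = []
    conf: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 columns in .ss2 row")
            seq.append(parts[1])
            conf.append([float(parts[3]), float(parts[4]), float(parts[5])])
    if not conf:
        raise ParseError(f"{path}: no .ss2 rows found")
    return "".join(seq).upper(), np.array(conf, dtype=float).T


def read_iupred(path: str | Path) -> tuple[str, np.ndarray]:
    """Read IUPred long-mode output: one ``pos aa score`` row per residue.

    Returns ``(sequence_letters, length-L score vector)``; scores must lie
    in [0, 1].
    """
    path = Path(path)
    seq: list[str] = []
    scores: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 'pos aa score' row")
            if len(parts) >= 3:
                seq.append(parts[1])
                score = float(parts[2])
            else:
                seq.append("?")
                score = float(parts[1])
            if not 0.0 <= score <= 1.0:
                raise ValidationError(
                    f"{path}: line {lineno}: disorder score {score} outside [0, 1]"
                )
            scores.append(score)
    if not scores:
        raise ParseError(f"{path}: no disorder scores found")
    return "".join(seq).upper(), np.array(scores, dtype=float)


def assemble_ssf(
    record: ProteinRecord,
    ss2: tuple[str, np.ndarray],
    iupred: tuple[str, np.ndarray],
) -> PropertyTrackSet:
    """Combine secondary-structure confidences and disorder scores into the
    4 x L structural/functional track set (order: coil, helix, strand,
    disorder)."""
    L = len(record.sequence)
    ss_seq, ss_mat = ss2
    iu_seq, iu_vec = iupred
    if ss_mat.shape[1] != L:
        raise ProfileMismatchError(
            f"{record.id}: .ss2 has {ss_mat.shape[1]} rows but sequence length is {L}"
        )
    if iu_vec.shape[0] != L:
        raise ProfileMismatchError(
            f"{record.id}: IUPred output has {iu_vec.shape[0]} rows but sequence length is {L}"
        )
    if ss_seq != record.sequence:
        raise ProfileMismatchError(f"{record.id}: .ss2 residues do not match the sequence")
    if "?" not in iu_seq and iu_seq != record.sequence:
        raise ProfileMismatchError(f"{record.id}: IUPred residues do not match the sequence")
    mat = np.vstack([ss_mat, iu_vec[None, :]])
    return PropertyTrackSet(record.id, "ssf", SSF_TRACKS, mat)


def load_tracks(
    record: ProteinRecord,
    profile_dir: str | Path,
    require_ssf: bool = True,
) -> dict[str, PropertyTrackSet]:
    """Resolve and read all profile files for one protein.

    Looks for ``<id>.pssm``, ``<id>.ss2`` and ``<id>.iupred`` under
    ``profile_dir`` and returns ``{"aaindex": ..., "pssm": ..., "ssf": ...}``.
    """
    profile_dir = Path(profile_dir)
    out = {"aaindex": encode_aaindex(record)}
    pssm_path = profile_dir / f"{record.id}.pssm"
    ss2_path = profile_dir / f"{record.id}.ss2"
    iup_path = profile_dir / f"{record.id}.iupred"
    if pssm_path.exists():
        out["pssm"] = read_pssm(pssm_path, record)
    elif require_ssf:
        raise FileNotFoundError(
            f"{pssm_path} not found: run PSI-BLAST for {record.id} or generate "
            "surrogate profiles with `dbp simulate` / dbpred.synthetic"
        )
    if ss2_path.exists() and iup_path.exists():
        out["ssf"] = assemble_ssf(record, read_ss2(ss2_path), read_iupred(iup_path))
    elif require_ssf:
        missing = ss2_path if not ss2_path.exists() else iup_path
        raise FileNotFoundError(
            f"{missing} not found: run PSIPRED/IUPred for {record.id} or generate "
            "surrogate profiles with `dbp simulate` / dbpred.synthetic"
        )
    return out
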