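"""Protein sequence records and FASTA / label-table I/O.

A :class:`ProteinRecord` is the unit every descriptor module consumes: an
identifier plus a validated amino-acid sequence over the 20 standard
one-letter codes, optionally carrying a binary label (1 = DNA-binding,
0 = non-binding).  Sequences containing ambiguous or non-standard letters
(X, Z, B, U, O, ...) are rejected outright, mirroring how curated
DNA-binding benchmark sets are constructed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical residue order used for every composition feature vector.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID = frozenset(AMINO_ACIDS)

#: Default minimum usable sequence length.  This floor guarantees every
#: descriptor in the pipeline is defined: the autocovariance transform needs
#: L >= max-lag + 1 = 12 and the short-sequence region split needs non-empty
#: N-terminal, middle and C-terminal parts (L >= 31 suffices for both).
MIN_LENGTH_DEFAULT = 31


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: id, validated sequence, optional binary label."""

    id: str
    sequence: str
    label: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self, min_length: int = MIN_LENGTH_DEFAULT) -> "ProteinRecord":
        """Check the record invariants; raise :class:`ValidationError` naming
        the record id on failure.  Returns ``self`` for chaining."""
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValidationError(
                f"record {self.id!r}: non-standard amino-acid letter(s) "
                f"{''.join(sorted(bad))!r} in sequence"
            )
        if len(self.sequence) < min_length:
            raise ValidationError(
                f"record {self.id!r}: sequence length {len(self.sequence)} "
                f"< minimum {min_length}"
            )
        return self

    def with_label(self, label: int | None) -> "ProteinRecord":
        return ProteinRecord(self.id, self.sequence, label)


def make_record(
    id: str,
    sequence: str,
    label: int | None = None,
    min_length: int = MIN_LENGTH_DEFAULT,
) -> ProteinRecord:
    """Build a validated record.  Lower-case letters are upcased first
    (a common FASTA dialect) before the alphabet check."""
    return ProteinRecord(id, sequence.upper(), label).validate(min_length)


def _check_fasta_shape(path: Path) -> None:
    """Light structural pre-check so parse errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                return
            raise ParseError(
                f"{path}: line {lineno} is not FASTA "
                f"(expected a '>' header before sequence data): {stripped[:40]!r}"
            )


def read_fasta(
    path: str | Path,
    labels: Mapping[str, int] | None = None,
    min_length: int = MIN_LENGTH_DEFAULT,
) -> list[ProteinRecord]:
    """Read a (multi-)FASTA file into validated records, preserving order.

    Parameters
    ----------
    path
        FASTA file; lower-case sequence letters are tolerated and upcased.
    labels
        Optional ``id -> 0/1`` mapping (see :func:`read_labels`); ids absent
        from the map get ``label=None``.
    min_length
        Minimum accepted sequence length.

    Raises
    ------
    ParseError
        If the file is not FASTA-shaped (names the offending line).
    ValidationError
        If any sequence contains a non-standard letter or is too short
        (names the record id).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    if path.stat().st_size == 0:
        logger.warning("%s: empty FASTA file, returning no records", path)
        return records
    _check_fasta_shape(path)
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        label = labels.get(rec.id) if labels is not None else None
        records.append(make_record(rec.id, str(rec.seq), label, min_length))
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (inverse of :func:`read_fasta` on valid lists)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV ``id<TAB>label`` (header row optional).

    Labels must be 0 or 1.  Keeping labels out of FASTA headers leaves the
    headers free-form.
    """
    path = Path(path)
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated columns")
            ident, raw = parts[0].strip(), parts[1].strip()
            if lineno == 1 and raw not in {"0", "1"}:
                continue  # header row
            if raw not in {"0", "1"}:
                raise ParseError(f"{path}: line {lineno}: label must be 0 or 1, got {raw!r}")
            if ident in out:
                raise ParseError(f"{path}: line {lineno}: duplicate id {ident!r}")
            out[ident] = int(raw)
    return out


def write_labels(labels: Mapping[str, int] | Sequence[ProteinRecord], path: str | Path) -> None:
    """Write an ``id<TAB>label`` TSV from a mapping or labelled records."""
    if not isinstance(labels, Mapping):
        labels = {r.id: r.label for r in labels if r.label is not None}
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for ident, lab in labels.items():
            fh.write(f"{ident}\t{lab}\n")
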