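"""Synthetic labeled datasets: sequences plus surrogate profile files.

The generator emulates the inputs of the real pipeline so every stage is
testable without running PSI-BLAST, PSIPRED or IUPred:

* sequences — i.i.d. residues; the positive (DNA-binding) class puts an
  extra ``delta`` of probability mass on lysine, arginine and
  phenylalanine (the residue types enriched in DNA-contacting positions),
  split equally among the three;
* PSSM — a one-hot profile peaked on the emitting residue
  (``pssm_scale``) plus small integer noise, written in the PSI-BLAST
  ASCII dialect, so profile/sequence consistency checks hold;
* secondary structure — per-residue coil/helix/strand states with a
  class-shifted helix fraction, written as PSIPRED VFORMAT ``.ss2``
  confidence rows;
* disorder — per-residue Beta-distributed scores in [0, 1] with a
  class-shifted mean, written as IUPred long-mode output.

Everything is driven by one seeded generator, so identical configs produce
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import ConfigError
from .sequence_io import AMINO_ACIDS, ProteinRecord, write_fasta, write_labels
from .track_providers import (
    PSSM_RESIDUE_ORDER,
    PropertyTrackSet,
    SSF_TRACKS,
    encode_aaindex,
)

_PSSM_POS = {aa: i for i, aa in enumerate(PSSM_RESIDUE_ORDER)}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    ``delta`` is the total extra probability mass the positive class puts
    on the ``bias_residues`` (delta = 0 makes the classes exchangeable);
    ``helix_shift`` / ``disorder_shift`` move the positive class's helix
    state probability and mean disorder score.
    """

    n_per_class: int = 100
    length_range: tuple[int, int] = (50, 350)
    delta: float = 0.15
    bias_residues: tuple[str, ...] = ("K", "R", "F")
    helix_shift: float = 0.10
    disorder_shift: float = 0.10
    base_state_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)  # coil, helix, strand
    base_disorder_mean: float = 0.35
    disorder_concentration: float = 8.0
    pssm_scale: int = 7
    pssm_noise: int = 2
    seed: int = 0

    def residue_probs(self, positive: bool) -> np.ndarray:
        """Per-residue emission probabilities for one class."""
        probs = np.full(20, 1 / 20)
        if positive and self.delta:
            bias_idx = [AMINO_ACIDS.index(aa) for aa in self.bias_residues]
            rest = [i for i in range(20) if i not in bias_idx]
            base_rest = probs[rest].sum()
            probs[bias_idx] += self.delta / len(bias_idx)
            probs[rest] *= (base_rest - self.delta) / base_rest
        return probs

    def state_probs(self, positive: bool) -> np.ndarray:
        coil, helix, strand = self.base_state_probs
        if positive:
            helix += self.helix_shift
            coil -= self.helix_shift
        return np.array([coil, helix, strand])

    def disorder_mean(self, positive: bool) -> float:
        return self.base_disorder_mean + (self.disorder_shift if positive else 0.0)

    def validate(self) -> "SyntheticConfig":
        if self.n_per_class < 1:
            raise ConfigError("n_per_class must be >= 1")
        lo, hi = self.length_range
        if not 31 <= lo <= hi:
            raise ConfigError("length_range must satisfy 31 <= min <= max")
        for positive in (False, True):
            p = self.residue_probs(positive)
            if (p < 0).any() or abs(p.sum() - 1) > 1e-9:
                raise ConfigError(f"invalid residue distribution (delta={self.delta})")
            s = self.state_probs(positive)
            if (s < 0).any() or abs(s.sum() - 1) > 1e-9:
                raise ConfigError("invalid secondary-structure state probabilities")
            m = self.disorder_mean(positive)
            if not 0 < m < 1:
                raise ConfigError("disorder mean must lie in (0, 1)")
        return self


@dataclass
class SyntheticProtein:
    record: ProteinRecord
    pssm: np.ndarray = field(repr=False)  # L x 20 integer log-odds, PSSM column order
    ss2: np.ndarray = field(repr=False)  # L x 3 confidences (coil, helix, strand)
    disorder: np.ndarray = field(repr=False)  # L scores in [0, 1]

    def track_sets(self) -> dict[str, PropertyTrackSet]:
        """In-memory track sets equal to what the file readers would return."""
        rid = self.record.id
        ssf = np.vstack([self.ss2.T, self.disorder[None, :]])
        return {
            "aaindex": encode_aaindex(self.record),
            "pssm": PropertyTrackSet(rid, "pssm", tuple(PSSM_RESIDUE_ORDER), self.pssm.T),
            "ssf": PropertyTrackSet(rid, "ssf", SSF_TRACKS, ssf),
        }


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    proteins: list[SyntheticProtein]

    @property
    def records(self) -> list[ProteinRecord]:
        return [p.record for p in self.proteins]

    @property
    def labels(self) -> dict[str, int]:
        return {p.record.id: p.record.label for p in self.proteins}

    def track_sets(self) -> dict[str, dict[str, PropertyTrackSet]]:
        return {p.record.id: p.track_sets() for p in self.proteins}


def _simulate_protein(
    cfg: SyntheticConfig, rng: np.random.Generator, ident: str, positive: bool
) -> SyntheticProtein:
    lo, hi = cfg.length_range
    L = int(rng.integers(lo, hi + 1))
    seq_idx = rng.choice(20, size=L, p=cfg.residue_probs(positive))
    seq = "".join(AMINO_ACIDS[i] for i in seq_idx)

    pssm = rng.integers(-cfg.pssm_noise, cfg.pssm_noise + 1, size=(L, 20))
    for j, aa in enumerate(seq):
        pssm[j, _PSSM_POS[aa]] += cfg.pssm_scale

    states = rng.choice(3, size=L, p=cfg.state_probs(positive))
    alpha = np.ones((L, 3))
    alpha[np.arange(L), states] = 9.0
    ss2 = np.round(_dirichlet(rng, alpha), 3)

    m = cfg.disorder_mean(positive)
    k = cfg.disorder_concentration
    disorder = np.round(rng.beta(m * k, (1 - m) * k, size=L), 4)
    disorder = np.clip(disorder, 0.0, 1.0)

    record = ProteinRecord(ident, seq, int(positive))
    return SyntheticProtein(record, pssm.astype(float), ss2, disorder)


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Row-wise Dirichlet draws with per-row concentration parameters."""
    g = rng.gamma(alpha)
    return g / g.sum(axis=1, keepdims=True)


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate ``2 * n_per_class`` labelled proteins with surrogate tracks,
    fully deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    proteins = []
    width = len(str(cfg.n_per_class))
    for positive in (True, False):
        tag = "pos" if positive else "neg"
        for i in range(cfg.n_per_class):
            proteins.append(
                _simulate_protein(cfg, rng, f"{tag}_{i + 1:0{width}d}", positive)
            )
    return SyntheticDataset(cfg, proteins)


# ---------------------------------------------------------------------------
# profile-file writers (the exact dialects the readers consume)

_PSSM_HEADER = (
    "\n"
    "Last position-specific scoring matrix computed, weighted observed percentages "
    "rounded down, information per position, and relative weight of gapless real "
    "matches to pseudocounts\n"
)


def write_pssm(protein: SyntheticProtein, path: Path) -> None:
    """Write a PSI-BLAST-style ASCII PSSM (log-odds block only is meaningful)."""
    seq = protein.record.sequence
    with open(path, "w") as fh:
        fh.write(_PSSM_HEADER)
        letters = "   ".join(PSSM_RESIDUE_ORDER)
        fh.write(f"            {letters}   {letters}\n")
        for j, aa in enumerate(seq, start=1):
            logodds = " ".join(f"{int(v):3d}" for v in protein.pssm[j - 1])
            percents = " ".join(f"{0:3d}" for _ in range(20))
            fh.write(f"{j:5d} {aa} {logodds}  {percents}  0.00 0.00\n")
        fh.write("\n")


def write_ss2(protein: SyntheticProtein, path: Path) -> None:
    """Write a PSIPRED VFORMAT .ss2 file (columns: coil, helix, strand)."""
    state_letter = "CHE"
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT (synthetic surrogate)\n\n")
        for j, aa in enumerate(protein.record.sequence, start=1):
            c, h, e = protein.ss2[j - 1]
            letter = state_letter[int(np.argmax(protein.ss2[j - 1]))]
            fh.write(f"{j:4d} {aa} {letter}   {c:5.3f} {h:5.3f} {e:5.3f}\n")


def write_iupred(protein: SyntheticProtein, path: Path) -> None:
    """Write IUPred long-mode style output: ``pos aa score`` rows."""
    with open(path, "w") as fh:
        fh.write("# IUPred-style long disorder scores (synthetic surrogate)\n")
        fh.write("# POS\tAA\tSCORE\n")
        for j, aa in enumerate(protein.record.sequence, start=1):
            fh.write(f"{j} {aa} {protein.disorder[j - 1]:.4f}\n")


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write FASTA + label TSV + per-protein profile files under ``out_dir``."""
    out_dir = Path(out_dir)
    profiles = out_dir / "profiles"
    profiles.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.records, out_dir / "sequences.fasta")
    write_labels(dataset.labels, out_dir / "labels.tsv")
    for protein in dataset.proteins:
        rid = protein.record.id
        write_pssm(protein, profiles / f"{rid}.pssm")
        write_ss2(protein, profiles / f"{rid}.ss2")
        write_iupred(protein, profiles / f"{rid}.iupred")
    return out_dir


def generate(cfg: SyntheticConfig, out_dir: str | Path) -> Path:
    """Generate a dataset and write it to disk (see :func:`write_dataset`)."""
    return write_dataset(generate_dataset(cfg), out_dir)


def null_config(cfg: SyntheticConfig | None = None) -> SyntheticConfig:
    """A copy of ``cfg`` with every class effect removed (exchangeable classes)."""
    base = cfg or SyntheticConfig()
    return replace(base, delta=0.0, helix_shift=0.0, disorder_shift=0.0)
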