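"""Feature-transformation engines: OCTD, autocovariance (AC) and split
amino-acid (SAA) region averaging, applied to any per-residue track set.

The three transforms read the same protein at three scales:

* **OCTD** (global) — Overall Composition/Transition/Distribution.  Each
  track is min-max normalized within the protein, positions are split into
  two groups at a 0.5 threshold, and 13 summary values are emitted per
  track: the two group fractions, the transition rate between groups along
  the chain, and five distribution quantile positions per group.
* **AC** (nonlocal) — the autocovariance of each track at lags
  ``lg = 1..LG``, capturing residue-residue coupling a fixed distance apart.
  Only autocovariance (not cross-covariance between tracks) is used.
* **SAA** (local) — the track mean over six sequence regions: four
  N-terminal windows, a middle part and a C-terminal tail, with
  short-sequence fallbacks.

:func:`assemble` stacks the three composition blocks and the nine
transform blocks (3 transforms x 3 track sources) into the fixed 12-block
descriptor schema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, DescriptorUndefinedError, ValidationError
from .sequence_io import ProteinRecord
from .track_providers import PropertyTrackSet

#: Map track source -> block-name prefix used in feature names.
SOURCE_PREFIX = {"aaindex": "AAIndex", "pssm": "PSSM", "ssf": "S&F"}

#: Fixed order of the 12 descriptor blocks.
BLOCK_ORDER = (
    "OAAC",
    "DPC",
    "SAAC",
    "AAIndex-OCTD",
    "AAIndex-AC",
    "AAIndex-SAA",
    "PSSM-OCTD",
    "PSSM-AC",
    "PSSM-SAA",
    "S&F-OCTD",
    "S&F-AC",
    "S&F-SAA",
)

_OCTD_SLOTS = (
    "C_A",
    "C_B",
    "T",
    "D_A_0",
    "D_A_25",
    "D_A_50",
    "D_A_75",
    "D_A_100",
    "D_B_0",
    "D_B_25",
    "D_B_50",
    "D_B_75",
    "D_B_100",
)


@dataclass
class DescriptorBlock:
    """One named fixed-length feature vector with ordered feature names."""

    block_name: str
    feature_names: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.feature_names):
            raise ValidationError(
                f"block {self.block_name!r}: {len(self.feature_names)} names vs "
                f"{self.values.shape} values"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"block {self.block_name!r}: non-finite value")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TransformConfig:
    """Transform parameters.

    ``lg_*`` are the maximum autocovariance lags per track source (in
    residues); ``d_n``/``d_m_min``/``d_c`` are the N-terminal window size,
    minimum middle-part length and C-terminal tail length of the SAA region
    split; ``octd_threshold`` is the normalized-value cut separating the two
    OCTD groups.
    """

    lg_aaindex: int = 9
    lg_pssm: int = 11
    lg_ssf: int = 10
    d_n: int = 25
    d_m_min: int = 20
    d_c: int = 10
    octd_threshold: float = 0.5
    min_length: int = 31

    def __post_init__(self) -> None:
        if min(self.lg_aaindex, self.lg_pssm, self.lg_ssf) < 1:
            raise ConfigError("autocovariance maximum lag must be >= 1")
        if min(self.d_n, self.d_m_min, self.d_c) < 1:
            raise ConfigError("SAA region lengths must be >= 1")
        if not 0.0 < self.octd_threshold < 1.0:
            raise ConfigError("octd_threshold must lie in (0, 1)")

    def lg_for(self, source: str) -> int:
        return {"aaindex": self.lg_aaindex, "pssm": self.lg_pssm, "ssf": self.lg_ssf}[source]


DEFAULT_CONFIG = TransformConfig()

#: Names of the six SAA regions, in order.
REGION_NAMES = ("r1", "r2", "r3", "r4", "r5", "r6")


@dataclass(frozen=True)
class RegionList:
    """Six 1-based inclusive ``(start, end)`` intervals: N1-N4, middle, C."""

    regions: tuple[tuple[int, int], ...]
    length: int

    def __post_init__(self) -> None:
        if len(self.regions) != 6:
            raise ValidationError("exactly six SAA regions required")
        for start, end in self.regions:
            if not (1 <= start <= end <= self.length):
                raise ValidationError(
                    f"region ({start}, {end}) invalid for length {self.length}"
                )
        if self.regions[-1][1] != self.length:
            raise ValidationError("C-terminal region must end at the last residue")

    def slices(self) -> list[slice]:
        """0-based half-open slices for the six regions."""
        return [slice(s - 1, e) for s, e in self.regions]


def split_regions(L: int, cfg: TransformConfig = DEFAULT_CONFIG) -> RegionList:
    """Split a length-L sequence into the six SAA regions.

    With defaults (d_n=25, d_m_min=20, d_c=10):

    * ``L >= 130``: four N-terminal windows of d_n, middle ``[4*d_n+1, L-d_c]``,
      C-tail of d_c;
    * ``110 < L < 130``: same N windows and C tail, but the middle is the
      d_m_min residues immediately before the C tail (it may overlap N4);
    * ``L <= 110``: the N part is a single window of ``floor((L-d_c)/2)``
      residues duplicated into all four N slots, the middle runs from there
      to the C tail.
    """
    if L < cfg.min_length:
        raise DescriptorUndefinedError(f"sequence length {L} < minimum {cfg.min_length}")
    d_n, d_m, d_c = cfg.d_n, cfg.d_m_min, cfg.d_c
    c_region = (L - d_c + 1, L)
    if L >= 4 * d_n + d_m + d_c:  # case A: full-length geometry
        n_regions = [(k * d_n + 1, (k + 1) * d_n) for k in range(4)]
        middle = (4 * d_n + 1, L - d_c)
    elif L > 4 * d_n + d_c:  # case B: middle anchored at the C tail
        n_regions = [(k * d_n + 1, (k + 1) * d_n) for k in range(4)]
        middle = (L - d_c - d_m + 1, L - d_c)
    else:  # case C: undivided N part, equal N/middle lengths
        n = (L - d_c) // 2
        n_regions = [(1, n)] * 4
        middle = (n + 1, L - d_c)
    return RegionList(tuple(n_regions) + (middle, c_region), L)


def octd(tracks: PropertyTrackSet, threshold: float = 0.5) -> DescriptorBlock:
    """Overall Composition/Transition/Distribution: 13 values per track.

    Per track: min-max normalize the L values within this protein; assign
    position j to group A if the normalized value is <= ``threshold``, else
    group B (a constant track puts every position in A).  Emit
    ``[C_A, C_B, T, D_A x5, D_B x5]`` where ``C_g`` is the group fraction,
    ``T`` the fraction of adjacent pairs that switch group, and ``D_g`` the
    chain positions (as fractions of L) of the first and the 25/50/75/100%
    occurrences of group g (five zeros for an empty group).
    """
    L = tracks.length
    if L < 2:
        raise DescriptorUndefinedError(
            f"{tracks.protein_id}: OCTD undefined for length {L} < 2"
        )
    prefix = SOURCE_PREFIX[tracks.source] + "-OCTD"
    names: list[str] = []
    values: list[float] = []
    for name, row in zip(tracks.track_names, tracks.values):
        lo, hi = row.min(), row.max()
        if hi > lo:
            in_a = (row - lo) / (hi - lo) <= threshold
        else:
            in_a = np.ones(L, dtype=bool)
        out = np.zeros(13)
        out[0] = in_a.sum() / L
        out[1] = 1.0 - out[0]
        out[2] = np.count_nonzero(in_a[:-1] != in_a[1:]) / (L - 1)
        for g, mask in enumerate((in_a, ~in_a)):
            pos = np.flatnonzero(mask) + 1  # 1-based chain positions
            n_g = len(pos)
            if n_g:
                idx = [1] + [math.ceil(r * n_g) for r in (0.25, 0.5, 0.75, 1.0)]
                out[3 + 5 * g : 8 + 5 * g] = pos[np.array(idx) - 1] / L
        names.extend(f"{prefix}:{name}:{slot}" for slot in _OCTD_SLOTS)
        values.extend(out)
    return DescriptorBlock(prefix, tuple(names), np.array(values))


def ac(tracks: PropertyTrackSet, lg_max: int) -> DescriptorBlock:
    """Autocovariance of each track at lags 1..lg_max (track-major order).

    ``AC(i, lg) = sum_{j=1}^{L-lg} (S_ij - mean_i)(S_i,j+lg - mean_i) / (L - lg)``.
    """
    L = tracks.length
    if L <= lg_max:
        raise DescriptorUndefinedError(
            f"{tracks.protein_id}: AC with max lag {lg_max} undefined for length {L}"
        )
    prefix = SOURCE_PREFIX[tracks.source] + "-AC"
    centered = tracks.values - tracks.values.mean(axis=1, keepdims=True)
    names: list[str] = []
    values = np.empty(len(tracks.track_names) * lg_max)
    k = 0
    for name, row in zip(tracks.track_names, centered):
        for lg in range(1, lg_max + 1):
            values[k] = np.dot(row[:-lg], row[lg:]) / (L - lg)
            names.append(f"{prefix}:{name}:lg{lg}")
            k += 1
    return DescriptorBlock(prefix, tuple(names), values)


def saa(tracks: PropertyTrackSet, regions: RegionList) -> DescriptorBlock:
    """Region means of each track over the six SAA regions (region-major per
    track: r1..r6 for track 1, then track 2, ...)."""
    if regions.length != tracks.length:
        raise ValidationError(
            f"{tracks.protein_id}: region list is for length {regions.length}, "
            f"tracks have length {tracks.length}"
        )
    prefix = SOURCE_PREFIX[tracks.source] + "-SAA"
    slices = regions.slices()
    names: list[str] = []
    values: list[float] = []
    for name, row in zip(tracks.track_names, tracks.values):
        for rname, sl in zip(REGION_NAMES, slices):
            values.append(float(row[sl].mean()))
            names.append(f"{prefix}:{name}:{rname}")
    return DescriptorBlock(prefix, tuple(names), np.array(values))


def transform_source(
    tracks: PropertyTrackSet, cfg: TransformConfig = DEFAULT_CONFIG
) -> list[DescriptorBlock]:
    """Apply OCTD, AC and SAA to one track source, in that order."""
    regions = split_regions(tracks.length, cfg)
    return [
        octd(tracks, cfg.octd_threshold),
        ac(tracks, cfg.lg_for(tracks.source)),
        saa(tracks, regions),
    ]


def assemble(
    record: ProteinRecord,
    aaindex: PropertyTrackSet | None,
    pssm: PropertyTrackSet | None,
    ssf: PropertyTrackSet | None,
    cfg: TransformConfig = DEFAULT_CONFIG,
    require: tuple[str, ...] = ("aaindex", "pssm", "ssf"),
) -> list[DescriptorBlock]:
    """Assemble all descriptor blocks for one protein in the fixed order.

    Composition blocks (OAAC, DPC raw, SAAC) are always computed from the
    sequence; each available track source contributes its OCTD/AC/SAA
    blocks.  Sources listed in ``require`` must be present.  With all three
    sources and DPC reduced from 1200 to its selected 400 during training,
    the total descriptor dimension is 2040.
    """
    from . import composition  # deferred: composition imports split_regions

    provided = {"aaindex": aaindex, "pssm": pssm, "ssf": ssf}
    missing = [s for s in require if provided[s] is None]
    if missing:
        raise ValidationError(
            f"{record.id}: missing required track source(s): {', '.join(missing)}"
        )
    blocks = [
        composition.oaac(record),
        composition.dpc_raw(record),
        composition.saac(record, cfg),
    ]
    for source in ("aaindex", "pssm", "ssf"):
        tracks = provided[source]
        if tracks is not None:
            if tracks.protein_id != record.id:
                raise ValidationError(
                    f"track set for {tracks.protein_id!r} passed with record {record.id!r}"
                )
            blocks.extend(transform_source(tracks, cfg))
    return blocks
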