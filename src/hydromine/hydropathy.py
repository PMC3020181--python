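"""Kyte-Doolittle hydropathy profiles and doublet-flank classification.

The hydropathy profile of a candidate is computed as the unweighted sliding
window mean of the Kyte-Doolittle index (window 9 by default), restricted to
the region from the first to the eighth conserved cysteine.  Class calls use
the sign of the raw (unwindowed) hydropathy of the residues immediately
C-terminal of the two cysteine doublets: hydrophilic flanks after both
doublets indicate class I, hydrophobic flanks class II.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .motif_scan import CysteineTopology
    from .seqio import ProteinRecord

#: Kyte & Doolittle hydropathy index; positive = hydrophobic.  'X' scores 0.
KD_SCALE: Mapping[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

DEFAULT_WINDOW = 9
DEFAULT_FLANK_LEN = 5

__all__ = [
    "KD_SCALE",
    "DEFAULT_WINDOW",
    "DEFAULT_FLANK_LEN",
    "HydropathyProfile",
    "DoubletFlankStats",
    "kd_values",
    "kd_profile",
    "motif_span_profile",
    "align_profiles",
    "doublet_flank_stats",
    "hydropathy_class",
]


@dataclass(frozen=True)
class HydropathyProfile:
    """Windowed hydropathy values over ``span`` of the underlying sequence.

    ``values[i]`` is the mean scale value of the full window centred on
    sequence position ``span[0] + i``; only full windows are emitted, so the
    span excludes ``(window - 1) // 2`` residues at each end of the region
    profiled.
    """

    values: tuple[float, ...]
    window: int
    span: tuple[int, int]  # 0-based half-open interval of window centres

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 1")
        if len(self.values) != self.span[1] - self.span[0]:
            raise ValueError("profile length inconsistent with span")


@dataclass(frozen=True)
class DoubletFlankStats:
    """Mean raw hydropathy of the residues after each cysteine doublet."""

    flank1_mean: float
    flank2_mean: float
    flank_len: int


def kd_values(seq: str, scale: Mapping[str, float] = KD_SCALE) -> np.ndarray:
    """Per-residue hydropathy values (no smoothing)."""
    try:
        return np.array([scale[aa] for aa in seq], dtype=float)
    except KeyError as exc:  # pragma: no cover - guarded upstream by seqio
        raise ValueError(f"residue {exc.args[0]!r} not in hydropathy scale") from exc


def kd_profile(
    seq: str,
    window: int = DEFAULT_WINDOW,
    *,
    offset: int = 0,
    scale: Mapping[str, float] = KD_SCALE,
) -> HydropathyProfile:
    """Sliding-window mean hydropathy profile of ``seq``.

    Parameters
    ----------
    seq:
        Amino-acid string; must be at least ``window`` residues long.
    window:
        Odd window length in residues.  Window 1 reproduces the raw per-residue
        scale values.
    offset:
        Position of ``seq[0]`` in a larger parent sequence, so that the
        profile's span refers to parent coordinates (used by
        :func:`motif_span_profile`).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if len(seq) < window:
        raise ValueError(
            f"sequence length {len(seq)} shorter than window {window}"
        )
    raw = kd_values(seq, scale)
    kernel = np.full(window, 1.0 / window)
    means = np.convolve(raw, kernel, mode="valid")
    half = (window - 1) // 2
    span = (offset + half, offset + len(seq) - half)
    return HydropathyProfile(values=tuple(means), window=window, span=span)


def motif_span_profile(
    record: "ProteinRecord",
    topology: "CysteineTopology",
    window: int = DEFAULT_WINDOW,
) -> HydropathyProfile:
    """Hydropathy profile of the region from Cys1 through Cys8 inclusive."""
    start = topology.cys_positions[0]
    end = topology.cys_positions[7] + 1
    sub = record.sequence[start:end]
    return kd_profile(sub, window, offset=start)


def _segment_lengths(topology: "CysteineTopology") -> list[int]:
    """Lengths of the 7 inter-cysteine runs (two of them are the 0-length doublets)."""
    pos = topology.cys_positions
    return [pos[i + 1] - pos[i] - 1 for i in range(7)]


def align_profiles(
    profiles: Sequence[tuple[HydropathyProfile, "CysteineTopology"]],
) -> tuple[np.ndarray, list[int]]:
    """Anchor hydropathy profiles on the eight conserved cysteines.

    Each row is one protein's motif-span profile laid out on a common column
    grid in which the 8 cysteine columns coincide across rows.  Within each of
    the 7 inter-cysteine segments, shorter segments are padded at their right
    edge with NaN gap markers; positions not covered by a full window (profile
    edge effects) are also NaN.

    Returns
    -------
    matrix:
        ``(n_rows, n_cols)`` float array with NaN gaps.
    cys_columns:
        The 8 column indices holding the conserved cysteines (identical for
        every row).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to align")
    seg_lens = [_segment_lengths(t) for _, t in profiles]
    max_seg = [max(row[i] for row in seg_lens) for i in range(7)]

    # column layout: C seg0 C seg1 C ... seg6 C
    cys_columns: list[int] = []
    col = 0
    for i in range(8):
        cys_columns.append(col)
        col += 1
        if i < 7:
            col += max_seg[i]
    n_cols = col

    matrix = np.full((len(profiles), n_cols), np.nan)
    for r, ((profile, topology), lens) in enumerate(zip(profiles, seg_lens)):
        pos = topology.cys_positions
        lo, hi = profile.span

        def put(col_idx: int, seq_idx: int) -> None:
            if lo <= seq_idx < hi:
                matrix[r, col_idx] = profile.values[seq_idx - lo]

        for i in range(8):
            put(cys_columns[i], pos[i])
            if i < 7:
                for k in range(lens[i]):  # left-aligned; right edge stays gap
                    put(cys_columns[i] + 1 + k, pos[i] + 1 + k)
    return matrix, cys_columns


def doublet_flank_stats(
    record: "ProteinRecord",
    topology: "CysteineTopology",
    flank_len: int = DEFAULT_FLANK_LEN,
) -> DoubletFlankStats:
    """Mean raw hydropathy of the ``flank_len`` residues after each doublet.

    The two doublets are Cys2-Cys3 and Cys6-Cys7; the flank starts at the
    residue immediately C-terminal of Cys3 (resp. Cys7).  Flanks are truncated
    at the sequence end; an empty flank is an error.
    """
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    seq = record.sequence
    means = []
    for doublet_end in (topology.cys_positions[2], topology.cys_positions[6]):
        flank = seq[doublet_end + 1 : doublet_end + 1 + flank_len]
        if not flank:
            raise ValueError(
                f"{record.id}: cysteine doublet at sequence end, empty flank"
            )
        means.append(float(np.mean(kd_values(flank))))
    return DoubletFlankStats(
        flank1_mean=means[0], flank2_mean=means[1], flank_len=flank_len
    )


def hydropathy_class(stats: DoubletFlankStats) -> str:
    """Classify doublet flanks: both hydrophilic -> class I, both hydrophobic -> class II.

    Returns one of ``"classI_hydropathy"``, ``"classII_hydropathy"``,
    ``"mixed"``.  A mean of exactly zero counts as neither hydrophobic nor
    hydrophilic.
    """
    if stats.flank1_mean < 0 and stats.flank2_mean < 0:
        return "classI_hydropathy"
    if stats.flank1_mean > 0 and stats.flank2_mean > 0:
        return "classII_hydropathy"
    return "mixed"
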