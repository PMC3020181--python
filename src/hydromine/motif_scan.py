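"""Detection of the conserved eight-cysteine hydrophobin motif and candidate filtering.

The motif is ``C N{s1} CC N{s2} C N{s3} C N{s4} CC N{s5} C``: eight cysteines
of which the second/third and sixth/seventh form adjacent doublets, with no
other cysteine anywhere between the first and eighth.  Because the internal
region must be free of extra cysteines, every valid topology consists of
eight *consecutive* entries of the sequence's cysteine-position list, which
is how the scanner enumerates candidates.  Additional cysteines before Cys1
or after Cys8 are allowed and counted separately.

Filtering follows the mining criteria used for the Aspergillus survey: a
motif hit, a total cysteine count within bounds (8-10 by default; proteins
with 11 or more are disregarded), a protein length within bounds, and
optionally a signal-peptide check supplied as a pluggable predicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .hydropathy import KD_SCALE
from .seqio import ProteinRecord

#: Rejection reason codes used by :func:`apply_filters`.
NO_MOTIF = "NO_MOTIF"
TOO_FEW_CYSTEINES = "TOO_FEW_CYSTEINES"
TOO_MANY_CYSTEINES = "TOO_MANY_CYSTEINES"
INTERNAL_EXTRA_CYSTEINE = "INTERNAL_EXTRA_CYSTEINE"
LENGTH_OUT_OF_RANGE = "LENGTH_OUT_OF_RANGE"
NO_SIGNAL = "NO_SIGNAL"

__all__ = [
    "CysteineTopology",
    "ScanConfig",
    "HydrophobinCandidate",
    "scan_motif",
    "scan_near_miss",
    "apply_filters",
    "naive_signal_heuristic",
    "NO_MOTIF",
    "TOO_FEW_CYSTEINES",
    "TOO_MANY_CYSTEINES",
    "INTERNAL_EXTRA_CYSTEINE",
    "LENGTH_OUT_OF_RANGE",
    "NO_SIGNAL",
]


@dataclass(frozen=True)
class CysteineTopology:
    """Placement of the eight conserved cysteines in one protein.

    ``cys_positions`` are 0-based indices into the sequence, strictly
    increasing, with ``cys_positions[2] == cys_positions[1] + 1`` and
    ``cys_positions[6] == cys_positions[5] + 1`` (the two doublets).
    ``spacers`` are the five variable run lengths (Cys1-2, Cys3-4, Cys4-5,
    Cys5-6, Cys7-8).
    """

    cys_positions: tuple[int, ...]
    spacers: tuple[int, ...]
    extra_cys_before: int = 0
    extra_cys_after: int = 0

    def __post_init__(self) -> None:
        p = self.cys_positions
        if len(p) != 8 or any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError("cys_positions must be 8 strictly increasing indices")
        if p[2] != p[1] + 1 or p[6] != p[5] + 1:
            raise ValueError("Cys2-Cys3 and Cys6-Cys7 must be adjacent doublets")
        expected = (
            p[1] - p[0] - 1,
            p[3] - p[2] - 1,
            p[4] - p[3] - 1,
            p[5] - p[4] - 1,
            p[7] - p[6] - 1,
        )
        if tuple(self.spacers) != expected:
            raise ValueError(f"spacers {self.spacers} inconsistent with positions")

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open interval from Cys1 through Cys8."""
        return (self.cys_positions[0], self.cys_positions[7] + 1)


@dataclass(frozen=True)
class ScanConfig:
    """Motif and candidate-filter parameters.

    Defaults bracket every spacing observed in the Aspergillus survey table
    (spacers 5-14 / 11-40 / 6-25 / 5-8 / 4-44, lengths 83-251 AA, 8-10
    cysteines) with margin.
    """

    spacer_bounds: tuple[tuple[int, int], ...] = (
        (1, 25),
        (5, 50),
        (1, 30),
        (1, 12),
        (1, 50),
    )
    min_total_cys: int = 8
    max_total_cys: int = 10
    min_length: int = 60
    max_length: int = 260
    require_signal: bool = False

    def __post_init__(self) -> None:
        if len(self.spacer_bounds) != 5:
            raise ValueError("spacer_bounds must have 5 (min, max) pairs")
        for lo, hi in self.spacer_bounds:
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid spacer bound ({lo}, {hi})")
        if self.min_total_cys < 8:
            raise ValueError("min_total_cys must be >= 8")
        if self.max_total_cys < self.min_total_cys:
            raise ValueError("max_total_cys < min_total_cys")
        if self.min_length < 1 or self.max_length < self.min_length:
            raise ValueError("invalid length bounds")


@dataclass(frozen=True)
class HydrophobinCandidate:
    """Per-protein filtering outcome; passes iff no rejection reasons."""

    record: ProteinRecord
    topology: Optional[CysteineTopology]
    passed_filters: bool
    rejection_reasons: tuple[str, ...] = ()
    signal_verdict: Optional[bool] = None
    near_miss_7cys: bool = False

    def __post_init__(self) -> None:
        if self.passed_filters != (len(self.rejection_reasons) == 0):
            raise ValueError("passed_filters inconsistent with rejection_reasons")


def _topology_from_window(positions: Sequence[int]) -> Optional[CysteineTopology]:
    p = tuple(positions)
    if p[2] != p[1] + 1 or p[6] != p[5] + 1:
        return None
    # the other five gaps must be true spacers (length >= 1 enforced by caller bounds)
    spacers = (p[1] - p[0] - 1, p[3] - p[2] - 1, p[4] - p[3] - 1,
               p[5] - p[4] - 1, p[7] - p[6] - 1)
    return CysteineTopology(cys_positions=p, spacers=spacers)


def scan_motif(record: ProteinRecord, config: ScanConfig = ScanConfig()) -> list[CysteineTopology]:
    """Find every eight-cysteine motif topology in ``record``.

    Topologies are returned ordered by start position; overlapping alternatives
    are all reported.  A sequence without the motif yields an empty list.
    """
    cys = [i for i, aa in enumerate(record.sequence) if aa == "C"]
    out: list[CysteineTopology] = []
    for w in range(len(cys) - 7):
        topo = _topology_from_window(cys[w : w + 8])
        if topo is None:
            continue
        if all(lo <= s <= hi for s, (lo, hi) in zip(topo.spacers, config.spacer_bounds)):
            out.append(
                CysteineTopology(
                    cys_positions=topo.cys_positions,
                    spacers=topo.spacers,
                    extra_cys_before=w,
                    extra_cys_after=len(cys) - (w + 8),
                )
            )
    return out


def scan_near_miss(record: ProteinRecord, config: ScanConfig = ScanConfig()) -> bool:
    """Detect a seven-cysteine fragment of the motif (last cysteine missing).

    True when some run of seven consecutive cysteines matches
    ``C N{s1} CC N{s2} C N{s3} C N{s4} CC`` with in-bounds spacers s1..s4 and
    no eighth cysteine follows.  Used only for reporting; fragments are never
    auto-accepted.
    """
    if scan_motif(record, config):
        return False
    cys = [i for i, aa in enumerate(record.sequence) if aa == "C"]
    for w in range(len(cys) - 6):
        p = cys[w : w + 7]
        if p[2] != p[1] + 1 or p[6] != p[5] + 1:
            continue
        spacers = (p[1] - p[0] - 1, p[3] - p[2] - 1, p[4] - p[3] - 1, p[5] - p[4] - 1)
        if all(lo <= s <= hi for s, (lo, hi) in zip(spacers, config.spacer_bounds[:4])):
            if w + 7 == len(cys):  # nothing left to serve as Cys8
                return True
    return False


def apply_filters(
    record: ProteinRecord,
    topologies: Sequence[CysteineTopology],
    config: ScanConfig = ScanConfig(),
    signal_check: Optional[Callable[[ProteinRecord], bool]] = None,
) -> HydrophobinCandidate:
    """Apply the candidate filters to a scanned protein.

    A candidate passes iff a motif topology exists, the total cysteine count
    and sequence length are within the configured bounds, all cysteines outside
    the chosen topology lie before Cys1 or after Cys8, and (when
    ``config.require_signal``) the signal predicate accepts the record.  When
    several topologies exist the one minimising internal extra cysteines, then
    the earliest start, is chosen.  All failed criteria are reported.
    """
    reasons: list[str] = []
    topology: Optional[CysteineTopology] = None
    if topologies:
        def internal_extras(t: CysteineTopology) -> int:
            lo, hi = t.span
            inside = record.sequence.count("C", lo, hi)
            return inside - 8

        topology = min(topologies, key=lambda t: (internal_extras(t), t.span[0]))
        if internal_extras(topology) > 0:
            reasons.append(INTERNAL_EXTRA_CYSTEINE)
    else:
        reasons.append(NO_MOTIF)

    n_cys = record.n_cys
    if n_cys < config.min_total_cys:
        reasons.append(TOO_FEW_CYSTEINES)
    elif n_cys > config.max_total_cys:
        reasons.append(TOO_MANY_CYSTEINES)

    if not (config.min_length <= len(record) <= config.max_length):
        reasons.append(LENGTH_OUT_OF_RANGE)

    verdict: Optional[bool] = None
    if signal_check is not None:
        verdict = bool(signal_check(record))
        if config.require_signal and not verdict:
            reasons.append(NO_SIGNAL)

    return HydrophobinCandidate(
        record=record,
        topology=topology,
        passed_filters=not reasons,
        rejection_reasons=tuple(reasons),
        signal_verdict=verdict,
        near_miss_7cys=scan_near_miss(record, config) if not topologies else False,
    )


def naive_signal_heuristic(
    record: ProteinRecord,
    *,
    n_terminal: int = 30,
    core_len: int = 6,
    min_mean_kd: float = 1.6,
) -> bool:
    """Crude secretion-signal check: a hydrophobic core near the N-terminus.

    True iff the first ``n_terminal`` residues contain a run of at least
    ``core_len`` consecutive residues whose mean Kyte-Doolittle value exceeds
    ``min_mean_kd``, with at least one residue preceding the run.  This is a
    deliberately simple approximation of signal-peptide structure (charged
    n-region followed by hydrophobic h-region); it is an annotation only and
    is not applied as a filter by default.
    """
    head = record.sequence[:n_terminal]
    if len(head) < core_len + 1:
        return False
    vals = np.array([KD_SCALE[aa] for aa in head])
    window_means = np.convolve(vals, np.full(core_len, 1.0 / core_len), mode="valid")
    # run may start at index >= 1 so that at least one residue precedes it
    return bool(np.any(window_means[1:] > min_mean_kd))
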