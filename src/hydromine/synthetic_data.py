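"""Synthetic proteomes with ground-truth-labelled planted hydrophobins and decoys.

The generator emulates the statistical shape of a hydrophobin gene as the
mining pipeline sees it: a signal-peptide-like N-terminus (hydrophobic core),
the eight-cysteine motif with configurable spacer lengths, post-doublet
flanks drawn from sign-pure hydrophilic or hydrophobic residue pools (so the
doublet-flank class of each planted gene is known by construction), and a
cysteine-free tail.  Decoy classes exercise each rejection path: a cysteine
planted inside a spacer (broken motif), eleven total cysteines, a missing
eighth cysteine (fragment), a hydrophilic N-terminus (no signal), and an
out-of-bounds length.

It makes no attempt to mimic real Aspergillus residue composition or gene
structure; it is a benchmark for the scanner/classifier contract, not a
proteome simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .motif_scan import (
    LENGTH_OUT_OF_RANGE,
    NO_MOTIF,
    NO_SIGNAL,
    TOO_MANY_CYSTEINES,
)
from .seqio import ProteinRecord, write_fasta

#: residues with strictly negative Kyte-Doolittle values (cysteine-free)
HYDROPHILIC_POOL = "DEKRNQSTGH"
#: residues with strictly positive Kyte-Doolittle values, cysteine excluded
HYDROPHOBIC_POOL = "IVLFMA"
#: general filler: every canonical residue except cysteine
FILLER_POOL = "ADEFGHIKLMNPQRSTVWY"

DECOY_CLASSES = ("broken_motif", "excess_cys", "fragment", "no_signal", "length_out")

#: the rejection reason each decoy class is built to trigger
INTENDED_REJECTION = {
    "broken_motif": NO_MOTIF,
    "excess_cys": TOO_MANY_CYSTEINES,
    "fragment": NO_MOTIF,
    "no_signal": NO_SIGNAL,
    "length_out": LENGTH_OUT_OF_RANGE,
}

__all__ = [
    "SyntheticSpec",
    "GroundTruthLabel",
    "generate_proteome",
    "write_proteome",
    "HYDROPHILIC_POOL",
    "HYDROPHOBIC_POOL",
    "FILLER_POOL",
    "DECOY_CLASSES",
    "INTENDED_REJECTION",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic proteome.

    ``spacer_sampler`` holds inclusive (min, max) ranges for the five variable
    spacers of class-I-style (and mixed-style) genes; the default keeps the
    Cys5-Cys6 spacer fixed at five residues, the class I signature, and the
    other spacers within the ranges observed across the Aspergillus survey.
    Class-II-style genes draw from ``class2_spacer_sampler``, a narrow band
    around the canonical class II spacing (10, 11, 16, 8, 10).
    """

    n_true: int = 6
    n_decoys_per_class: int = 2
    spacer_sampler: tuple[tuple[int, int], ...] = (
        (5, 14),
        (11, 40),
        (6, 25),
        (5, 5),
        (5, 44),
    )
    class2_spacer_sampler: tuple[tuple[int, int], ...] = (
        (9, 11),
        (10, 12),
        (15, 17),
        (7, 9),
        (9, 11),
    )
    flank_styles: Optional[Sequence[str]] = None  # per planted gene; cycles I/II/mixed
    flank_len: int = 5
    signal_len: tuple[int, int] = (18, 24)
    tail_len: tuple[int, int] = (5, 20)
    seed: int = 0
    hydrophilic_pool: str = HYDROPHILIC_POOL
    hydrophobic_pool: str = HYDROPHOBIC_POOL
    filler_pool: str = FILLER_POOL

    def __post_init__(self) -> None:
        for sampler in (self.spacer_sampler, self.class2_spacer_sampler):
            if len(sampler) != 5 or any(hi < lo or lo < 1 for lo, hi in sampler):
                raise ValueError(f"invalid spacer sampler {sampler}")
        if self.spacer_sampler[1][0] < self.flank_len or self.spacer_sampler[4][0] < self.flank_len:
            raise ValueError("post-doublet spacers must be at least flank_len long")
        if self.class2_spacer_sampler[1][0] < self.flank_len or self.class2_spacer_sampler[4][0] < self.flank_len:
            raise ValueError("post-doublet spacers must be at least flank_len long")
        if "C" in self.hydrophilic_pool + self.hydrophobic_pool + self.filler_pool:
            raise ValueError("residue pools must be cysteine-free")
        if set(self.hydrophilic_pool) & set(self.hydrophobic_pool):
            raise ValueError("hydrophilic and hydrophobic pools must be disjoint")
        if self.n_true < 0 or self.n_decoys_per_class < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class GroundTruthLabel:
    """What the generator planted for one record."""

    record_id: str
    is_hydrophobin: bool
    planted_spacers: Optional[tuple[int, ...]]
    flank_style: Optional[str]  # "classI" | "classII" | "mixed"
    decoy_class: str  # "none" or one of DECOY_CLASSES
    expected_class: Optional[str]  # "I" | "II" | "Intermediate" for planted genes

    def __post_init__(self) -> None:
        if self.is_hydrophobin != (self.decoy_class == "none"):
            raise ValueError("is_hydrophobin must match decoy_class == 'none'")


def _draw(rng: np.random.Generator, pool: str, n: int) -> str:
    return "".join(rng.choice(list(pool), size=n)) if n else ""


def _signal(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    """Signal-peptide-like prefix: Met, charged n-region, hydrophobic h-region."""
    total = int(rng.integers(spec.signal_len[0], spec.signal_len[1] + 1))
    core = _draw(rng, "LIVF", 8)
    rest = max(0, total - 11)
    return "M" + _draw(rng, "KR", 2) + core + _draw(rng, "ASG", rest)


def _flank_pools(style: str, spec: SyntheticSpec) -> tuple[str, str]:
    if style == "classI":
        return spec.hydrophilic_pool, spec.hydrophilic_pool
    if style == "classII":
        return spec.hydrophobic_pool, spec.hydrophobic_pool
    if style == "mixed":
        return spec.hydrophilic_pool, spec.hydrophobic_pool
    raise ValueError(f"unknown flank_style {style!r}")


def _motif(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    spacers: Sequence[int],
    style: str,
) -> str:
    """The Cys1..Cys8 region with style-controlled post-doublet flanks."""
    pool1, pool2 = _flank_pools(style, spec)

    def spacer_seq(length: int, flank_pool: Optional[str]) -> str:
        if flank_pool is None:
            return _draw(rng, spec.filler_pool, length)
        flank = _draw(rng, flank_pool, spec.flank_len)
        return flank + _draw(rng, spec.filler_pool, length - spec.flank_len)

    s1, s2, s3, s4, s5 = spacers
    return (
        "C" + spacer_seq(s1, None)
        + "CC" + spacer_seq(s2, pool1)
        + "C" + spacer_seq(s3, None)
        + "C" + spacer_seq(s4, None)
        + "CC" + spacer_seq(s5, pool2)
        + "C"
    )


def _sample_spacers(rng: np.random.Generator, sampler) -> tuple[int, ...]:
    return tuple(int(rng.integers(lo, hi + 1)) for lo, hi in sampler)


_EXPECTED_CLASS = {"classI": "I", "classII": "II", "mixed": "Intermediate"}


def generate_proteome(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], list[GroundTruthLabel]]:
    """Generate a labelled synthetic proteome, deterministically from ``spec.seed``.

    Planted genes follow their flank style on both evidence axes (spacing and
    doublet-flank hydropathy), so a class-I-style gene is expected to be
    called theoretical class I end to end, a class-II-style gene class II,
    and a mixed-style gene Intermediate.  Each decoy class violates exactly
    the filter it is named for (the eleven-cysteine decoy, like its
    real-world precedent, also has a cysteine inside a spacer and therefore
    no intact motif).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    labels: list[GroundTruthLabel] = []

    styles = list(spec.flank_styles) if spec.flank_styles is not None else None
    default_cycle = ("classI", "classII", "mixed")

    for i in range(spec.n_true):
        style = styles[i] if styles else default_cycle[i % 3]
        sampler = spec.class2_spacer_sampler if style == "classII" else spec.spacer_sampler
        spacers = _sample_spacers(rng, sampler)
        tail = _draw(rng, spec.filler_pool, int(rng.integers(*spec.tail_len)))
        seq = _signal(rng, spec) + _motif(rng, spec, spacers, style) + tail
        rid = f"SYN_TRUE_{i:03d}_{style}"
        records.append(ProteinRecord(rid, f"{rid} planted hydrophobin", seq))
        labels.append(
            GroundTruthLabel(rid, True, spacers, style, "none", _EXPECTED_CLASS[style])
        )

    for decoy_class in DECOY_CLASSES:
        for j in range(spec.n_decoys_per_class):
            spacers = _sample_spacers(rng, spec.spacer_sampler)
            tail = _draw(rng, spec.filler_pool, int(rng.integers(*spec.tail_len)))
            style = "classI"
            signal = _signal(rng, spec)
            motif = _motif(rng, spec, spacers, style)

            if decoy_class == "broken_motif":
                # cysteine in the middle of spacer 2, clear of both doublets
                k = 1 + spacers[0] + 2 + spec.flank_len + 2
                motif = motif[:k] + "C" + motif[k + 1 :]
                seq = signal + motif + tail
            elif decoy_class == "excess_cys":
                k = 1 + spacers[0] + 2 + spacers[1] + 1 + 2  # inside spacer 3
                motif = motif[:k] + "C" + motif[k + 1 :]
                seq = signal + motif + tail + "CAAC"  # 11 cysteines total
            elif decoy_class == "fragment":
                motif = motif[:-1] + _draw(rng, spec.filler_pool, 1)
                seq = signal + motif + tail
            elif decoy_class == "no_signal":
                hydrophilic_head = _draw(
                    rng, spec.hydrophilic_pool, len(signal)
                )
                # keep the first spacer hydrophilic too, so no hydrophobic
                # core can arise within the heuristic's N-terminal window
                s1 = spacers[0]
                motif = (
                    "C" + _draw(rng, spec.hydrophilic_pool, s1) + motif[1 + s1 :]
                )
                seq = hydrophilic_head + motif + tail
            elif decoy_class == "length_out":
                seq = signal + motif + tail + _draw(rng, spec.filler_pool, 300)
            else:  # pragma: no cover
                raise AssertionError(decoy_class)

            rid = f"SYN_DECOY_{decoy_class}_{j:03d}"
            records.append(ProteinRecord(rid, f"{rid} decoy", seq))
            labels.append(GroundTruthLabel(rid, False, None, None, decoy_class, None))

    return records, labels


def write_proteome(
    records: Sequence[ProteinRecord],
    labels: Sequence[GroundTruthLabel],
    out_dir: Union[str, Path],
) -> None:
    """Write the proteome FASTA and a ground-truth manifest TSV."""
    import csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(records, out / "proteome.fasta")
    with open(out / "ground_truth.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["record_id", "is_hydrophobin", "planted_spacers", "flank_style",
             "decoy_class", "expected_class"]
        )
        for lab in labels:
            writer.writerow(
                [
                    lab.record_id,
                    int(lab.is_hydrophobin),
                    ",".join(map(str, lab.planted_spacers)) if lab.planted_spacers else "",
                    lab.flank_style or "",
                    lab.decoy_class,
                    lab.expected_class or "",
                ]
            )
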