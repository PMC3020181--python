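"""Protein FASTA I/O and the packaged reference table of Aspergillus hydrophobins.

Sequences are held as plain uppercase strings over the 20 canonical amino
acids plus ``X`` (unknown residue).  A trailing ``*`` stop symbol, common in
translated-ORF FASTA dialects, is stripped on input; an internal ``*`` is an
error.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")

__all__ = [
    "AMINO_ACIDS",
    "ALPHABET",
    "ProteinRecord",
    "Table1Entry",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "load_table1",
    "load_table1_fixture",
]


class FastaParseError(ValueError):
    """Raised when a FASTA file violates the protein-record contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein FASTA entry.

    ``len(record)`` is the residue count (the n(AA) of a report row).
    """

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: illegal residue character(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_cys(self) -> int:
        return self.sequence.count("C")


@dataclass(frozen=True)
class Table1Entry:
    """One row of the packaged Aspergillus hydrophobin table."""

    gene_id: str
    species: str
    size_da: float
    n_aa: int
    n_cys: int
    pattern_text: str
    theoretical_class: str  # "I" | "II" | "Intermediate"
    common_name: str = ""

    @property
    def has_pattern(self) -> bool:
        """True when pattern_text is a spacing pattern (not a fragment note)."""
        return self.pattern_text.startswith("C")


def _clean_sequence(raw: str, record_id: str) -> str:
    seq = str(raw).upper()
    seq = seq.rstrip("*")
    if not seq:
        raise FastaParseError(f"{record_id}: empty sequence")
    if "*" in seq:
        raise FastaParseError(f"{record_id}: internal stop symbol '*'")
    bad = set(seq) - ALPHABET
    if bad:
        raise FastaParseError(
            f"{record_id}: illegal residue character(s) {sorted(bad)!r}"
        )
    return seq


def read_fasta(path: Union[str, Path]) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Sequences are uppercased and a trailing ``*`` is stripped.  Duplicate ids,
    illegal residue characters and internal stops raise :class:`FastaParseError`.
    An empty file yields an empty list.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = _clean_sequence(str(rec.seq), rec.id)
        records.append(ProteinRecord(id=rec.id, description=rec.description, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: Union[str, Path]) -> None:
    """Write records to ``path`` in FASTA format (round-trips with read_fasta)."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def load_table1() -> list[Table1Entry]:
    """Load the packaged 50-entry Aspergillus hydrophobin table.

    Entries are returned in the table's printed order with pattern strings kept
    verbatim.  Exactly one entry (JGI128530) is a fragment without a parseable
    pattern.
    """
    with resources.files("hydromine.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    expected = [
        "species",
        "gene_id",
        "size_da",
        "n_aa",
        "n_cys",
        "pattern_text",
        "theoretical_class",
        "common_name",
    ]
    if list(df.columns) != expected:
        raise RuntimeError("packaged table1 fixture is corrupt: bad columns")
    entries = [
        Table1Entry(
            gene_id=row.gene_id,
            species=row.species,
            size_da=float(row.size_da),
            n_aa=int(row.n_aa),
            n_cys=int(row.n_cys),
            pattern_text=row.pattern_text,
            theoretical_class=row.theoretical_class,
            common_name=row.common_name,
        )
        for row in df.itertuples(index=False)
    ]
    if len(entries) != 50:
        raise RuntimeError(
            f"packaged table1 fixture is corrupt: {len(entries)} entries, expected 50"
        )
    return entries


# Alias used in older call sites / docs.
load_table1_fixture = load_table1
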