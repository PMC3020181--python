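"""Combined class calls, per-candidate statistics and the tabular report.

The theoretical class of a candidate is the conjunction of two independent
lines of evidence: the cysteine-spacing class and the doublet-flank
hydropathy class.  Only a candidate that is class I on both counts is called
class I, only one that is class II on both counts is called class II;
everything else is an intermediate form.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from statistics import mean
from typing import Optional, Sequence, Union

import pandas as pd
from Bio.Data.IUPACData import protein_weights

from .hydropathy import (
    DEFAULT_FLANK_LEN,
    DEFAULT_WINDOW,
    doublet_flank_stats,
    hydropathy_class,
)
from .motif_scan import HydrophobinCandidate, ScanConfig, apply_filters, naive_signal_heuristic, scan_motif
from .seqio import ProteinRecord
from .spacing_grammar import (
    CLASS_I_SPACING,
    CLASS_II_SPACING,
    SpacingClassRule,
    classify_spacing,
    pattern_from_topology,
)

WATER_MASS = 18.0153
# average residue masses: free amino-acid mass minus one water per peptide bond
_RESIDUE_MASS = {aa: w - WATER_MASS for aa, w in protein_weights.items()}
_RESIDUE_MASS["X"] = mean(_RESIDUE_MASS[aa] for aa in "ACDEFGHIKLMNPQRSTVWY")

REPORT_COLUMNS = [
    "species",
    "gene_id",
    "size_da",
    "n_aa",
    "n_cys",
    "pattern_text",
    "spacing_class",
    "hydro_class",
    "theoretical_class",
    "trp_count",
    "proline_near_cleavage",
    "signal_heuristic",
    "external_signal",
]

__all__ = [
    "ClassCall",
    "CandidateReportRow",
    "call_class",
    "compute_mw",
    "composition_stats",
    "classify_candidate",
    "build_report",
    "run_pipeline",
    "REPORT_COLUMNS",
]


@dataclass(frozen=True)
class ClassCall:
    """Spacing, hydropathy and combined theoretical class for one candidate."""

    spacing_class: str
    hydro_class: str
    theoretical_class: str  # "I" | "II" | "Intermediate"


@dataclass(frozen=True)
class CandidateReportRow:
    gene_id: str
    species: str
    mw_da: float
    n_aa: int
    n_cys: int
    pattern_text: str
    spacing_class: str
    hydro_class: str
    theoretical_class: str
    trp_count: int
    proline_near_cleavage: bool
    signal_heuristic: Optional[bool] = None
    external_signal: Optional[bool] = None


def call_class(spacing_class: str, hydro_class: str) -> ClassCall:
    """Combine spacing and hydropathy evidence into the theoretical class.

    Over the full 3x3 evidence grid exactly one cell yields class I
    (classI_spacing + classI_hydropathy), exactly one yields class II, and
    the remaining seven yield Intermediate.
    """
    if spacing_class == CLASS_I_SPACING and hydro_class == "classI_hydropathy":
        theoretical = "I"
    elif spacing_class == CLASS_II_SPACING and hydro_class == "classII_hydropathy":
        theoretical = "II"
    else:
        theoretical = "Intermediate"
    return ClassCall(
        spacing_class=spacing_class,
        hydro_class=hydro_class,
        theoretical_class=theoretical,
    )


def compute_mw(seq: str) -> float:
    """Average molecular weight in Daltons (residue masses plus one water).

    ``X`` contributes the mean of the twenty canonical residue masses.
    """
    if not seq:
        raise ValueError("empty sequence")
    try:
        return sum(_RESIDUE_MASS[aa] for aa in seq) + WATER_MASS
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from exc


def composition_stats(
    record: ProteinRecord,
    cleavage_pos: Optional[int] = None,
    proline_window: int = 3,
) -> tuple[int, bool]:
    """Tryptophan count and proline-near-cleavage flag.

    ``cleavage_pos`` is the 0-based index of the first mature residue, when a
    signal-peptide cleavage position is supplied; the proline check looks for
    a P within ``proline_window`` residues on either side of it and is False
    when no cleavage position is given.
    """
    trp = record.sequence.count("W")
    near = False
    if cleavage_pos is not None:
        if not (0 <= cleavage_pos <= len(record)):
            raise ValueError(f"cleavage_pos {cleavage_pos} outside sequence")
        lo = max(0, cleavage_pos - proline_window)
        hi = min(len(record), cleavage_pos + proline_window + 1)
        near = "P" in record.sequence[lo:hi]
    return trp, near


def classify_candidate(
    candidate: HydrophobinCandidate,
    rule: SpacingClassRule = SpacingClassRule(),
    flank_len: int = DEFAULT_FLANK_LEN,
) -> ClassCall:
    """Full class call for a passed candidate (spacing + doublet-flank hydropathy)."""
    if candidate.topology is None:
        raise ValueError(f"{candidate.record.id}: no motif topology to classify")
    spacing = classify_spacing(pattern_from_topology(candidate.topology), rule)
    hydro = hydropathy_class(
        doublet_flank_stats(candidate.record, candidate.topology, flank_len)
    )
    return call_class(spacing, hydro)


def build_report(
    rows: Sequence[CandidateReportRow],
) -> tuple[pd.DataFrame, dict]:
    """Assemble the report table and its summary.

    Rows are sorted by (species, gene_id).  The summary counts candidates per
    theoretical class and per species, including the per-species min/max.
    """
    df = pd.DataFrame(
        [
            {
                "species": r.species,
                "gene_id": r.gene_id,
                "size_da": round(r.mw_da, 1),
                "n_aa": r.n_aa,
                "n_cys": r.n_cys,
                "pattern_text": r.pattern_text,
                "spacing_class": r.spacing_class,
                "hydro_class": r.hydro_class,
                "theoretical_class": r.theoretical_class,
                "trp_count": r.trp_count,
                "proline_near_cleavage": r.proline_near_cleavage,
                "signal_heuristic": r.signal_heuristic,
                "external_signal": r.external_signal,
            }
            for r in rows
        ],
        columns=REPORT_COLUMNS,
    )
    df = df.sort_values(["species", "gene_id"], kind="stable").reset_index(drop=True)
    class_counts = df["theoretical_class"].value_counts().to_dict()
    species_counts = df["species"].value_counts().to_dict()
    summary = {
        "n_candidates": int(len(df)),
        "class_counts": {k: int(v) for k, v in sorted(class_counts.items())},
        "species_counts": {k: int(v) for k, v in sorted(species_counts.items())},
        "per_species_min": int(min(species_counts.values())) if species_counts else 0,
        "per_species_max": int(max(species_counts.values())) if species_counts else 0,
    }
    assert sum(summary["class_counts"].values()) == summary["n_candidates"]
    return df, summary


def run_pipeline(
    records: Sequence[ProteinRecord],
    config: ScanConfig = ScanConfig(),
    rule: SpacingClassRule = SpacingClassRule(),
    *,
    species: str = "",
    flank_len: int = DEFAULT_FLANK_LEN,
    cleavage_positions: Optional[dict[str, int]] = None,
    external_signal: Optional[dict[str, bool]] = None,
    proline_window: int = 3,
) -> tuple[pd.DataFrame, dict, list[HydrophobinCandidate]]:
    """Scan, filter and classify a collection of proteins.

    Returns the report table of passed candidates, its summary (augmented
    with rejection counts and the 7-cysteine near-miss list), and the full
    per-record candidate list.
    """
    candidates = [
        apply_filters(rec, scan_motif(rec, config), config, naive_signal_heuristic)
        for rec in records
    ]
    rows: list[CandidateReportRow] = []
    for cand in candidates:
        if not cand.passed_filters:
            continue
        call = classify_candidate(cand, rule, flank_len)
        cleave = (cleavage_positions or {}).get(cand.record.id)
        trp, pro = composition_stats(cand.record, cleave, proline_window)
        rows.append(
            CandidateReportRow(
                gene_id=cand.record.id,
                species=species,
                mw_da=compute_mw(cand.record.sequence),
                n_aa=len(cand.record),
                n_cys=cand.record.n_cys,
                pattern_text=str(pattern_from_topology(cand.topology)),
                spacing_class=call.spacing_class,
                hydro_class=call.hydro_class,
                theoretical_class=call.theoretical_class,
                trp_count=trp,
                proline_near_cleavage=pro,
                signal_heuristic=cand.signal_verdict,
                external_signal=(external_signal or {}).get(cand.record.id),
            )
        )
    df, summary = build_report(rows)
    reject_counts: dict[str, int] = {}
    for cand in candidates:
        for reason in cand.rejection_reasons:
            reject_counts[reason] = reject_counts.get(reason, 0) + 1
    summary["rejection_counts"] = dict(sorted(reject_counts.items()))
    summary["near_miss_7cys"] = sorted(
        c.record.id for c in candidates if c.near_miss_7cys
    )
    return df, summary, candidates


def write_report(
    df: pd.DataFrame, summary: dict, out_dir: Union[str, Path]
) -> None:
    """Serialize the report as TSV plus a JSON summary."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "report.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
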