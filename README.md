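# hydromine

Mining protein FASTA files for **hydrophobins** — small (~100–200 AA)
secreted fungal proteins that carry eight conserved cysteines in the pattern

```
C N{s1} CC N{s2} C N{s3} C N{s4} CC N{s5} C
```

where `N` is any residue other than cysteine, `CC` marks the two cysteine
doublets (Cys2–Cys3 and Cys6–Cys7), and `s1..s5` are the five variable
spacer lengths. Hydrophobins self-assemble at hydrophobic/hydrophilic
interfaces and are traditionally split into two classes: **class I**
(variable cysteine spacing, hydrophilic residues after the cysteine
doublets, SDS-insoluble assemblies) and **class II** (near-fixed spacing,
hydrophobic residues after the doublets, soluble assemblies). Many genomic
candidates satisfy neither definition fully and are **intermediate** forms.

The package is aimed at anyone screening fungal proteomes for candidate
hydrophobins without relying on homology search: the motif itself, not
sequence similarity, is the detector.

## What it does

- **Motif scan** (`hydromine.scan_motif`): finds every placement of the
  eight-cysteine motif in a protein. Because no extra cysteine may occur
  between Cys1 and Cys8, valid placements are windows of eight consecutive
  entries of the cysteine-position list, checked for the two doublets and
  per-spacer length bounds.
- **Candidate filters** (`apply_filters`): total cysteine count within 8–10
  (proteins with 11+ cysteines are disregarded), mature-protein length
  within 60–260 residues, all excess cysteines outside the Cys1–Cys8 span,
  and an optional, pluggable signal-peptide predicate (a naive
  hydrophobic-core heuristic ships as an annotation-only default).
  Seven-cysteine near misses (fragments) are reported separately, never
  auto-accepted.
- **Spacing grammar** (`parse_pattern` / `SpacingPattern`): parses and
  renders the `CN{k}` notation, e.g. `CN{10}CCN{11}CN{16}CN{8}CCN{10}C`
  ⇢ spacers (10, 11, 16, 8, 10).
- **Spacing classes** (`classify_spacing`): class I spacing iff the
  Cys5–Cys6 spacer `s4` = 5 (the signature shared by SC3, EAS and MPG1);
  class II iff all five spacers fall in a ±1 band around the canonical
  class II spacing (10, 11, 16, 8, 10); otherwise atypical. Class II is
  tested first and the default regions are disjoint.
- **Hydropathy** (`kd_profile`, `motif_span_profile`, `doublet_flank_stats`):
  Kyte–Doolittle profiles (9-residue unweighted window, full windows only)
  over the Cys1–Cys8 span, cysteine-anchored profile alignment with
  right-edge gap padding, and the doublet-flank rule: mean raw hydropathy of
  the 5 residues after each doublet — both negative ⇒ class I hydropathy,
  both positive ⇒ class II, otherwise mixed.
- **Combined call** (`call_class`): theoretical class I iff class I on both
  spacing and hydropathy; class II iff class II on both; everything else
  Intermediate (7 of the 9 evidence combinations).
- **Synthetic benchmark** (`hydromine.synthetic_data`): seeded generator of
  proteomes with ground-truth-labelled planted hydrophobins (sign-pure
  flank pools, style-matched spacing) and five decoy classes (broken motif,
  11 cysteines, 7-cysteine fragment, no signal, out-of-bounds length).
- **Reference table**: a packaged 50-entry table of Aspergillus
  hydrophobins from nine proteomes (gene, species, size, cysteine count,
  spacing pattern, theoretical class) used for desk-scale self-checks.

## Worked example

Generate a labelled synthetic proteome, then run the full pipeline on it:

```
$ hydromine simulate --n-true 3 --n-decoys-per-class 1 --seed 42 --out demo
wrote 8 records to demo/proteome.fasta

$ hydromine classify --fasta demo/proteome.fasta --species synthetic --out demo_report
{
  "class_counts": {"I": 2, "II": 1, "Intermediate": 1},
  "n_candidates": 4,
  "near_miss_7cys": ["SYN_DECOY_fragment_000"],
  ...
  "rejection_counts": {
    "LENGTH_OUT_OF_RANGE": 1,
    "NO_MOTIF": 3,
    "TOO_FEW_CYSTEINES": 1,
    "TOO_MANY_CYSTEINES": 1
  }
}
```

The three planted genes are recovered with their planted classes (one
class I, one class II, one intermediate "mixed" gene); the no-signal decoy
also passes — and is called class I — because the signal heuristic is an
annotation, not a filter, by default (its `signal_heuristic` column reads
`False`). The fragment decoy is rejected for lacking the motif and is
listed as a 7-cysteine near miss. A row of the report:

```
synthetic  SYN_TRUE_001_classII  11825.8  103  8  CN{10}CCN{11}CN{17}CN{8}CCN{9}C  classII_spacing  classII_hydropathy  II  2  False  True
```

i.e. a 103-residue, 11.8 kDa candidate whose spacing fits the class II
template and whose doublet flanks are hydrophobic, hence theoretical
class II.

The packaged reference table can be self-checked without any input data:

```
$ hydromine table1 --check
{
  "class_labels": {"I": 23, "II": 1, "Intermediate": 26},
  "cys5_cys6_spacer_7_or_8": 6,
  "entries": 50,
  "max_per_species": 8,
  "printed_patterns": 49,
  "spacing_classes": {"atypical": 5, "classII_spacing": 1, "classI_spacing": 44}
}
```

Of the 50 reference entries, 44 show class I spacing (`s4` = 5), exactly
one — ATEG_04730 — fits the class II template, and six patterns have a
Cys5–Cys6 spacer of seven or eight residues.

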