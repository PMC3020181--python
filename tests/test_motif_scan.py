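import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydromine.motif_scan import (
    LENGTH_OUT_OF_RANGE,
    NO_MOTIF,
    TOO_MANY_CYSTEINES,
    CysteineTopology,
    ScanConfig,
    apply_filters,
    naive_signal_heuristic,
    scan_motif,
)
from hydromine.seqio import ProteinRecord

from conftest import regex_oracle, subset_oracle


def build_motif_sequence(spacers, signal="M" + "K" + "LLLLLLLL" + "SA", tail="GSTA"):
    """Assemble signal + C/CC motif + tail with non-cysteine spacers."""
    s1, s2, s3, s4, s5 = spacers
    motif = (
        "C" + "A" * s1 + "CC" + "G" * s2 + "C" + "S" * s3
        + "C" + "T" * s4 + "CC" + "N" * s5 + "C"
    )
    return signal + motif + tail


class TestScanMotif:
    def test_no_cysteines_no_motif(self):
        rec = ProteinRecord("p", "", "A" * 40)
        assert scan_motif(rec) == []

    def test_planted_motif_recovered(self):
        # spacing of the An03g02400 pattern, planted in a synthetic carrier
        seq = build_motif_sequence((6, 31, 23, 5, 6), tail="G" * 40)
        rec = ProteinRecord("p", "", seq)
        topos = scan_motif(rec)
        assert len(topos) == 1
        assert topos[0].spacers == (6, 31, 23, 5, 6)
        assert topos[0].extra_cys_before == 0
        assert topos[0].extra_cys_after == 0

    def test_extra_cysteines_outside_span_counted(self):
        seq = "CAA" + build_motif_sequence((6, 31, 23, 5, 6)) + "AAC"
        topos = scan_motif(ProteinRecord("p", "", seq))
        assert len(topos) == 1
        assert topos[0].extra_cys_before == 1
        assert topos[0].extra_cys_after == 1

    def test_cysteine_inside_spacer_breaks_motif(self):
        seq = build_motif_sequence((6, 31, 23, 5, 6))
        # replace a residue in the middle of spacer 2 with a cysteine
        start = seq.index("C")
        k = start + 1 + 6 + 2 + 15
        broken = seq[:k] + "C" + seq[k + 1 :]
        assert scan_motif(ProteinRecord("p", "", broken)) == []

    def test_agrees_with_subset_oracle_on_sparse_cysteine_sequences(self, default_config):
        rng = np.random.default_rng(42)
        residues = np.array(list("ACGS"))
        probs = np.array([0.6, 0.08, 0.16, 0.16])  # <= ~14 cysteines typical
        checked = 0
        for _ in range(300):
            n = int(rng.integers(30, 251))
            seq = "".join(rng.choice(residues, size=n, p=probs))
            if seq.count("C") > 14:
                continue
            got = sorted(t.cys_positions for t in scan_motif(ProteinRecord("p", "", seq), default_config))
            assert got == subset_oracle(seq, default_config)
            checked += 1
        assert checked > 200

    def test_agrees_with_regex_oracle_on_dense_cysteine_sequences(self, default_config):
        rng = np.random.default_rng(7)
        residues = np.array(list("ACGS"))
        for _ in range(300):
            n = int(rng.integers(20, 201))
            seq = "".join(rng.choice(residues, size=n))
            got = sorted(t.cys_positions for t in scan_motif(ProteinRecord("p", "", seq), default_config))
            assert got == regex_oracle(seq, default_config)

    @given(
        widen=st.integers(0, 4),
        delta=st.integers(1, 10),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_widening_spacer_bounds_never_removes_topologies(self, widen, delta, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(np.array(list("ACGS")), size=150))
        rec = ProteinRecord("p", "", seq)
        base = ScanConfig()
        bounds = list(base.spacer_bounds)
        lo, hi = bounds[widen]
        bounds[widen] = (max(1, lo - delta), hi + delta)
        wide = ScanConfig(spacer_bounds=tuple(bounds))
        narrow_hits = {t.cys_positions for t in scan_motif(rec, base)}
        wide_hits = {t.cys_positions for t in scan_motif(rec, wide)}
        assert narrow_hits <= wide_hits

    def test_deterministic(self, default_config):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(np.array(list("ACGS")), size=180))
        rec = ProteinRecord("p", "", seq)
        assert scan_motif(rec, default_config) == scan_motif(rec, default_config)


class TestTopologyInvariants:
    def test_doublet_adjacency_enforced(self):
        with pytest.raises(ValueError):
            CysteineTopology(cys_positions=(0, 2, 5, 10, 15, 20, 21, 30), spacers=(1, 4, 4, 4, 8))

    def test_spacer_consistency_enforced(self):
        with pytest.raises(ValueError):
            CysteineTopology(cys_positions=(0, 2, 3, 10, 15, 20, 21, 30), spacers=(0, 0, 0, 0, 0))


class TestApplyFilters:
    def test_eleven_cysteines_rejected(self):
        seq = build_motif_sequence((6, 31, 23, 5, 6)) + "CAACAAC"
        rec = ProteinRecord("p", "", seq)
        cand = apply_filters(rec, scan_motif(rec), ScanConfig())
        assert not cand.passed_filters
        assert TOO_MANY_CYSTEINES in cand.rejection_reasons

    def test_compliant_candidate_passes(self):
        seq = build_motif_sequence((6, 31, 23, 5, 6), tail="G" * 20)
        rec = ProteinRecord("p", "", seq)
        cand = apply_filters(rec, scan_motif(rec), ScanConfig())
        assert cand.passed_filters
        assert cand.rejection_reasons == ()

    def test_ninth_cysteine_before_motif_allowed(self):
        seq = "MAC" + build_motif_sequence((6, 31, 23, 5, 6), signal="ALKS", tail="G" * 20)
        rec = ProteinRecord("p", "", seq)
        assert rec.n_cys == 9
        cand = apply_filters(rec, scan_motif(rec), ScanConfig())
        assert cand.passed_filters

    def test_length_out_of_range_rejected(self):
        seq = build_motif_sequence((6, 31, 23, 5, 6), tail="G" * 300)
        rec = ProteinRecord("p", "", seq)
        cand = apply_filters(rec, scan_motif(rec), ScanConfig())
        assert cand.rejection_reasons == (LENGTH_OUT_OF_RANGE,)

    def test_no_motif_reported(self):
        rec = ProteinRecord("p", "", "A" * 100)
        cand = apply_filters(rec, [], ScanConfig())
        assert NO_MOTIF in cand.rejection_reasons
        assert cand.topology is None

    def test_all_failed_criteria_enumerated(self):
        rec = ProteinRecord("p", "", "A" * 30)  # no motif, too few cys, too short
        cand = apply_filters(rec, [], ScanConfig())
        assert set(cand.rejection_reasons) >= {NO_MOTIF, LENGTH_OUT_OF_RANGE}

    def test_signal_requirement(self):
        # hydrophilic head and hydrophilic early spacers: no hydrophobic core
        motif = "C" + "G" * 6 + "CC" + "G" * 31 + "C" + "S" * 23 + "C" + "T" * 5 + "CC" + "N" * 6 + "C"
        rec = ProteinRecord("p", "", "D" * 12 + motif + "G" * 20)
        cfg = ScanConfig(require_signal=True)
        cand = apply_filters(rec, scan_motif(rec, cfg), cfg, naive_signal_heuristic)
        assert "NO_SIGNAL" in cand.rejection_reasons
        assert cand.signal_verdict is False


class TestNaiveSignalHeuristic:
    def test_leucine_run_accepted(self):
        rec = ProteinRecord("p", "", "M" + "LLLLLLLL" + "DDDDDDDDDDDDDDDDDDDD")
        assert naive_signal_heuristic(rec)

    def test_all_glycine_rejected(self):
        rec = ProteinRecord("p", "", "G" * 60)
        assert not naive_signal_heuristic(rec)

    def test_run_must_be_preceded_by_a_residue(self):
        # a marginal 6-residue core right at position 0 does not count, and
        # every shifted window dips below the threshold
        rec = ProteinRecord("p", "", "MMMMMM" + "R" * 40)
        assert not naive_signal_heuristic(rec)
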