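"""Motif grammar compilation, scanning, and the catalytic-site scanners."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peroxfam import motifs, references
from peroxfam.sequence_io import ProteinRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def rec(seq, pid="p"):
    return ProteinRecord(pid, "sp", seq)


class TestCompile:
    def test_cp_pattern_structure(self):
        p = motifs.compile_pattern("PXXX[TS]XXC")
        assert len(p.elements) == 8
        assert p.elements[0] == ("set", frozenset("P"))
        assert p.elements[4] == ("set", frozenset("TS"))
        assert p.elements[7] == ("set", frozenset("C"))
        assert all(e == ("any",) for i, e in enumerate(p.elements) if i in (1, 2, 3, 5, 6))

    def test_srx_pattern_alternation(self):
        p = motifs.compile_pattern("F[SG]GCHR")
        assert len(p.elements) == 6
        assert p.elements[1] == ("set", frozenset("SG"))

    def test_bounded_gap_triad(self):
        p = motifs.compile_pattern("HX{0,40}SX{0,40}D")
        assert p.elements[1] == ("gap", 0, 40)
        assert p.min_length == 3

    @pytest.mark.parametrize("bad,col", [
        ("PX[TS", 2), ("X{2,1}", 1), ("PX{a,b}", 2), ("P?Q", 1), ("", 0),
    ])
    def test_syntax_errors_carry_column(self, bad, col):
        with pytest.raises(motifs.MotifSyntaxError) as ei:
            motifs.compile_pattern(bad)
        assert ei.value.column == col

    def test_all_wildcard_pattern_rejected(self):
        with pytest.raises(motifs.MotifSyntaxError):
            motifs.compile_pattern("XXX")


class TestScan:
    def test_cp_match_and_catalytic_position(self):
        m = motifs.scan(rec("MKPVDFTFVCR"), motifs.CP_PATTERN)
        assert len(m) == 1
        assert (m[0].start, m[0].end) == (3, 10)
        assert m[0].substring == "PVDFTFVC"
        assert m[0].catalytic_positions["CP"] == 10

    def test_ts_slot_violation_blocks_match(self):
        assert motifs.scan(rec("MKPVDFAFVCR"), motifs.CP_PATTERN) == []

    def test_region_constrains_match_start(self):
        seq = "PAAATAAC" + "G" * 10 + "PAAATAAC"
        p = motifs.CP_PATTERN
        assert len(motifs.scan(seq, p)) == 2
        only_late = motifs.scan(seq, p, region=(15, 26))
        assert [m.start for m in only_late] == [19]
        with pytest.raises(motifs.RegionError):
            motifs.scan(seq, p, region=(1, 999))

    def test_sec_equivalence_flag(self):
        seq = "PAAATAAU"
        assert motifs.scan(seq, motifs.CP_PATTERN) == []
        m = motifs.scan(seq, motifs.CP_PATTERN, sec_equivalence=True)
        assert len(m) == 1 and m[0].substring.endswith("U")

    @pytest.mark.parametrize("name,spec", [
        ("CP", "PXXX[TS]XXC"),
        ("SRX", "F[SG]GCHR"),
        ("GGLG", "GGLG"),
        ("YF", "YF"),
        ("GXSXG", "GXSXG"),
        ("PLA2", "HX{0,60}SX{0,60}D"),
    ])
    def test_scanner_equals_exhaustive_offset_oracle(self, oracle, name, spec):
        rng = np.random.default_rng(17)
        pattern = motifs.compile_pattern(spec, name=name)
        for _ in range(60):
            seq = "".join(rng.choice(list(AA20), size=300))
            got = [(m.start, m.end) for m in motifs.scan(seq, pattern)]
            assert got == oracle(seq, spec)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet=AA20, min_size=1, max_size=120))
    def test_matched_substring_equals_slice_property(self, seq):
        for pattern in motifs.BUNDLED_PATTERNS.values():
            for m in motifs.scan(seq, pattern):
                assert m.substring == seq[m.start - 1 : m.end]
                for pos in m.catalytic_positions.values():
                    assert m.start <= pos <= m.end

    def test_shrinking_region_never_adds_matches(self):
        rng = np.random.default_rng(23)
        seq = "".join(rng.choice(list(AA20), size=200))
        p = motifs.GXSXG_PATTERN
        full = {(m.start, m.end) for m in motifs.scan(seq, p)}
        for lo, hi in [(1, 200), (20, 150), (50, 100), (70, 80)]:
            sub = {(m.start, m.end) for m in motifs.scan(seq, p, region=(lo, hi))}
            assert sub <= full

    def test_corrupting_a_fixed_residue_removes_only_that_motif(self):
        base = list("A" * 140)
        base[9:17] = "PVDFTFVC"     # CP at 10-17
        base[39:45] = "FSGCHR"      # SRX at 40-45
        base[69:73] = "GGLG"
        base[99:104] = "GASTG"      # GXSXG
        seq = "".join(base)
        r0 = {n: len(motifs.scan(seq, p)) for n, p in motifs.BUNDLED_PATTERNS.items()}
        mutated = seq[:40] + "A" + seq[41:]  # break SRX alternation slot... fixed F stays
        mutated = seq[:39] + "A" + seq[40:]  # break the SRX leading F
        r1 = {n: len(motifs.scan(mutated, p)) for n, p in motifs.BUNDLED_PATTERNS.items()}
        assert r1["SRX_NTERM"] == r0["SRX_NTERM"] - 1
        for name in r0:
            if name != "SRX_NTERM":
                assert r1[name] == r0[name]


class TestFindCp:
    def test_leftmost_of_two_matches(self):
        seq = "PAAATAAC" + "W" * 20 + "PAAASAAC"
        m = motifs.find_cp(rec(seq))
        assert m.start == 1 and m.catalytic_positions["CP"] == 8
        assert len(motifs.scan(seq, motifs.CP_PATTERN)) == 2

    def test_knockout_to_serine_is_definitive_negative(self):
        seq = "PAAATAAS" + "W" * 20
        assert motifs.find_cp(rec(seq)) is None


class TestFindCr:
    def test_intact_context_reports_present(self):
        seq = "W" * 30 + "GEVCPAGW" + "W" * 30
        cr = motifs.find_cr(rec(seq), "AhpC-PRX1")
        assert cr.status == "present" and cr.position == 34

    def test_valine_substitution_detected(self):
        seq = "W" * 30 + "GEVVPAGW" + "W" * 30
        cr = motifs.find_cr(rec(seq), "AhpC-PRX1")
        assert cr.status == "substituted" and cr.residue == "V"

    def test_truncated_sequence_lacks_context(self):
        cr = motifs.find_cr(rec("W" * 40), "AhpC-PRX1")
        assert cr.status == "absent"

    def test_subfamily_without_context_is_absent(self):
        seq = "W" * 30 + "GEVCPAGW" + "W" * 30
        assert motifs.find_cr(rec(seq), "PRX6").status == "absent"

    def test_search_restricted_after_cp(self):
        seq = "GEVCPAGW" + "W" * 30
        assert motifs.find_cr(rec(seq), "AhpC-PRX1", after=20).status == "absent"


class TestPla2Triad:
    # constructed over an alphabet free of stray H/S/D so roles are exact
    def test_planted_ordered_triad_is_full(self):
        seq = "A" * 10 + "H" + "A" * 15 + "GASTG" + "A" * 15 + "D" + "A" * 10
        t = motifs.pla2_triad(rec(seq), region=(1, len(seq)))
        assert t.status == "full"
        assert t.positions["S"] == 29  # the GXSXG serine is preferred

    def test_order_violation_is_absent(self):
        seq = "A" * 10 + "D" + "A" * 15 + "H" + "A" * 30
        t = motifs.pla2_triad(rec(seq), region=(1, len(seq)))
        assert t.status == "absent"

    def test_mutated_serine_is_partial_missing_s(self):
        seq = "A" * 10 + "H" + "A" * 20 + "D" + "A" * 10
        t = motifs.pla2_triad(rec(seq), region=(1, len(seq)))
        assert t.status == "partial" and t.missing == ("S",)

    def test_gap_bound_enforced(self):
        seq = "H" + "A" * 100 + "S" + "A" * 5 + "D"
        t = motifs.pla2_triad(rec(seq), region=(1, len(seq)))
        assert t.status != "full"


class TestGxsxg:
    def test_present_and_violation(self):
        assert motifs.gxsxg(rec("WWGASTGWW"))
        assert not motifs.gxsxg(rec("WWGASTAWW"))

    def test_matches_oracle_on_random_sequences(self, oracle):
        rng = np.random.default_rng(31)
        for _ in range(40):
            seq = "".join(rng.choice(list(AA20), size=250))
            got = [(m.start, m.end) for m in motifs.scan(seq, motifs.GXSXG_PATTERN)]
            assert got == oracle(seq, "GXSXG")


class TestSrxMotif:
    @pytest.mark.parametrize("seq,expected", [
        ("AAFSGCHRAA", True), ("AAFGGCHRAA", True), ("AAFAGCHRAA", False),
    ])
    def test_both_alternation_branches(self, seq, expected):
        assert motifs.srx_motif(rec(seq)) is expected


class TestGpxTetrad:
    def test_sec_at_catalytic_slot_is_selenium_dependent(self):
        cons = references.load_gpx_group_consensi()["GPX1/2"]
        call = references.gpx_tetrad(rec(cons))
        assert call.catalysis == references.SELENIUM
        assert call.residues["UC"] == "U"

    def test_sec_to_cys_flips_catalysis_type(self):
        ref = references.load_tetrad_reference()
        cons = references.load_gpx_group_consensi()["GPX1/2"]
        slot = ref.positions["UC"]
        mutated = cons[: slot - 1] + "C" + cons[slot:]
        assert references.gpx_tetrad(rec(mutated)).catalysis == references.CYSTEINE

    def test_deleted_catalytic_slot_is_undetermined(self):
        ref = references.load_tetrad_reference()
        cons = references.load_gpx_group_consensi()["GPX1/2"]
        slot = ref.positions["UC"]
        deleted = cons[: slot - 6] + cons[slot + 5 :]
        call = references.gpx_tetrad(rec(deleted))
        assert call.catalysis == references.UNDETERMINED

    def test_short_fragment_fails_coverage(self):
        cons = references.load_gpx_group_consensi()["GPX1/2"]
        call = references.gpx_tetrad(rec(cons[:40]))
        assert call.catalysis == references.UNDETERMINED
        assert "coverage" in call.reason


class TestHyperoxMotifs:
    def _ahpc_like(self, gglg=True, yf=True, his="H"):
        base = list("A" * 240)
        base[139:146] = f"FRY{his}EIA"
        if gglg:
            base[169:173] = "GGLG"
        if yf:
            base[189:191] = "YF"
        base[204:211] = "LDNWSVK"
        return rec("".join(base))

    def test_planted_motifs_found(self):
        r = motifs.hyperox_motifs(self._ahpc_like())
        assert r.gglg and r.yf and r.a_b_substitutions == ()

    def test_yf_deleted(self):
        r = motifs.hyperox_motifs(self._ahpc_like(yf=False))
        assert r.gglg and not r.yf

    def test_motif_a_his_substitution_reported(self):
        r = motifs.hyperox_motifs(self._ahpc_like(his="A"))
        assert ("motif_a", "His", "A") in r.a_b_substitutions

    def test_cterm_restriction(self):
        base = list("A" * 240)
        base[9:13] = "GGLG"  # N-terminal occurrence only
        r = motifs.hyperox_motifs(rec("".join(base)))
        assert not r.gglg
        r_full = motifs.hyperox_motifs(rec("".join(base)), cterm_only=False)
        assert r_full.gglg


class TestSanitizer:
    def test_removes_all_unkept_matches(self):
        rng = np.random.default_rng(41)
        pats = list(motifs.BUNDLED_PATTERNS.values())
        for _ in range(20):
            seq = "".join(rng.choice(list(AA20), size=400))
            clean = motifs.break_accidental_matches(seq, pats)
            for p in pats:
                assert motifs.scan(clean, p) == []

    def test_keeps_planted_matches(self):
        seq = "W" * 50 + "FSGCHR" + "W" * 50
        clean = motifs.break_accidental_matches(
            seq, [motifs.SRX_PATTERN], keep={("SRX_NTERM", 51)}, protected=[(51, 56)]
        )
        assert clean == seq
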