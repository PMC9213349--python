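"""Tryptic digestion, peptide-to-reference mapping, coverage and
Gly-Xaa-Yaa validation."""

import numpy as np
import pytest

from paleopept.collagen import (
    coverage,
    map_peptide,
    tryptic_digest,
    validate_triplets,
    diagnostic_sites,
)
from paleopept.evidence import ReferenceSequence
from paleopept.synthetic_references import (
    OBSERVED_COL1A1_PEPTIDES,
    OBSERVED_COL1A2_PEPTIDES,
)

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def random_seq(rng, length):
    return "".join(rng.choice(AA, size=length))


class TestTrypticDigest:
    def test_single_site_cleavage(self):
        products = tryptic_digest("AAAKGGGR", max_missed=0)
        assert [(d.peptide, d.start, d.end) for d in products] == [
            ("AAAK", 1, 4), ("GGGR", 5, 8)
        ]

    def test_missed_cleavage_enumeration(self):
        products = tryptic_digest("AKRK", max_missed=1)
        assert {(d.peptide, d.missed) for d in products} == {
            ("AK", 0), ("R", 0), ("K", 0), ("AKR", 1), ("RK", 1),
        }

    def test_proline_rule_blocks_cleavage(self):
        assert [d.peptide for d in tryptic_digest("AKPGGR", max_missed=0)] == ["AKPGGR"]
        assert [d.peptide for d in tryptic_digest("AKPGGR", max_missed=0,
                                                  proline_rule=False)] == ["AK", "PGGR"]

    def test_zero_missed_products_reassemble_input(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            seq = random_seq(rng, int(rng.integers(5, 120)))
            frags = [d for d in tryptic_digest(seq, max_missed=0)]
            assert "".join(d.peptide for d in frags) == seq
            # coordinates tile the sequence
            assert frags[0].start == 1 and frags[-1].end == len(seq)

    def test_agrees_with_pyteomics_cleave(self):
        from pyteomics import parser as pparser

        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = random_seq(rng, 80)
            mine = {d.peptide for d in tryptic_digest(seq, max_missed=2, min_len=1)}
            # same dialect: cleave after K/R except before P
            theirs = pparser.cleave(seq, r"[KR](?=[^P])", missed_cleavages=2)
            assert mine == set(theirs)


REF_EDIT_CASES = [
    # (observed peptide, expected (type, ref_position, ref_res, obs_res) calls)
    (
        "GNDGATGAAGPPGPTGPAGPPGFPGAVGAK",
        [("deletion", 174, "V", "-"), ("substitution", 175, "S", "G")],
    ),
    ("VGPPGPSGNAGPPGPPGPAGKEGAK", [("substitution", 746, "G", "A")]),
    ("GPPGSAGTPGKDGLNGLPGPIGPPGPR", [("substitution", 989, "A", "T")]),
]


class TestMapPeptide:
    @pytest.mark.parametrize("peptide,expected", REF_EDIT_CASES)
    def test_published_col1a1_edit_calls(self, col1a1, peptide, expected):
        aln = map_peptide(peptide, col1a1)
        assert aln is not None and not aln.ambiguous
        assert [
            (e.type, e.ref_position, e.ref_residue, e.obs_residue) for e in aln.edits
        ] == expected

    def test_published_col1a2_substitution(self, col1a2):
        aln = map_peptide("GSDGEAGSAGPAGPPGLR", col1a2)
        assert [(e.type, e.ref_position, e.ref_residue, e.obs_residue)
                for e in aln.edits] == [("substitution", 305, "S", "D")]
        assert (aln.ref_start, aln.ref_end) == (303, 320)

    def test_database_entry_missing_glycine_detected_as_insertion(self, col1a1):
        # reference chain lacks G at position 400; the observed fragment has it
        aln = map_peptide("TGPPGPAGQDGRPGPPGPPGAR", col1a1)
        assert [(e.type, e.ref_position, e.obs_residue) for e in aln.edits] == [
            ("insertion", 399, "G")
        ]

    def test_exact_match_has_no_edits(self, col1a1):
        aln = map_peptide("VGPPGPSGNAGPPGPPGPAGKEGGK", col1a1)
        assert aln.edits == () and (aln.ref_start, aln.ref_end) == (723, 747)

    def test_short_peptide_skipped(self, col1a1):
        assert map_peptide("GPAGK", col1a1) is None

    def test_excess_edits_rejected(self, col1a1):
        aln = map_peptide("GNDGATGAAGPPGPTGPAGPPGFPGAVGAK", col1a1, max_edits=1)
        assert aln is None

    def test_zero_edit_mapping_equals_substring_search(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            ref_seq = random_seq(rng, 200)
            ref = ReferenceSequence("R", "", ref_seq)
            start = int(rng.integers(0, 180))
            pep = ref_seq[start : start + 15]
            aln = map_peptide(pep, ref, max_edits=0)
            expected_start = ref_seq.index(pep) + 1
            assert aln is not None and aln.edits == ()
            assert aln.ref_start == expected_start
            # a peptide absent from the reference finds no 0-edit placement
            foreign = random_seq(rng, 15)
            if foreign not in ref_seq:
                assert map_peptide(foreign, ref, max_edits=0) is None

    def test_numbering_offset_respected(self):
        ref = ReferenceSequence("R", "", "GGGAAAGGG", numbering_offset=100)
        aln = map_peptide("AAAGGG", ref, max_edits=0, min_len=6)
        assert (aln.ref_start, aln.ref_end) == (103, 108)


class TestCoverage:
    def test_single_fragment_arithmetic(self):
        ref = ReferenceSequence("R", "", "A" * 300)
        aln = map_peptide("A" * 30, ref, max_edits=0)
        rep = coverage([aln], ref)
        assert rep.pct_covered == pytest.approx(10.0)

    def test_overlapping_fragments_union(self, col1a1):
        a = map_peptide("VGPPGPSGNAGPPGPPGPAGKEGGK", col1a1)
        rep1 = coverage([a], col1a1)
        rep2 = coverage([a, a], col1a1)
        assert rep1.pct_covered == rep2.pct_covered
        assert rep2.n_fragments == 2

    def test_deleted_positions_not_covered(self, col1a1):
        aln = map_peptide("GNDGATGAAGPPGPTGPAGPPGFPGAVGAK", col1a1)
        rep = coverage([aln], col1a1)
        assert 174 not in rep.covered_positions
        assert 175 in rep.covered_positions  # substituted position is covered

    def test_monotone_in_alignment_set(self, col1a1):
        alns = [map_peptide(p, col1a1) for p in OBSERVED_COL1A1_PEPTIDES]
        pcts = [coverage(alns[:k], col1a1).pct_covered for k in range(1, len(alns) + 1)]
        assert pcts == sorted(pcts)

    def test_wrong_reference_rejected(self, col1a1, col1a2):
        aln = map_peptide(OBSERVED_COL1A2_PEPTIDES[0], col1a2)
        with pytest.raises(ValueError):
            coverage([aln], col1a1)


class TestTriplets:
    def test_mammoth_fragment_respects_triplets(self):
        rep = validate_triplets("GNDGATGAAGPPGPTGPAGPPGFPGAVGAK", frame=0)
        assert rep.ok

    def test_vs_trait_breaks_triplets(self):
        rep = validate_triplets("GNDGATGAAGPPVSPTGPAGPPGFPGAVGAK", frame=0,
                                region_start=162)
        assert not rep.ok
        assert any(v.residue == "V" and v.ref_position == 174 for v in rep.violations)

    def test_gxx_pattern_clean_any_x(self):
        rep = validate_triplets("GXYGQWGMN".replace("X", "A").replace("Y", "P"))
        assert rep.frame == 0 and rep.ok

    def test_frame_selection_minimises_violations(self):
        # triplet structure shifted by one residue
        rep = validate_triplets("AGPAGPAGPA", frame=None)
        assert rep.frame == 1 and rep.ok

    def test_too_short_region_rejected(self):
        with pytest.raises(ValueError):
            validate_triplets("GA")


class TestDiagnosticSites:
    @pytest.fixture()
    def panel(self):
        # three panel chains agreeing at 746 (G) and differing at 701 (P vs A)
        base = list("G" * 1000)
        a = base.copy(); a[700] = "P"; a[745] = "G"
        b = base.copy(); b[700] = "P"; b[745] = "G"
        c = base.copy(); c[700] = "A"; c[745] = "G"
        return {
            "elephant": ReferenceSequence("E", "", "".join(a)),
            "mammoth_ref": ReferenceSequence("M", "", "".join(b)),
            "mastodon": ReferenceSequence("D", "", "".join(c)),
        }

    def test_unique_observed_residue_is_diagnostic(self, panel):
        df = diagnostic_sites({746: "A"}, panel)
        assert bool(df.loc[df.position == 746, "diagnostic"].iloc[0])

    def test_observed_matching_a_member_not_diagnostic(self, panel):
        df = diagnostic_sites({701: "P"}, panel)
        row = df.loc[df.position == 701].iloc[0]
        assert not row.diagnostic
        assert row.separates_panel  # still separates elephantids from mastodon
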