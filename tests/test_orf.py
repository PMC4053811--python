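"""Translation, ORF search, frames, splice QC and edge matching."""

import itertools
import random

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from genecurate import (
    ReferenceSequence,
    SequenceAlteration,
    edge_matches,
    longest_orf,
    reading_frame,
    reverse_complement,
    six_frame_translation,
    splice_qc,
    translate,
)
from genecurate.orf import translate_display

from conftest import (
    WORKED_MRNA,
    WORKED_PEPTIDE,
    make_transcript,
    oracle_longest_orf,
    random_dna,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=120)


class TestTranslate:
    @pytest.mark.parametrize("cds,pep", [
        ("ATGAAATAA", "MK"),
        (WORKED_MRNA, WORKED_PEPTIDE),
        ("ATGNAA", "MX"),
        ("ATGAA", "M"),          # trailing partial codon ignored
        ("", ""),
    ])
    def test_examples(self, cds, pep):
        assert translate(cds) == pep

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(dna)
    def test_agrees_with_biopython(self, seq):
        trimmed = seq[:len(seq) - len(seq) % 3]
        assert translate(seq) == str(Seq(trimmed).translate(to_stop=True))


class TestLongestOrf:
    def test_single_orf(self):
        r = longest_orf("ATGAAATAA")
        assert (r.start, r.end, r.has_stop, r.peptide) == (0, 9, True, "MK")

    def test_no_atg_returns_none(self):
        assert longest_orf("CCCCCC") is None

    def test_partial_orf_extends_to_end(self):
        r = longest_orf("ATGAAAAAA")
        assert (r.start, r.end, r.has_stop) == (0, 9, False)

    def test_ties_broken_by_most_5prime_start(self):
        # two ATG..stop ORFs of equal length in different frames
        r = longest_orf("ATGAAATAAATGAAATAA")
        assert r.start == 0

    def test_exhaustive_small_strings(self):
        # all strings up to length 9 over the reduced alphabet {A,T,G}
        for n in range(1, 10):
            for tup in itertools.product("ATG", repeat=n):
                s = "".join(tup)
                r = longest_orf(s)
                expected = oracle_longest_orf(s)
                got = None if r is None else (r.start, r.end, r.has_stop)
                assert got == expected, s

    def test_random_300mers_match_bruteforce(self):
        rng = random.Random(11)
        for _ in range(200):
            s = random_dna(rng, 300)
            r = longest_orf(s)
            expected = oracle_longest_orf(s)
            got = None if r is None else (r.start, r.end, r.has_stop)
            assert got == expected

    def test_peptide_consistent_with_span(self):
        r = longest_orf(WORKED_MRNA)
        assert r.peptide == WORKED_PEPTIDE
        assert (r.end - r.start) % 3 == 0 and r.has_stop
        assert len(r.peptide) == (r.end - r.start) // 3 - 1


class TestSixFrames:
    def test_forward_frame_one(self):
        assert six_frame_translation("ATGAAA")[0] == "MK"

    def test_stops_render_as_star_without_termination(self):
        assert six_frame_translation("TAAATGTAA")[0] == "*M*"

    def test_reverse_frames_equal_forward_of_revcomp(self):
        rng = random.Random(5)
        s = random_dna(rng, 60)
        frames = six_frame_translation(s)
        assert frames[3:] == six_frame_translation(reverse_complement(s))[:3]

    def test_each_frame_matches_naive_shift(self):
        rng = random.Random(6)
        s = random_dna(rng, 60)
        frames = six_frame_translation(s)
        for f in range(3):
            assert frames[f] == translate_display(s[f:])


class TestReadingFrame:
    def test_first_coding_exon_is_frame_zero(self):
        t = make_transcript([(0, 9), (17, 26)], cds=(0, 26))
        assert reading_frame(t, "t1-e1") == 0

    @pytest.mark.parametrize("first_exon_end,expected", [(9, 0), (10, 1)])
    def test_second_exon_frame_mod3(self, first_exon_end, expected):
        t = make_transcript([(0, first_exon_end), (17, 26)],
                            cds=(0, 26))
        assert reading_frame(t, "t1-e2") == expected

    def test_noncoding_exon_has_no_frame(self):
        t = make_transcript([(0, 9), (17, 26)], cds=(17, 26))
        assert reading_frame(t, "t1-e1") is None

    def test_frames_match_codon_walk_on_multi_exon_cds(self):
        exons = [(0, 7), (10, 21), (30, 38), (50, 59)]
        t = make_transcript(exons, cds=(2, 55))
        walked = 0
        for i, (s, e) in enumerate(exons):
            lo, hi = max(s, 2), min(e, 55)
            assert reading_frame(t, f"t1-e{i + 1}") == walked % 3
            walked += hi - lo

    def test_minus_strand_walks_from_rightmost_exon(self):
        t = make_transcript([(0, 9), (17, 26)], strand=-1, cds=(0, 26))
        assert reading_frame(t, "t1-e2") == 0
        assert reading_frame(t, "t1-e1") == (26 - 17) % 3


class TestSpliceQC:
    def test_canonical_intron_clean(self, worked_ref):
        t = make_transcript([(0, 9), (17, 26)], cds=(0, 26))
        assert splice_qc(t, worked_ref, []).noncanonical_junctions == []

    def test_non_gt_donor_flagged_and_rescued_by_substitution(self):
        residues = "ATGGCCAAA" + "CTAAGTAG" + "GGGTTTTAACGCG"
        ref = ReferenceSequence("chr", residues)
        t = make_transcript([(0, 9), (17, 26)], cds=(0, 26))
        report = splice_qc(t, ref, [])
        assert report.noncanonical_junctions == [(0, "CT", "AG")]
        fix = SequenceAlteration("f", "substitution", "chr", 9, "G", 1)
        assert splice_qc(t, ref, [fix]).noncanonical_junctions == []

    def test_minus_strand_reads_reverse_complement(self):
        # plus-strand CT..AC intron is GT..AG on the minus strand
        residues = "ATGGCCAAA" + "CTAAGTAC" + "GGGTTTTAACGCG"
        ref = ReferenceSequence("chr", residues)
        t_plus = make_transcript([(0, 9), (17, 26)])
        t_minus = make_transcript([(0, 9), (17, 26)], strand=-1)
        assert len(splice_qc(t_plus, ref, []).noncanonical_junctions) == 1
        assert splice_qc(t_minus, ref, []).noncanonical_junctions == []

    def test_missing_start_and_partial_flags_carried(self, worked_ref):
        t = make_transcript([(0, 9), (17, 26)])
        t.cds = None
        assert splice_qc(t, worked_ref, []).missing_start
        t.cds, t.cds_partial = (0, 26), True
        assert splice_qc(t, worked_ref, []).partial_cds


class TestEdgeMatches:
    def test_identical_exon_lists_match_every_edge(self):
        sel = make_transcript([(0, 9), (17, 26)]).sorted_exons()
        cand = {"ev1": make_transcript([(0, 9), (17, 26)],
                                       tx_id="ev1").sorted_exons()}
        assert edge_matches(sel, cand) == [
            ("ev1", 0), ("ev1", 9), ("ev1", 17), ("ev1", 26)]

    def test_disjoint_coordinates_empty(self):
        sel = make_transcript([(0, 9)]).sorted_exons()
        cand = {"ev1": make_transcript([(40, 50)], tx_id="ev1").sorted_exons()}
        assert edge_matches(sel, cand) == []

    def test_partial_overlap_matches_shared_edge_only(self):
        sel = make_transcript([(5, 20)]).sorted_exons()
        cand = {"ev1": make_transcript([(5, 30)], tx_id="ev1").sorted_exons()}
        assert edge_matches(sel, cand) == [("ev1", 5)]
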