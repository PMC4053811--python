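"""Edit operations, their cascades, serialization and atomicity."""

import random

import pytest

from genecurate import (
    AnnotationEngine,
    EditRequest,
    ReferenceSequence,
    validate_all,
)

from conftest import (
    CLK,
    WORKED_EXONS,
    WORKED_MRNA,
    fixture_engine,
    gff_bytes,
    oracle_longest_orf,
    oracle_spliced,
    random_edit_request,
)


def make_engine(residues, policy="simple_overlap", window=10):
    ref = ReferenceSequence("chr", residues)
    return AnnotationEngine({"chr": ref}, policy=policy,
                            splice_window=window, clock=lambda: CLK)


def add_tx(eng, exons, strand=+1):
    res = eng.perform("create_transcript_from_evidence", seqid="chr",
                      strand=strand, exons=exons)
    assert res.ok, res.message
    return res.created[1]


class TestCreateFromEvidence:
    def test_copy_sets_cds_to_longest_orf(self, worked_engine):
        t = worked_engine.transcripts()[0]
        s, e, _ = worked_engine.spliced_cds_span(t)
        assert (s, e) == oracle_longest_orf(WORKED_MRNA)[:2]
        assert t.cds == (0, 26) and not t.cds_partial
        assert t.created == t.modified == CLK

    def test_identical_copies_become_isoforms_under_simple_overlap(
            self, worked_engine):
        worked_engine.perform("create_transcript_from_evidence", seqid="chr",
                              strand=+1, exons=WORKED_EXONS)
        assert len(worked_engine.genes) == 1
        (gene,) = worked_engine.genes.values()
        assert len(gene.transcripts) == 2

    def test_disjoint_predictions_found_separate_genes(self, worked_engine):
        worked_engine.perform("create_transcript_from_evidence", seqid="chr",
                              strand=+1, exons=[(27, 30)])
        assert len(worked_engine.genes) == 2

    def test_invalid_exons_rejected(self, worked_engine):
        res = worked_engine.perform("create_transcript_from_evidence",
                                    seqid="chr", strand=+1, exons=[(0, 99)])
        assert res.status == "invalid"


class TestDelete:
    def test_delete_one_of_two_exons_recomputes_cds(self, worked_engine):
        t = worked_engine.transcripts()[0]
        e2 = t.sorted_exons()[1]
        res = worked_engine.perform("delete_exon", tx_id=t.id, exon_id=e2.id)
        assert res.ok
        assert t.span() == (0, 9)
        s, e, _ = worked_engine.spliced_cds_span(t)
        assert (s, e) == oracle_longest_orf("ATGGCCAAA")[:2]

    def test_delete_last_exon_cascades_to_transcript_and_gene(self):
        eng = make_engine(WORKED_MRNA)
        tx = add_tx(eng, [(0, 18)])
        t = eng.transcripts()[0]
        res = eng.perform("delete_exon", tx_id=tx, exon_id=t.exons[0].id)
        assert res.ok and eng.genes == {}
        assert set(res.deleted) >= {t.exons and t.exons or tx} or tx in res.deleted

    def test_delete_stale_id_is_conflict_and_leaves_state(self, worked_engine):
        before = gff_bytes(worked_engine)
        res = worked_engine.perform("delete_transcript", tx_id="tx-99")
        assert res.status == "conflict"
        assert gff_bytes(worked_engine) == before

    def test_double_delete_conflicts(self, worked_engine):
        t = worked_engine.transcripts()[0]
        assert worked_engine.perform("delete_transcript", tx_id=t.id).ok
        res = worked_engine.perform("delete_transcript", tx_id=t.id)
        assert res.status == "conflict"


class TestDuplicate:
    def test_duplicate_then_delete_copy_restores_export(self, worked_engine):
        before = gff_bytes(worked_engine)
        res = worked_engine.perform("duplicate_transcript",
                                    tx_id=worked_engine.transcripts()[0].id)
        assert res.ok
        assert worked_engine.perform("delete_transcript",
                                     tx_id=res.created[0]).ok
        assert gff_bytes(worked_engine) == before

    def test_copy_shares_gene_and_coordinates(self, worked_engine):
        t = worked_engine.transcripts()[0]
        worked_engine.perform("duplicate_transcript", tx_id=t.id)
        (gene,) = worked_engine.genes.values()
        a, b = gene.transcripts
        assert [(e.start, e.end) for e in a.sorted_exons()] == \
            [(e.start, e.end) for e in b.sorted_exons()]
        assert a.id != b.id

    def test_copy_preserves_manual_translation_start(self, worked_engine):
        t = worked_engine.transcripts()[0]
        worked_engine.perform("set_translation_start", tx_id=t.id, position=0)
        res = worked_engine.perform("duplicate_transcript", tx_id=t.id)
        gene = next(iter(worked_engine.genes.values()))
        copy = gene.transcript_by_id(res.created[0])
        assert copy.manual_start == 0 and copy.cds == t.cds


class TestMergeTranscripts:
    def test_disjoint_union(self, worked_engine):
        t2 = add_tx(worked_engine, [(27, 30)])
        t1 = worked_engine.transcripts()[0].id
        res = worked_engine.perform("merge_transcripts", tx_id1=t1, tx_id2=t2)
        assert res.ok
        (gene,) = worked_engine.genes.values()
        (t,) = gene.transcripts
        assert [(e.start, e.end) for e in t.sorted_exons()] == [
            (0, 9), (17, 26), (27, 30)]

    def test_overlapping_exons_coalesce(self):
        eng = make_engine("A" * 40)
        t1 = add_tx(eng, [(0, 10)])
        t2 = add_tx(eng, [(5, 15)])
        assert eng.perform("merge_transcripts", tx_id1=t1, tx_id2=t2).ok
        t = eng.transcripts()[0]
        assert [(e.start, e.end) for e in t.sorted_exons()] == [(0, 15)]

    def test_two_single_transcript_genes_merge_to_one(self):
        eng = make_engine("A" * 60, policy="no_overlap")
        t1 = add_tx(eng, [(0, 10)])
        t2 = add_tx(eng, [(30, 40)])
        assert len(eng.genes) == 2
        assert eng.perform("merge_transcripts", tx_id1=t1, tx_id2=t2).ok
        assert len(eng.genes) == 1
        assert validate_all(eng.genes.values(), eng.refs) == []

    def test_strand_mismatch_is_invalid(self, worked_engine):
        t2 = add_tx(worked_engine, [(27, 30)], strand=-1)
        t1 = worked_engine.transcripts()[0].id
        before = gff_bytes(worked_engine)
        res = worked_engine.perform("merge_transcripts", tx_id1=t1, tx_id2=t2)
        assert res.status == "invalid"
        assert gff_bytes(worked_engine) == before


class TestSplitTranscript:
    def test_partition_into_two_single_exon_transcripts(self, worked_engine):
        t = worked_engine.transcripts()[0]
        res = worked_engine.perform("split_transcript", tx_id=t.id,
                                    after_exon_index=0)
        assert res.ok
        spans = sorted(x.span() for x in worked_engine.transcripts())
        assert spans == [(0, 9), (17, 26)]

    def test_split_then_merge_restores_export_bytes(self, worked_engine):
        before = gff_bytes(worked_engine)
        t = worked_engine.transcripts()[0]
        res = worked_engine.perform("split_transcript", tx_id=t.id,
                                    after_exon_index=0)
        assert worked_engine.perform("merge_transcripts", tx_id1=t.id,
                                     tx_id2=res.created[0]).ok
        assert gff_bytes(worked_engine) == before

    def test_split_under_no_overlap_gives_two_genes(self):
        eng = make_engine(WORKED_MRNA + "GTAAGTAG" + WORKED_MRNA,
                          policy="no_overlap")
        tx = add_tx(eng, [(0, 18), (26, 44)])
        assert eng.perform("split_transcript", tx_id=tx,
                           after_exon_index=0).ok
        assert len(eng.genes) == 2

    def test_single_exon_split_is_invalid(self):
        eng = make_engine("A" * 30)
        tx = add_tx(eng, [(0, 10)])
        assert eng.perform("split_transcript", tx_id=tx,
                           after_exon_index=0).status == "invalid"


class TestSetExonBoundary:
    def test_extension_changes_mrna_and_orf(self, worked_engine):
        t = worked_engine.transcripts()[0]
        e2 = t.sorted_exons()[1]
        res = worked_engine.perform("set_exon_boundary", tx_id=t.id,
                                    exon_id=e2.id, new_start=15, new_end=26)
        assert res.ok
        mrna = worked_engine.mrna(t)
        assert mrna == oracle_spliced(worked_engine.refs["chr"].residues, [],
                                      [(0, 9), (15, 26)], +1)
        s, e, _ = worked_engine.spliced_cds_span(t)
        assert (s, e) == oracle_longest_orf(mrna)[:2]

    def test_noop_boundary_still_touches_modified(self, worked_engine):
        t = worked_engine.transcripts()[0]
        t.modified = "old"
        e1 = t.sorted_exons()[0]
        res = worked_engine.perform("set_exon_boundary", tx_id=t.id,
                                    exon_id=e1.id, new_start=0, new_end=9)
        assert res.ok and t.modified == CLK

    def test_overlap_with_sibling_is_invalid(self, worked_engine):
        t = worked_engine.transcripts()[0]
        e1 = t.sorted_exons()[0]
        before = gff_bytes(worked_engine)
        res = worked_engine.perform("set_exon_boundary", tx_id=t.id,
                                    exon_id=e1.id, new_start=0, new_end=20)
        assert res.status == "invalid"
        assert gff_bytes(worked_engine) == before


class TestMergeSplitExons:
    def test_merge_absorbs_intron_into_mrna(self, worked_engine):
        t = worked_engine.transcripts()[0]
        e1, e2 = t.sorted_exons()
        res = worked_engine.perform("merge_exons", tx_id=t.id,
                                    exon_id1=e1.id, exon_id2=e2.id)
        assert res.ok
        assert [(x.start, x.end) for x in t.sorted_exons()] == [(0, 26)]
        assert worked_engine.mrna(t) == \
            worked_engine.refs["chr"].residues[0:26]

    def test_merge_non_adjacent_is_invalid(self):
        eng = make_engine("A" * 60)
        tx = add_tx(eng, [(0, 8), (15, 25), (35, 45)])
        t = eng.transcripts()[0]
        exons = t.sorted_exons()
        res = eng.perform("merge_exons", tx_id=tx, exon_id1=exons[0].id,
                          exon_id2=exons[2].id)
        assert res.status == "invalid"

    def test_split_snaps_to_canonical_dinucleotides(self):
        # GT at 12 and AG ending at 20 sit inside the snap window
        residues = "ATGGCCAAACCCGTCCCCAGCCCTTTAAACCC"
        eng = make_engine(residues)
        tx = add_tx(eng, [(0, 30)])
        t = eng.transcripts()[0]
        res = eng.perform("split_exon", tx_id=tx, exon_id=t.exons[0].id,
                          split_point=14)
        assert res.ok
        (gap,) = [(a.end, b.start) for a, b in
                  zip(t.sorted_exons(), t.sorted_exons()[1:])]
        intron = residues[gap[0]:gap[1]]
        assert intron.startswith("GT") and intron.endswith("AG")
        assert eng.qc(t).noncanonical_junctions == []

    def test_split_without_canonical_sites_falls_back_flagged(self):
        eng = make_engine("A" * 40, window=3)
        tx = add_tx(eng, [(0, 30)])
        t = eng.transcripts()[0]
        res = eng.perform("split_exon", tx_id=tx, exon_id=t.exons[0].id,
                          split_point=15)
        assert res.ok
        assert [(x.start, x.end) for x in t.sorted_exons()] == [
            (0, 15), (17, 30)]
        assert len(eng.qc(t).noncanonical_junctions) == 1

    def test_fallback_split_then_merge_restores_export(self):
        eng = make_engine("A" * 40, window=0)
        tx = add_tx(eng, [(0, 30)])
        before = gff_bytes(eng)
        t = eng.transcripts()[0]
        res = eng.perform("split_exon", tx_id=tx, exon_id=t.exons[0].id,
                          split_point=15)
        assert res.ok
        left, right = t.sorted_exons()
        assert eng.perform("merge_exons", tx_id=tx, exon_id1=left.id,
                           exon_id2=right.id).ok
        assert gff_bytes(eng) == before

    def test_split_at_exon_edge_is_invalid(self):
        eng = make_engine("A" * 40)
        tx = add_tx(eng, [(0, 30)])
        t = eng.transcripts()[0]
        res = eng.perform("split_exon", tx_id=tx, exon_id=t.exons[0].id,
                          split_point=0)
        assert res.status == "invalid"


class TestTranslationStart:
    def test_set_at_annotated_atg_matches_automatic(self, worked_engine):
        t = worked_engine.transcripts()[0]
        auto = (t.cds, t.cds_partial)
        res = worked_engine.perform("set_translation_start", tx_id=t.id,
                                    position=0)
        assert res.ok and (t.cds, t.cds_partial) == auto

    def test_downstream_start_removes_peptide_prefix(self):
        # two in-frame ATGs: full peptide MKM..., pinned start gives M...
        eng = make_engine("ATGAAAATGCCCTTTTAA")
        tx = add_tx(eng, [(0, 18)])
        t = eng.transcripts()[0]
        from genecurate.io_formats import spliced_cds_sequence
        from genecurate import translate
        full = translate(spliced_cds_sequence(t, eng.refs["chr"],
                                              eng.alterations))
        assert eng.perform("set_translation_start", tx_id=tx, position=6).ok
        pinned = translate(spliced_cds_sequence(t, eng.refs["chr"],
                                                eng.alterations))
        assert full == "MKMPF" and pinned == "MPF"
        assert full.endswith(pinned)

    def test_intron_position_is_invalid(self, worked_engine):
        t = worked_engine.transcripts()[0]
        res = worked_engine.perform("set_translation_start", tx_id=t.id,
                                    position=12)
        assert res.status == "invalid"

    def test_manual_start_pinned_across_structural_edits(self):
        eng = make_engine("ATGAAAATGCCCTTTTAAAAAA")
        tx = add_tx(eng, [(0, 18)])
        t = eng.transcripts()[0]
        assert eng.perform("set_translation_start", tx_id=tx, position=6).ok
        assert eng.perform("set_exon_boundary", tx_id=tx,
                           exon_id=t.exons[0].id, new_start=0,
                           new_end=22).ok
        assert t.manual_start == 6 and t.cds[0] == 6


class TestFlipStrand:
    def test_involution_up_to_modified_timestamp(self, worked_engine):
        t = worked_engine.transcripts()[0]
        before = t.to_dict()
        assert worked_engine.perform("flip_strand", tx_id=t.id).ok
        assert worked_engine.perform("flip_strand", tx_id=t.id).ok
        # the transcript itself is fully restored (fixed clock, so even
        # the modified timestamp matches); only the auto-assigned gene
        # container gets a fresh id
        assert t.to_dict() == before

    def test_flip_to_strand_without_atg_clears_cds(self):
        eng = make_engine("ATGAAAAAATAA")
        tx = add_tx(eng, [(0, 12)])
        t = eng.transcripts()[0]
        assert t.cds is not None
        assert eng.perform("flip_strand", tx_id=tx).ok
        assert t.cds is None
        assert eng.qc(t).missing_start

    def test_flipped_isoform_moves_to_its_own_gene(self, worked_engine):
        worked_engine.perform("duplicate_transcript",
                              tx_id=worked_engine.transcripts()[0].id)
        assert len(worked_engine.genes) == 1
        t2 = sorted(worked_engine.transcripts(), key=lambda t: t.id)[-1]
        assert worked_engine.perform("flip_strand", tx_id=t2.id).ok
        assert len(worked_engine.genes) == 2
        assert validate_all(worked_engine.genes.values(),
                            worked_engine.refs) == []


class TestApplySerialization:
    def test_unknown_op_is_protocol_error(self, worked_engine):
        with pytest.raises(Exception, match="unknown operation"):
            worked_engine.apply(EditRequest("frobnicate", {}))

    def test_second_request_overwrites_first(self, worked_engine):
        t = worked_engine.transcripts()[0]
        e1 = t.sorted_exons()[0]
        r1 = EditRequest("set_exon_boundary",
                         {"tx_id": t.id, "exon_id": e1.id,
                          "new_start": 1, "new_end": 9}, user="alice")
        r2 = EditRequest("set_exon_boundary",
                         {"tx_id": t.id, "exon_id": e1.id,
                          "new_start": 2, "new_end": 9}, user="bob")
        assert worked_engine.apply(r1).ok and worked_engine.apply(r2).ok
        assert (e1.start, e1.end) == (2, 9)

    def test_delete_then_boundary_change_conflicts_and_preserves(
            self, worked_engine):
        t = worked_engine.transcripts()[0]
        e2 = t.sorted_exons()[1]
        assert worked_engine.apply(EditRequest(
            "delete_exon", {"tx_id": t.id, "exon_id": e2.id},
            user="alice")).ok
        before = gff_bytes(worked_engine)
        res = worked_engine.apply(EditRequest(
            "set_exon_boundary",
            {"tx_id": t.id, "exon_id": e2.id, "new_start": 17,
             "new_end": 20}, user="bob"))
        assert res.status == "conflict"
        assert gff_bytes(worked_engine) == before

    def test_one_history_entry_per_cascading_request(self):
        eng = make_engine(WORKED_MRNA)
        tx = add_tx(eng, [(0, 18)])
        t = eng.transcripts()[0]
        n = eng.history.latest
        # deleting the only exon cascades through transcript and gene
        assert eng.perform("delete_exon", tx_id=tx,
                           exon_id=t.exons[0].id).ok
        assert eng.history.latest == n + 1


class TestRandomScriptClosure:
    def test_invariants_hold_across_random_scripts(self):
        rng = random.Random(99)
        for script in range(12):
            eng = fixture_engine(seed=script, scaffold_count=1,
                                 genes_per_scaffold=2)
            for _ in range(25):
                before = gff_bytes(eng)
                res = eng.apply(random_edit_request(rng, eng))
                if res.ok:
                    assert validate_all(eng.genes.values(), eng.refs) == []
                    for t in eng.transcripts():
                        assert t.exons, "orphan transcript"
                    for g in eng.genes.values():
                        assert g.transcripts, "orphan gene"
                else:
                    assert gff_bytes(eng) == before

    def test_cds_freshness_after_random_scripts(self):
        rng = random.Random(5)
        eng = fixture_engine(seed=2, scaffold_count=1, genes_per_scaffold=2)
        for _ in range(40):
            eng.apply(random_edit_request(rng, eng))
        for t in eng.transcripts():
            if t.manual_start is not None:
                continue
            stored = (t.cds, t.cds_partial)
            orf = oracle_longest_orf(eng.mrna(t))
            if orf is None:
                assert stored == (None, False)
            else:
                eng.recompute_cds(t)
                assert (t.cds, t.cds_partial) == stored
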