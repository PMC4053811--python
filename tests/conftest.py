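"""Shared fixtures and independent oracles.

The oracles deliberately use different algorithms from the package:
virtual sequences are rebuilt base-by-base with provenance tags, and ORFs
are found by brute-force enumeration of every ATG..stop pair.
"""

from __future__ import annotations

import random

import pytest

from genecurate import (
    AnnotationEngine,
    Exon,
    Gene,
    ReferenceSequence,
    SequenceAlteration,
    Transcript,
    reverse_complement,
)

CLK = "2013-06-01T00:00:00Z"

#: The worked two-exon example: exons [0,9)+[17,26), intron GT..AG,
#: spliced mRNA "ATGGCCAAAGGGTTTTAA", peptide "MAKGF".
WORKED_REF = "ATGGCCAAAGTAAGTAGGGGTTTTAACGCG"
WORKED_EXONS = [(0, 9), (17, 26)]
WORKED_MRNA = "ATGGCCAAAGGGTTTTAA"
WORKED_PEPTIDE = "MAKGF"

STOPS = ("TAA", "TAG", "TGA")


@pytest.fixture
def worked_ref() -> ReferenceSequence:
    return ReferenceSequence("chr", WORKED_REF)


def make_transcript(exons, strand=+1, seqid="chr", tx_id="t1", cds=None,
                    **kw) -> Transcript:
    return Transcript(
        id=tx_id, seqid=seqid, strand=strand,
        exons=[Exon(f"{tx_id}-e{i + 1}", s, e)
               for i, (s, e) in enumerate(sorted(exons))],
        cds=cds, created=CLK, modified=CLK, **kw)


def make_gene(exons, strand=+1, seqid="chr", gene_id="g1", tx_id="t1",
              cds=None) -> Gene:
    t = make_transcript(exons, strand, seqid, tx_id, cds)
    return Gene(id=gene_id, seqid=seqid, strand=strand, transcripts=[t])


@pytest.fixture
def worked_engine(worked_ref) -> AnnotationEngine:
    eng = AnnotationEngine({"chr": worked_ref}, clock=lambda: CLK)
    res = eng.perform("create_transcript_from_evidence", seqid="chr",
                      strand=+1, exons=WORKED_EXONS)
    assert res.ok
    return eng


# ---------------------------------------------------------------------------
# virtual-sequence oracle: rebuild base-by-base with provenance tags
# ---------------------------------------------------------------------------

def oracle_tagged_virtual(ref: str, alts) -> list[tuple[str, int]]:
    """(char, anchor) pairs; inserted bases are tagged with their anchor."""
    by_pos_ins = {}
    deleted = set()
    substituted = {}
    for a in alts:
        if a.kind == "insertion":
            by_pos_ins[a.position] = a.residues
        elif a.kind == "deletion":
            deleted.update(range(a.position, a.position + a.length))
        else:
            for k in range(a.length):
                substituted[a.position + k] = a.residues[k]
    out = []
    for pos in range(len(ref) + 1):
        if pos in by_pos_ins:
            out.extend((c, pos) for c in by_pos_ins[pos])
        if pos < len(ref) and pos not in deleted:
            out.append((substituted.get(pos, ref[pos]), pos))
    return out


def oracle_virtual(ref: str, alts) -> str:
    return "".join(c for c, _ in oracle_tagged_virtual(ref, alts))


def oracle_spliced(ref: str, alts, exons, strand) -> str:
    tagged = oracle_tagged_virtual(ref, alts)
    mrna = "".join(c for s, e in sorted(exons)
                   for c, tag in tagged if s <= tag < e)
    return reverse_complement(mrna) if strand == -1 else mrna


def random_alterations(rng: random.Random, reflen: int, n: int, seqid="chr",
                       prefix="ra") -> list[SequenceAlteration]:
    """Up to n random pairwise non-overlapping alterations."""
    taken: set[int] = set()
    out = []
    for i in range(n):
        kind = rng.choice(("insertion", "deletion", "substitution"))
        if kind == "insertion":
            pos = rng.randrange(0, reflen + 1)
            if pos in taken or (pos - 1) in taken or pos + 1 > reflen + 1:
                continue
            out.append(SequenceAlteration(
                f"{prefix}-{i}", kind, seqid, pos,
                "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4))),
                0))
            taken.add(pos)
        else:
            length = rng.randint(1, 4)
            pos = rng.randrange(0, max(1, reflen - length))
            span = set(range(pos - 1, pos + length + 1))
            if span & taken:
                continue
            if kind == "deletion":
                out.append(SequenceAlteration(
                    f"{prefix}-{i}", kind, seqid, pos, "", length))
            else:
                out.append(SequenceAlteration(
                    f"{prefix}-{i}", kind, seqid, pos,
                    "".join(rng.choice("ACGT") for _ in range(length)),
                    length))
            taken.update(span)
    return out


def random_exons(rng: random.Random, reflen: int) -> list[tuple[int, int]]:
    n = rng.randint(1, 4)
    cuts = sorted(rng.sample(range(0, reflen), min(2 * n, reflen // 3)))
    exons = []
    for s, e in zip(cuts[::2], cuts[1::2]):
        if e - s >= 1 and (not exons or s > exons[-1][1]):
            exons.append((s, e))
    return exons or [(0, max(1, reflen // 2))]


# ---------------------------------------------------------------------------
# longest-ORF oracle: brute-force enumeration of every ATG..stop pair
# ---------------------------------------------------------------------------

def oracle_longest_orf(mrna: str):
    """(start, end, has_stop) of the longest ATG-anchored ORF, 5'-most on
    ties, or None; stop-terminated spans include the stop codon."""
    candidates = []
    for s in range(len(mrna) - 2):
        if mrna[s:s + 3] != "ATG":
            continue
        end, has_stop = len(mrna), False
        for q in range(s + 3, len(mrna) - 2, 3):
            if mrna[q:q + 3] in STOPS:
                end, has_stop = q + 3, True
                break
        candidates.append((end - s, -s, s, end, has_stop))
    if not candidates:
        return None
    _, _, s, end, has_stop = max(candidates)
    return (s, end, has_stop)


def random_dna(rng: random.Random, n: int, alphabet="ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


# ---------------------------------------------------------------------------
# random edit scripts over the full operation menu
# ---------------------------------------------------------------------------

from genecurate import EditRequest  # noqa: E402
from genecurate.io_formats import write_gff3  # noqa: E402


def gff_bytes(eng: AnnotationEngine) -> str:
    return write_gff3(eng.genes.values(), eng.alterations, eng.refs)


def fixture_engine(seed: int, **spec_kw) -> AnnotationEngine:
    """Engine preloaded with a generated truth annotation set."""
    from genecurate import FixtureSpec, generate

    fx = generate(FixtureSpec(seed=seed, **spec_kw))
    eng = AnnotationEngine(fx.refs, clock=lambda: CLK)
    for g in fx.truth:
        eng.genes[g.id] = g
    eng.rebuild_initial()
    return eng


def random_edit_request(rng: random.Random, eng: AnnotationEngine,
                        user="tester") -> EditRequest:
    """One plausible (sometimes deliberately stale/invalid) request drawn
    from the whole operation menu."""
    seqids = sorted(eng.refs)
    txs = eng.transcripts()

    def tid() -> str:
        if txs and rng.random() > 0.1:
            return rng.choice(txs).id
        return "tx-bogus"

    def tx_exon() -> tuple[str, str]:
        if txs and rng.random() > 0.1:
            t = rng.choice(txs)
            return t.id, rng.choice(t.exons).id
        return "tx-bogus", "exon-bogus"

    op = rng.choice((
        "create_transcript_from_evidence", "delete_transcript", "delete_exon",
        "duplicate_transcript", "merge_transcripts", "split_transcript",
        "set_exon_boundary", "merge_exons", "split_exon",
        "set_translation_start", "clear_translation_start", "flip_strand",
        "add_alteration", "remove_alteration"))
    seqid = rng.choice(seqids)
    reflen = eng.refs[seqid].length
    args: dict
    if op == "create_transcript_from_evidence":
        args = {"seqid": seqid, "strand": rng.choice((1, -1)),
                "exons": random_exons(rng, reflen)}
    elif op in ("delete_transcript", "duplicate_transcript", "flip_strand",
                "clear_translation_start"):
        args = {"tx_id": tid()}
    elif op == "delete_exon":
        t_id, e_id = tx_exon()
        args = {"tx_id": t_id, "exon_id": e_id}
    elif op == "merge_transcripts":
        args = {"tx_id1": tid(), "tx_id2": tid()}
    elif op == "split_transcript":
        args = {"tx_id": tid(), "after_exon_index": rng.randint(0, 3)}
    elif op == "set_exon_boundary":
        t_id, e_id = tx_exon()
        lo = rng.randrange(0, reflen - 1)
        args = {"tx_id": t_id, "exon_id": e_id, "new_start": lo,
                "new_end": min(reflen, lo + rng.randint(1, 60))}
    elif op == "merge_exons":
        t_id, e1 = tx_exon()
        e2 = e1
        for t in txs:
            if t.id == t_id and len(t.exons) > 1:
                exons = t.sorted_exons()
                i = rng.randrange(len(exons) - 1)
                e1, e2 = exons[i].id, exons[i + rng.choice((1, 1, 2))
                                             if i + 2 < len(exons)
                                             else i + 1].id
                break
        args = {"tx_id": t_id, "exon_id1": e1, "exon_id2": e2}
    elif op == "split_exon":
        t_id, e_id = tx_exon()
        point = rng.randrange(0, reflen)
        for t in txs:
            if t.id == t_id:
                for e in t.exons:
                    if e.id == e_id and e.end - e.start > 6:
                        point = rng.randrange(e.start + 1, e.end - 3)
        args = {"tx_id": t_id, "exon_id": e_id, "split_point": point}
    elif op == "set_translation_start":
        t_id = tid()
        pos = rng.randrange(0, reflen)
        for t in txs:
            if t.id == t_id and rng.random() > 0.2:
                s, e = t.span()
                pos = rng.randrange(s, e)
        args = {"tx_id": t_id, "position": pos}
    elif op == "add_alteration":
        kind = rng.choice(("insertion", "deletion", "substitution"))
        pos = rng.randrange(0, reflen)
        if kind == "insertion":
            args = {"kind": kind, "seqid": seqid, "position": pos,
                    "residues": random_dna(rng, rng.randint(1, 3))}
        elif kind == "deletion":
            args = {"kind": kind, "seqid": seqid, "position": pos,
                    "length": rng.randint(1, 3)}
        else:
            n = rng.randint(1, 3)
            args = {"kind": kind, "seqid": seqid, "position": pos,
                    "residues": random_dna(rng, n), "length": n}
    else:  # remove_alteration
        ids = [a.id for a in eng.alterations]
        args = {"alt_id": rng.choice(ids) if ids and rng.random() > 0.2
                else "alt-bogus"}
    return EditRequest(op, args, user=user, timestamp=CLK)
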