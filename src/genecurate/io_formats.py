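"""Readers and writers for the standard interchange formats.

GFF3 dialect
------------
Output starts with the ``##gff-version 3`` pragma and one
``##sequence-region`` per scaffold, then features ordered by
``(scaffold, start, id)`` — two exports of the same state are
byte-identical.  The hierarchy is ``gene → mRNA → exon/CDS`` via
``Parent``; CDS phase is computed from the reading frame, never copied.
On input both ``mRNA`` and ``transcript`` type tokens are accepted; on
output only ``mRNA`` is written.  Sequence alterations travel as
top-level ``insertion`` / ``deletion`` / ``substitution`` rows with a
``residues`` attribute; a zero-length insertion uses ``start == end``
with the insertion site immediately right of that base, per the GFF3
zero-length-feature convention.

Ownership and dating use the attributes ``owner``, ``date_creation`` and
``date_last_modified``; a CDS without an in-frame stop is exported with
``partial=true`` and a pinned translation start as ``manual_start``.

Internal coordinates are 0-based half-open; GFF3 columns 4/5 are 1-based
closed; BED is already 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Optional, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alterations import (
    AlterationSet,
    SequenceAlteration,
    extract_slice,
    extract_spliced,
    mrna_to_ref,
)
from .model import (
    Exon,
    Gene,
    GenecurateError,
    ReferenceSequence,
    Transcript,
    reverse_complement,
)
from .orf import translate

logger = logging.getLogger("genecurate")

SOURCE = "genecurate"
ALTERATION_TYPES = ("insertion", "deletion", "substitution")
FASTA_KINDS = ("genomic", "cdna", "cds", "peptide")


class FastaError(GenecurateError):
    pass


class Gff3Error(GenecurateError):
    """Per-record problems, collected and reported together."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(problems))


class BedError(GenecurateError):
    pass


@dataclass
class EvidenceFeature:
    """A read-only, transcript-shaped prediction or alignment feature."""

    id: str
    ftype: str
    seqid: str
    strand: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))


@dataclass
class Gff3Content:
    """Everything a GFF3 file can contribute to a session."""

    genes: list[Gene] = field(default_factory=list)
    alterations: list[SequenceAlteration] = field(default_factory=list)
    evidence: list[EvidenceFeature] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, ReferenceSequence]:
    """Load reference scaffolds; residues are uppercased and must be ACGTN."""
    refs: dict[str, ReferenceSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in refs:
            raise FastaError(f"duplicate record id {rec.id!r}")
        residues = str(rec.seq).upper()
        m = re.search(r"[^ACGTN]", residues)
        if m:
            raise FastaError(
                f"record {rec.id!r}: illegal residue {m.group()!r} "
                f"at offset {m.start()}")
        refs[rec.id] = ReferenceSequence(rec.id, residues)
    if not refs:
        raise FastaError(f"no FASTA records in {path}")
    return refs


def write_fasta(refs: dict[str, ReferenceSequence], path) -> None:
    records = [SeqRecord(Seq(refs[k].residues), id=k, description="")
               for k in sorted(refs)]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 writing
# ---------------------------------------------------------------------------

_ESCAPES = {"%": "%25", ";": "%3B", "=": "%3D", "&": "%26", ",": "%2C",
            "\t": "%09", "\n": "%0A", "\r": "%0D"}


def _esc(value: str) -> str:
    return "".join(_ESCAPES.get(c, c) for c in value)


_UNESC_RE = re.compile(r"%([0-9A-Fa-f]{2})")


def _unesc(value: str) -> str:
    return _UNESC_RE.sub(lambda m: chr(int(m.group(1), 16)), value)


def _attrs(pairs: list[tuple[str, str]]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs if v != "")


def _strand_char(strand: int) -> str:
    return "+" if strand == +1 else "-"


def _row(seqid: str, ftype: str, start0: int, end0: int, strand: int,
         phase: str, attrs: str) -> str:
    return "\t".join([seqid, SOURCE, ftype, str(start0 + 1), str(end0),
                      ".", _strand_char(strand), phase, attrs])


def cds_segments(t: Transcript) -> list[tuple[int, int]]:
    """Reference-coordinate CDS pieces: the CDS interval clipped to exons."""
    if t.cds is None:
        return []
    cs, ce = t.cds
    segs = []
    for e in t.sorted_exons():
        lo, hi = max(e.start, cs), min(e.end, ce)
        if lo < hi:
            segs.append((lo, hi))
    return segs


def cds_phases(t: Transcript) -> dict[tuple[int, int], int]:
    """GFF3 phase per CDS segment via a strand-aware codon walk."""
    segs = cds_segments(t)
    ordered = segs if t.strand == +1 else segs[::-1]
    phases: dict[tuple[int, int], int] = {}
    coding_before = 0
    for seg in ordered:
        phases[seg] = (3 - coding_before % 3) % 3
        coding_before += seg[1] - seg[0]
    return phases


def write_gff3(genes: Iterable[Gene],
               alterations: Iterable[SequenceAlteration],
               refs: dict[str, ReferenceSequence],
               path=None) -> str:
    """Serialize the annotation set; returns the text (and writes *path*)."""
    out = StringIO()
    out.write("##gff-version 3\n")
    for seqid in sorted(refs):
        out.write(f"##sequence-region {seqid} 1 {refs[seqid].length}\n")

    toplevel: list[tuple[tuple, object]] = []
    for g in genes:
        toplevel.append(((g.seqid, g.span()[0], g.id), g))
    for a in alterations:
        toplevel.append(((a.seqid, a.position, a.id), a))

    for _, feat in sorted(toplevel, key=lambda kv: kv[0]):
        if isinstance(feat, SequenceAlteration):
            _write_alteration(out, feat)
        else:
            _write_gene(out, feat)
    text = out.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _write_alteration(out: TextIO, a: SequenceAlteration) -> None:
    if a.kind == "insertion":
        start0, end0 = a.position - 1, a.position  # GFF3 zero-length site
    else:
        start0, end0 = a.position, a.position + a.length
    pairs = [("ID", _esc(a.id))]
    if a.residues:
        pairs.append(("residues", _esc(a.residues)))
    out.write(_row(a.seqid, a.kind, start0, end0, +1, ".", _attrs(pairs)) + "\n")


def _write_gene(out: TextIO, g: Gene) -> None:
    gs, ge = g.span()
    pairs = [("ID", _esc(g.id))]
    if g.name:
        pairs.append(("Name", _esc(g.name)))
    if g.comments:
        pairs.append(("comments", ",".join(_esc(c) for c in g.comments)))
    if g.dbxrefs:
        pairs.append(("Dbxref", ",".join(_esc(d) for d in g.dbxrefs)))
    out.write(_row(g.seqid, "gene", gs, ge, g.strand, ".", _attrs(pairs)) + "\n")
    for t in sorted(g.transcripts, key=lambda t: (t.span()[0], t.id)):
        _write_transcript(out, g, t)


def _write_transcript(out: TextIO, g: Gene, t: Transcript) -> None:
    ts, te = t.span()
    pairs = [("ID", _esc(t.id)), ("Parent", _esc(g.id)),
             ("owner", _esc(t.owner)),
             ("date_creation", _esc(t.created)),
             ("date_last_modified", _esc(t.modified))]
    if t.cds_partial:
        pairs.append(("partial", "true"))
    if t.manual_start is not None:
        pairs.append(("manual_start", str(t.manual_start)))
    if t.comments:
        pairs.append(("comments", ",".join(_esc(c) for c in t.comments)))
    if t.dbxrefs:
        pairs.append(("Dbxref", ",".join(_esc(d) for d in t.dbxrefs)))
    out.write(_row(t.seqid, "mRNA", ts, te, t.strand, ".", _attrs(pairs)) + "\n")
    for e in t.sorted_exons():
        attrs = _attrs([("ID", _esc(e.id)), ("Parent", _esc(t.id))])
        out.write(_row(t.seqid, "exon", e.start, e.end, t.strand, ".", attrs)
                  + "\n")
    phases = cds_phases(t)
    for seg in cds_segments(t):
        attrs = _attrs([("ID", _esc(t.id) + ":cds"), ("Parent", _esc(t.id))])
        out.write(_row(t.seqid, "CDS", seg[0], seg[1], t.strand,
                       str(phases[seg]), attrs) + "\n")


def write_evidence_gff3(evidence: Iterable[EvidenceFeature],
                        refs: dict[str, ReferenceSequence],
                        path=None) -> str:
    """Evidence features as parentless mRNA rows with exon children."""
    out = StringIO()
    out.write("##gff-version 3\n")
    for seqid in sorted(refs):
        out.write(f"##sequence-region {seqid} 1 {refs[seqid].length}\n")
    for ev in sorted(evidence, key=lambda e: (e.seqid, e.span()[0], e.id)):
        s, e = ev.span()
        out.write(_row(ev.seqid, "mRNA", s, e, ev.strand, ".",
                       _attrs([("ID", _esc(ev.id))])) + "\n")
        for i, (xs, xe) in enumerate(sorted(ev.exons), start=1):
            attrs = _attrs([("ID", _esc(f"{ev.id}-e{i}")),
                            ("Parent", _esc(ev.id))])
            out.write(_row(ev.seqid, "exon", xs, xe, ev.strand, ".", attrs)
                      + "\n")
    text = out.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# GFF3 reading
# ---------------------------------------------------------------------------

@dataclass
class _Raw:
    line_no: int
    seqid: str
    ftype: str
    start0: int
    end0: int
    strand: int
    attrs: dict[str, str]


def _parse_attrs(col: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in col.split(";"):
        if not part:
            continue
        key, _, val = part.partition("=")
        out[key] = val
    return out


def read_gff3(path, refs: dict[str, ReferenceSequence]) -> Gff3Content:
    """Parse annotations, alterations and evidence from one GFF3 file.

    Per-record problems (dangling Parent, coordinates beyond the
    scaffold, CDS outside exons, malformed columns) are collected and
    raised together as one :class:`Gff3Error`.
    """
    problems: list[str] = []
    raws: list[_Raw] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                problems.append(f"line {i}: expected 9 columns, got {len(cols)}")
                continue
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            try:
                start1, end1 = int(start), int(end)
            except ValueError:
                problems.append(f"line {i}: non-integer coordinates")
                continue
            if ftype != "insertion" and start1 > end1:
                problems.append(f"line {i}: start {start1} > end {end1}")
                continue
            if strand not in "+-.":
                problems.append(f"line {i}: bad strand {strand!r}")
                continue
            if seqid not in refs:
                problems.append(f"line {i}: unknown scaffold {seqid!r}")
                continue
            reflen = refs[seqid].length
            if end1 > reflen or start1 < 0:
                problems.append(
                    f"line {i}: coordinates {start1}..{end1} beyond "
                    f"scaffold {seqid} of length {reflen}")
                continue
            raws.append(_Raw(i, seqid, ftype, start1 - 1, end1,
                             -1 if strand == "-" else +1,
                             _parse_attrs(attrs)))

    content = _assemble(raws, problems)
    if problems:
        raise Gff3Error(problems)
    return content


def _assemble(raws: list[_Raw], problems: list[str]) -> Gff3Content:
    content = Gff3Content()
    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    tx_parent: dict[str, str] = {}
    evidence: dict[str, EvidenceFeature] = {}
    cds_rows: dict[str, list[tuple[int, int]]] = {}
    anon = 0

    for r in raws:
        rid = _unesc(r.attrs.get("ID", ""))
        if r.ftype == "gene":
            g = Gene(id=rid or f"gene-anon-{(anon := anon + 1)}",
                     seqid=r.seqid, strand=r.strand,
                     name=_unesc(r.attrs.get("Name", "")),
                     comments=_split_list(r.attrs.get("comments", "")),
                     dbxrefs=_split_list(r.attrs.get("Dbxref", "")))
            genes[g.id] = g
        elif r.ftype in ("mRNA", "transcript"):
            t = Transcript(
                id=rid or f"tx-anon-{(anon := anon + 1)}",
                seqid=r.seqid, strand=r.strand,
                owner=_unesc(r.attrs.get("owner", "anonymous")),
                created=_unesc(r.attrs.get("date_creation", "")),
                modified=_unesc(r.attrs.get("date_last_modified", "")),
                cds_partial=r.attrs.get("partial", "") == "true",
                manual_start=(int(r.attrs["manual_start"])
                              if "manual_start" in r.attrs else None),
                comments=_split_list(r.attrs.get("comments", "")),
                dbxrefs=_split_list(r.attrs.get("Dbxref", "")))
            transcripts[t.id] = t
            parent = _unesc(r.attrs.get("Parent", ""))
            if parent:
                tx_parent[t.id] = parent
        elif r.ftype in ALTERATION_TYPES:
            alt = _read_alteration(r, problems)
            if alt is not None:
                content.alterations.append(alt)
        elif r.ftype in ("exon", "CDS"):
            parent = _unesc(r.attrs.get("Parent", ""))
            if not parent:
                problems.append(f"line {r.line_no}: {r.ftype} without Parent")
                continue
            if parent in transcripts:
                if r.ftype == "exon":
                    transcripts[parent].exons.append(
                        Exon(rid or f"exon-anon-{(anon := anon + 1)}",
                             r.start0, r.end0))
                else:
                    cds_rows.setdefault(parent, []).append((r.start0, r.end0))
            elif parent in evidence:
                evidence[parent].exons.append((r.start0, r.end0))
            else:
                problems.append(
                    f"line {r.line_no}: dangling Parent {parent!r}")
        else:
            # unknown types are preserved as opaque evidence features
            ev = EvidenceFeature(
                id=rid or f"ev-anon-{(anon := anon + 1)}", ftype=r.ftype,
                seqid=r.seqid, strand=r.strand, exons=[(r.start0, r.end0)])
            evidence[ev.id] = ev

    for tx_id, rows in cds_rows.items():
        t = transcripts[tx_id]
        t.cds = (min(s for s, _ in rows), max(e for _, e in rows))

    for tx_id, t in transcripts.items():
        parent = tx_parent.get(tx_id)
        if parent is None:
            # parentless transcript rows are prediction/alignment evidence
            evidence[tx_id] = EvidenceFeature(
                id=tx_id, ftype="mRNA", seqid=t.seqid, strand=t.strand,
                exons=[(e.start, e.end) for e in t.sorted_exons()])
            continue
        if parent not in genes:
            problems.append(f"transcript {tx_id}: dangling Parent {parent!r}")
            continue
        if t.cds is not None and (not t.exons or not _cds_inside_exons(t)):
            problems.append(f"transcript {tx_id}: CDS {t.cds} outside exons")
        genes[parent].transcripts.append(t)

    content.genes = [g for g in genes.values() if g.transcripts]
    for g in genes.values():
        if not g.transcripts:
            problems.append(f"gene {g.id}: no transcripts in file")
    content.evidence = sorted(evidence.values(), key=lambda e: e.id)
    return content


def _cds_inside_exons(t: Transcript) -> bool:
    cs, ce = t.cds
    exons = t.sorted_exons()
    return (any(e.start <= cs < e.end for e in exons)
            and any(e.start < ce <= e.end for e in exons))


def _read_alteration(r: _Raw, problems: list[str]
                     ) -> Optional[SequenceAlteration]:
    rid = _unesc(r.attrs.get("ID", "")) or f"alt-line-{r.line_no}"
    residues = _unesc(r.attrs.get("residues", "")).upper()
    try:
        if r.ftype == "insertion":
            return SequenceAlteration(rid, "insertion", r.seqid,
                                      r.end0, residues, 0)
        if r.ftype == "deletion":
            return SequenceAlteration(rid, "deletion", r.seqid, r.start0,
                                      "", r.end0 - r.start0)
        return SequenceAlteration(rid, "substitution", r.seqid, r.start0,
                                  residues, r.end0 - r.start0)
    except ValueError as exc:
        problems.append(f"line {r.line_no}: {exc}")
        return None


def _split_list(raw: str) -> list[str]:
    return [_unesc(p) for p in raw.split(",") if p] if raw else []


# ---------------------------------------------------------------------------
# FASTA exports of annotation sequences
# ---------------------------------------------------------------------------

def spliced_cds_sequence(t: Transcript, ref: ReferenceSequence, alts) -> str:
    """CDS portion of the spliced mRNA (inserted bases inside the CDS
    included), 5'→3' on the transcript strand."""
    if t.cds is None:
        return ""
    cs, ce = t.cds
    mrna = extract_spliced(t, ref, alts)
    prov = mrna_to_ref(t, ref, alts)
    idx = [i for i, c in enumerate(prov) if c is not None and cs <= c < ce]
    if not idx:
        return ""
    return mrna[idx[0]:idx[-1] + 1]


def transcript_sequence(t: Transcript, ref: ReferenceSequence, alts,
                        kind: str) -> Optional[str]:
    """One exported sequence; ``None`` when undefined (peptide sans CDS)."""
    if kind == "genomic":
        s, e = t.span()
        seq = extract_slice(s, e, ref, alts)
        return reverse_complement(seq) if t.strand == -1 else seq
    if kind == "cdna":
        return extract_spliced(t, ref, alts)
    if kind == "cds":
        return spliced_cds_sequence(t, ref, alts) or None
    if kind == "peptide":
        cds = spliced_cds_sequence(t, ref, alts)
        return translate(cds) if cds else None
    raise ValueError(f"unknown export kind {kind!r}")


def export_fasta(genes: Iterable[Gene], refs: dict[str, ReferenceSequence],
                 alts, kind: str, path=None) -> str:
    """FASTA of per-transcript sequences computed through the virtual
    layer; transcripts without a CDS are skipped (with a warning) for
    cds/peptide exports."""
    if kind not in FASTA_KINDS:
        raise ValueError(f"unknown export kind {kind!r}")
    records = []
    entries = sorted(((g, t) for g in genes for t in g.transcripts),
                     key=lambda gt: (gt[1].seqid, gt[1].span()[0], gt[1].id))
    for g, t in entries:
        seq = transcript_sequence(t, refs[t.seqid], alts, kind)
        if seq is None:
            logger.warning("transcript %s has no CDS; skipped in %s export",
                           t.id, kind)
            continue
        records.append(SeqRecord(Seq(seq), id=t.id,
                                 description=f"{kind} gene={g.id}"))
    buf = StringIO()
    SeqIO.write(records, buf, "fasta")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[EvidenceFeature]:
    """BED6/BED12 evidence; BED12 blocks become exon structures."""
    problems: list[str] = []
    out: list[EvidenceFeature] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) not in (6, 12):
                problems.append(f"line {i}: expected 6 or 12 columns, "
                                f"got {len(cols)}")
                continue
            try:
                chrom, start, end, name = cols[0], int(cols[1]), int(cols[2]), cols[3]
                strand = {"+": +1, "-": -1}[cols[5]]
            except (ValueError, KeyError):
                problems.append(f"line {i}: malformed BED fields")
                continue
            if start >= end or start < 0:
                problems.append(f"line {i}: bad interval {start}..{end}")
                continue
            if len(cols) == 6:
                exons = [(start, end)]
            else:
                exons = _bed12_blocks(cols, start, end, i, problems)
                if exons is None:
                    continue
            out.append(EvidenceFeature(id=name or f"bed-line-{i}",
                                       ftype="BED", seqid=chrom,
                                       strand=strand, exons=exons))
    if problems:
        raise BedError("; ".join(problems))
    return out


def _bed12_blocks(cols, start, end, line_no, problems
                  ) -> Optional[list[tuple[int, int]]]:
    try:
        count = int(cols[9])
        sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
        starts = [int(x) for x in cols[11].rstrip(",").split(",")]
    except ValueError:
        problems.append(f"line {line_no}: malformed block columns")
        return None
    if len(sizes) != count or len(starts) != count or count < 1:
        problems.append(f"line {line_no}: blockCount {count} inconsistent "
                        f"with blockSizes/blockStarts")
        return None
    exons = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
    if starts[0] != 0 or exons[-1][1] != end or any(
            a[1] > b[0] for a, b in zip(exons, exons[1:])):
        problems.append(f"line {line_no}: blocks inconsistent with "
                        f"chromStart/chromEnd")
        return None
    return exons
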