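"""The annotation-editing engine: every structural edit with its intrinsic
cascades, applied as serialized requests in arrival order.

Requests are handled one at a time.  The unit of operation includes all
cascading edits intrinsic to the original operation — deleting a
transcript's last exon deletes the transcript, deleting a gene's last
transcript deletes the gene, and every touched transcript gets its CDS
(longest ORF, or re-extension from a pinned manual start) and splice QC
recomputed against the current sequence-alteration layer.  A request that
fails leaves the annotation set bit-identical to before (atomicity) and a
request that succeeds records exactly one history entry covering the
whole cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable, Optional

from . import policy as policy_mod
from .alterations import (
    AlterationSet,
    SequenceAlteration,
    extract_slice,
    extract_spliced,
    mrna_to_ref,
)
from .history import History, HistoryEntry
from .model import (
    ConflictError,
    Exon,
    Gene,
    GenecurateError,
    InvalidOperationError,
    QCReport,
    RangeError,
    ReferenceSequence,
    Transcript,
    reverse_complement,
    validate_all,
)
from .orf import STOP_CODONS, longest_orf, splice_qc

#: Half-width, in bases, of the window scanned for canonical GT / AG
#: dinucleotides when splitting an exon.
DEFAULT_SPLICE_WINDOW = 10

DEFAULT_POLICY = "simple_overlap"


def _utc_now() -> str:
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


@dataclass(frozen=True)
class EditRequest:
    """A named, attributed operation referencing features by id only."""

    op: str
    args: dict
    user: str = "anonymous"
    timestamp: Optional[str] = None


@dataclass
class EditResult:
    status: str  # "ok" | "conflict" | "invalid"
    message: str = ""
    created: list = field(default_factory=list)
    deleted: list = field(default_factory=list)
    modified: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.status == "ok"


class AnnotationEngine:
    """Holds the editable annotation set for a set of reference scaffolds.

    Parameters
    ----------
    refs
        Scaffold id → :class:`ReferenceSequence`.  Immutable substrate.
    policy
        Active isoform-assignment rule: ``no_overlap``, ``simple_overlap``
        or ``orf_overlap``.
    splice_window
        Search half-width for canonical splice-site snapping in
        :meth:`split_exon`.
    clock
        Callable returning an ISO-8601 timestamp; injectable so exports
        are byte-reproducible in scripted runs.
    """

    def __init__(self, refs: dict[str, ReferenceSequence],
                 policy: str = DEFAULT_POLICY,
                 splice_window: int = DEFAULT_SPLICE_WINDOW,
                 clock: Optional[Callable[[], str]] = None):
        if policy not in policy_mod.POLICIES:
            raise ValueError(f"unknown isoform policy {policy!r}")
        if splice_window < 0:
            raise ValueError("splice window must be >= 0")
        self.refs = dict(refs)
        self.policy = policy
        self.splice_window = splice_window
        self.clock = clock or _utc_now
        self.genes: dict[str, Gene] = {}
        self.alterations = AlterationSet()
        self._counters = {"gene": 0, "tx": 0, "exon": 0, "alt": 0}
        self.history = History(initial_state=self.snapshot())

    # ------------------------------------------------------------------
    # state snapshots
    # ------------------------------------------------------------------

    def snapshot(self) -> dict:
        return {
            "genes": [self.genes[k].to_dict() for k in sorted(self.genes)],
            "alterations": self.alterations.to_list(),
            "counters": dict(self._counters),
        }

    def restore(self, state: dict) -> None:
        self.genes = {d["id"]: Gene.from_dict(d) for d in state["genes"]}
        self.alterations = AlterationSet.from_list(state["alterations"])
        self._counters = dict(state["counters"])

    def rebuild_initial(self) -> None:
        """Reset history so the current state becomes the initial load."""
        self.history = History(initial_state=self.snapshot())

    # ------------------------------------------------------------------
    # lookup helpers
    # ------------------------------------------------------------------

    def _fresh_id(self, kind: str) -> str:
        self._counters[kind] += 1
        return f"{kind}-{self._counters[kind]}"

    def find_transcript(self, tx_id: str) -> tuple[Gene, Transcript]:
        for g in self.genes.values():
            for t in g.transcripts:
                if t.id == tx_id:
                    return g, t
        raise ConflictError(f"no transcript {tx_id!r} (stale reference)")

    def transcripts(self) -> list[Transcript]:
        return [t for g in self.genes.values() for t in g.transcripts]

    def _ref_for(self, seqid: str) -> ReferenceSequence:
        try:
            return self.refs[seqid]
        except KeyError:
            raise RangeError(f"unknown scaffold {seqid!r}")

    # ------------------------------------------------------------------
    # CDS recomputation (the cascade everything else triggers)
    # ------------------------------------------------------------------

    def spliced_cds_span(self, t: Transcript) -> Optional[tuple[int, int, bool]]:
        """(start, end, partial) of the CDS on the spliced mRNA, computed
        fresh from the transcript's exons and the current alterations."""
        ref = self._ref_for(t.seqid)
        mrna = extract_spliced(t, ref, self.alterations)
        if t.manual_start is not None:
            m2r = mrna_to_ref(t, ref, self.alterations)
            try:
                offset = m2r.index(t.manual_start)
            except ValueError:
                return self._longest_span(mrna)
            stop = next((i for i in range(offset, len(mrna) - 2, 3)
                         if mrna[i:i + 3] in STOP_CODONS), None)
            if stop is not None:
                return (offset, stop + 3, False)
            return (offset, len(mrna), True)
        return self._longest_span(mrna)

    @staticmethod
    def _longest_span(mrna: str) -> Optional[tuple[int, int, bool]]:
        orf = longest_orf(mrna)
        if orf is None:
            return None
        return (orf.start, orf.end, not orf.has_stop)

    def recompute_cds(self, t: Transcript) -> None:
        """Refresh the stored reference-coordinate CDS from the spliced
        mRNA; clears it (missing start) when no ORF exists."""
        span = self.spliced_cds_span(t)
        if span is None:
            t.cds, t.cds_partial = None, False
            return
        s, e, partial = span
        ref = self._ref_for(t.seqid)
        coords = [c for c in mrna_to_ref(t, ref, self.alterations)[s:e]
                  if c is not None]
        if not coords:  # CDS lies wholly in inserted bases (degenerate)
            t.cds, t.cds_partial = None, False
            return
        t.cds = (min(coords), max(coords) + 1)
        t.cds_partial = partial

    def qc(self, t: Transcript) -> QCReport:
        return splice_qc(t, self._ref_for(t.seqid), self.alterations)

    def qc_all(self) -> list[QCReport]:
        return [self.qc(t) for t in sorted(
            self.transcripts(), key=lambda t: (t.seqid, t.span()[0], t.id))]

    def mrna(self, t: Transcript) -> str:
        return extract_spliced(t, self._ref_for(t.seqid), self.alterations)

    # ------------------------------------------------------------------
    # serialized request application
    # ------------------------------------------------------------------

    def apply(self, request: EditRequest) -> EditResult:
        """Dispatch one request; atomic; one history entry per success."""
        op = getattr(self, f"_op_{request.op}", None)
        if op is None:
            raise GenecurateError(f"unknown operation {request.op!r}")
        pre = self.snapshot()
        ts = request.timestamp or self.clock()
        try:
            result = op(ts=ts, user=request.user, **request.args)
        except ConflictError as exc:
            self.restore(pre)
            return EditResult("conflict", str(exc))
        except (InvalidOperationError, RangeError, ValueError) as exc:
            self.restore(pre)
            return EditResult("invalid", str(exc))
        violations = validate_all(self.genes.values(), self.refs)
        if violations:  # cascade failed to close; treat as invalid, roll back
            self.restore(pre)
            return EditResult("invalid", "; ".join(violations))
        post = self.snapshot()
        self.history.record(HistoryEntry(
            seq=self.history.next_seq(), op=request.op, user=request.user,
            timestamp=ts, pre_state=pre, post_state=post,
            message=result.message))
        return result

    def perform(self, op: str, user: str = "anonymous",
                timestamp: Optional[str] = None, **args) -> EditResult:
        """Convenience wrapper building and applying an :class:`EditRequest`."""
        return self.apply(EditRequest(op, args, user, timestamp))

    # ------------------------------------------------------------------
    # undo / redo
    # ------------------------------------------------------------------

    def undo(self) -> bool:
        state = self.history.undo()
        if state is None:
            return False
        self.restore(state)
        return True

    def redo(self) -> bool:
        state = self.history.redo()
        if state is None:
            return False
        self.restore(state)
        return True

    # ------------------------------------------------------------------
    # operations (each _op_* returns an EditResult and may raise)
    # ------------------------------------------------------------------

    def _op_create_transcript_from_evidence(self, *, seqid: str, strand: int,
                                            exons: list, name: str = "",
                                            ts: str, user: str) -> EditResult:
        ref = self._ref_for(seqid)
        intervals = sorted((int(s), int(e)) for s, e in exons)
        if not intervals:
            raise InvalidOperationError("evidence has no exons")
        for s, e in intervals:
            if not (0 <= s < e <= ref.length):
                raise RangeError(
                    f"exon [{s},{e}) outside reference {seqid} "
                    f"of length {ref.length}")
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 <= e1:
                raise RangeError(
                    f"evidence exons [{s1},{e1}) and [{s2},{e2}) overlap "
                    f"or abut")
        t = Transcript(
            id=self._fresh_id("tx"), seqid=seqid, strand=int(strand),
            exons=[Exon(self._fresh_id("exon"), s, e) for s, e in intervals],
            owner=user, created=ts, modified=ts)
        self.recompute_cds(t)
        gene = self._assign(t, name=name)
        return EditResult("ok", f"created {t.id} in {gene.id}",
                          created=[gene.id, t.id], modified=[gene.id])

    def _assign(self, t: Transcript, name: str = "") -> Gene:
        target = policy_mod.assign_gene(t, self.genes.values(), self.policy)
        if target is None:
            target = Gene(id=self._fresh_id("gene"), seqid=t.seqid,
                          strand=t.strand, transcripts=[], name=name)
            self.genes[target.id] = target
        target.transcripts.append(t)
        return target

    def _op_delete_transcript(self, *, tx_id: str, ts: str, user: str) -> EditResult:
        gene, t = self.find_transcript(tx_id)
        gene.transcripts.remove(t)
        deleted = [t.id]
        if not gene.transcripts:  # cascading delete of the orphan gene
            del self.genes[gene.id]
            deleted.append(gene.id)
        return EditResult("ok", f"deleted {t.id}", deleted=deleted)

    def _op_delete_exon(self, *, tx_id: str, exon_id: str,
                        ts: str, user: str) -> EditResult:
        gene, t = self.find_transcript(tx_id)
        exon = t.exon_by_id(exon_id)
        t.exons.remove(exon)
        deleted = [exon.id]
        if not t.exons:  # last exon: cascade to transcript (and maybe gene)
            gene.transcripts.remove(t)
            deleted.append(t.id)
            if not gene.transcripts:
                del self.genes[gene.id]
                deleted.append(gene.id)
            return EditResult("ok", f"deleted {exon.id} and emptied {t.id}",
                              deleted=deleted)
        t.modified = ts
        self.recompute_cds(t)
        return EditResult("ok", f"deleted {exon.id}", deleted=deleted,
                          modified=[t.id])

    def _op_duplicate_transcript(self, *, tx_id: str, ts: str, user: str
                                 ) -> EditResult:
        gene, t = self.find_transcript(tx_id)
        copy = Transcript(
            id=self._fresh_id("tx"), seqid=t.seqid, strand=t.strand,
            exons=[Exon(self._fresh_id("exon"), e.start, e.end)
                   for e in t.sorted_exons()],
            cds=t.cds, cds_partial=t.cds_partial,
            manual_start=t.manual_start,
            owner=user, created=ts, modified=ts,
            comments=list(t.comments), dbxrefs=list(t.dbxrefs))
        gene.transcripts.append(copy)  # isoform by construction
        return EditResult("ok", f"duplicated {t.id} as {copy.id}",
                          created=[copy.id], modified=[gene.id])

    def _op_merge_transcripts(self, *, tx_id1: str, tx_id2: str,
                              ts: str, user: str) -> EditResult:
        if tx_id1 == tx_id2:
            raise InvalidOperationError("cannot merge a transcript with itself")
        g1, t1 = self.find_transcript(tx_id1)
        g2, t2 = self.find_transcript(tx_id2)
        if t1.seqid != t2.seqid:
            raise InvalidOperationError(
                f"{t1.id} and {t2.id} lie on different scaffolds")
        if t1.strand != t2.strand:
            raise InvalidOperationError(
                f"{t1.id} and {t2.id} lie on different strands")
        t1.exons = _coalesce_exons(t1.sorted_exons() + t2.sorted_exons(),
                                   self._fresh_id)
        t1.comments += t2.comments
        t1.dbxrefs += t2.dbxrefs
        t1.manual_start = None  # no principled way to keep either anchor
        t1.modified = ts
        g2.transcripts.remove(t2)
        deleted = [t2.id]
        if g2 is not g1:  # merge the source genes into one
            g1.transcripts.extend(g2.transcripts)
            g1.comments += g2.comments
            g1.dbxrefs += g2.dbxrefs
            del self.genes[g2.id]
            deleted.append(g2.id)
        self.recompute_cds(t1)
        return EditResult("ok", f"merged {tx_id2} into {tx_id1}",
                          deleted=deleted, modified=[t1.id, g1.id])

    def _op_split_transcript(self, *, tx_id: str, after_exon_index: int,
                             ts: str, user: str) -> EditResult:
        gene, t = self.find_transcript(tx_id)
        exons = t.sorted_exons()
        if len(exons) < 2:
            raise InvalidOperationError(
                f"{t.id}: cannot split a single-exon transcript")
        i = int(after_exon_index)
        if not (0 <= i < len(exons) - 1):
            raise InvalidOperationError(
                f"{t.id}: split index {i} out of range 0..{len(exons) - 2}")
        # side A keeps the transcript id and anchors the original gene;
        # side B is assigned a gene by the active isoform policy
        t.exons = exons[:i + 1]
        t.manual_start = None
        t.modified = ts
        self.recompute_cds(t)
        b = Transcript(
            id=self._fresh_id("tx"), seqid=t.seqid, strand=t.strand,
            exons=exons[i + 1:], owner=user, created=ts, modified=ts,
            comments=list(t.comments), dbxrefs=list(t.dbxrefs))
        self.recompute_cds(b)
        gb = self._assign(b)
        return EditResult("ok", f"split {t.id}; new transcript {b.id} in {gb.id}",
                          created=[b.id, gb.id], modified=[t.id, gene.id])

    def _op_set_exon_boundary(self, *, tx_id: str, exon_id: str,
                              new_start: int, new_end: int,
                              ts: str, user: str) -> EditResult:
        gene, t = self.find_transcript(tx_id)
        exon = t.exon_by_id(exon_id)
        ref = self._ref_for(t.seqid)
        s, e = int(new_start), int(new_end)
        if not (0 <= s < e <= ref.length):
            raise RangeError(f"exon interval [{s},{e}) outside reference "
                             f"{ref.id} of length {ref.length}")
        for sib in t.exons:
            if sib is exon:
                continue
            if not (e < sib.start or sib.end < s):  # overlap or abut
                raise InvalidOperationError(
                    f"exon {exon.id}: new interval [{s},{e}) would overlap "
                    f"or abut sibling {sib.id} [{sib.start},{sib.end})")
        exon.start, exon.end = s, e
        t.modified = ts
        self.recompute_cds(t)
        return EditResult("ok", f"set {exon.id} to [{s},{e})",
                          modified=[exon.id, t.id])

    def _op_merge_exons(self, *, tx_id: str, exon_id1: str, exon_id2: str,
                        ts: str, user: str) -> EditResult:
        gene, t = self.find_transcript(tx_id)
        e1 = t.exon_by_id(exon_id1)
        e2 = t.exon_by_id(exon_id2)
        exons = t.sorted_exons()
        i1, i2 = exons.index(e1), exons.index(e2)
        if i2 < i1:
            e1, e2, i1, i2 = e2, e1, i2, i1
        if i2 != i1 + 1:
            raise InvalidOperationError(
                f"exons {exon_id1} and {exon_id2} are not adjacent in {t.id}")
        e1.end = e2.end  # absorb the intervening intron
        t.exons.remove(e2)
        t.modified = ts
        self.recompute_cds(t)
        return EditResult("ok", f"merged {e2.id} into {e1.id}",
                          deleted=[e2.id], modified=[e1.id, t.id])

    def _op_split_exon(self, *, tx_id: str, exon_id: str, split_point: int,
                       ts: str, user: str) -> EditResult:
        gene, t = self.find_transcript(tx_id)
        exon = t.exon_by_id(exon_id)
        p = int(split_point)
        if not (exon.start + 1 <= p <= exon.end - 3):
            raise InvalidOperationError(
                f"exon {exon.id}: split point {p} must leave >=1 base on "
                f"each side of a 2-base intron within [{exon.start},{exon.end})")
        d, a = self._snap_intron(t, exon, p)
        right = Exon(self._fresh_id("exon"), a, exon.end)
        exon.end = d
        t.exons.append(right)
        t.modified = ts
        self.recompute_cds(t)
        return EditResult("ok",
                          f"split {exon.id} at {p}; intron [{d},{a}), "
                          f"new exon {right.id}",
                          created=[right.id], modified=[exon.id, t.id])

    def _snap_intron(self, t: Transcript, exon: Exon, p: int
                     ) -> tuple[int, int]:
        """New-intron reference interval [d, a) for a split at ``p``.

        Within the search window the donor edge snaps to the nearest GT
        and the acceptor edge to the nearest AG on the transcript strand
        of the virtual sequence (donor snapped first).  With no canonical
        pair in reach, a minimal 2-base intron is cut verbatim at ``p``
        and left for QC to flag.
        """
        W = self.splice_window
        ref = self._ref_for(t.seqid)

        def dinuc(lo: int) -> str:
            s = extract_slice(lo, lo + 2, ref, self.alterations)
            return s if len(s) == 2 else ""

        fallback = (p, p + 2)
        if t.strand == +1:
            donor_pat, acceptor_pat = "GT", "AG"
            donor_lo = lambda d: d          # noqa: E731 — donor at intron start
            acceptor_lo = lambda a: a - 2   # noqa: E731
        else:
            # transcript reads right→left: donor sits at the intron's right
            # edge (reference "AC" = revcomp GT), acceptor at the left
            # (reference "CT" = revcomp AG)
            donor_pat, acceptor_pat = "AC", "CT"
            donor_lo = lambda a: a - 2      # noqa: E731
            acceptor_lo = lambda d: d       # noqa: E731

        if t.strand == +1:
            d = _nearest(p, W, exon.start + 1, exon.end - 5,
                         lambda x: dinuc(donor_lo(x)) == donor_pat)
            if d is None:
                return fallback
            a = _nearest(p + 2, W, d + 4, exon.end - 1,
                         lambda x: dinuc(acceptor_lo(x)) == acceptor_pat)
            if a is None:
                return fallback
            return (d, a)
        # minus strand: snap the donor (right edge, 5' of the intron) first
        a = _nearest(p + 2, W, exon.start + 5, exon.end - 1,
                     lambda x: dinuc(donor_lo(x)) == donor_pat)
        if a is None:
            return fallback
        d = _nearest(p, W, exon.start + 1, a - 4,
                     lambda x: dinuc(acceptor_lo(x)) == acceptor_pat)
        if d is None:
            return fallback
        return (d, a)

    def _op_set_translation_start(self, *, tx_id: str, position: int,
                                  ts: str, user: str) -> EditResult:
        gene, t = self.find_transcript(tx_id)
        pos = int(position)
        if not any(e.start <= pos < e.end for e in t.exons):
            raise InvalidOperationError(
                f"{t.id}: position {pos} is not inside an exon")
        t.manual_start = pos
        t.modified = ts
        self.recompute_cds(t)
        return EditResult("ok", f"translation start of {t.id} pinned at {pos}",
                          modified=[t.id])

    def _op_clear_translation_start(self, *, tx_id: str, ts: str, user: str
                                    ) -> EditResult:
        gene, t = self.find_transcript(tx_id)
        t.manual_start = None
        t.modified = ts
        self.recompute_cds(t)
        return EditResult("ok", f"translation start of {t.id} recomputed",
                          modified=[t.id])

    def _op_flip_strand(self, *, tx_id: str, ts: str, user: str) -> EditResult:
        gene, t = self.find_transcript(tx_id)
        gene.transcripts.remove(t)
        deleted = []
        if not gene.transcripts:
            del self.genes[gene.id]
            deleted.append(gene.id)
        t.strand = -t.strand
        t.manual_start = None  # anchored to the old reading direction
        t.modified = ts
        self.recompute_cds(t)
        target = self._assign(t)
        return EditResult("ok", f"flipped {t.id}; now in {target.id}",
                          created=[] if target.id in deleted else [target.id],
                          deleted=deleted, modified=[t.id])

    def _op_add_alteration(self, *, kind: str, seqid: str, position: int,
                           residues: str = "", length: int = 0,
                           ts: str, user: str) -> EditResult:
        ref = self._ref_for(seqid)
        if kind == "substitution" and residues and not length:
            length = len(residues)
        alt = SequenceAlteration(
            id=self._fresh_id("alt"), kind=kind, seqid=seqid,
            position=int(position), residues=residues.upper(),
            length=int(length))
        self.alterations.add(alt, ref)
        touched = self._recompute_scaffold(seqid, ts)
        return EditResult("ok", f"added {alt.kind} {alt.id} at {alt.position}",
                          created=[alt.id], modified=touched)

    def _op_remove_alteration(self, *, alt_id: str, ts: str, user: str
                              ) -> EditResult:
        alt = self.alterations.remove(alt_id)
        touched = self._recompute_scaffold(alt.seqid, ts)
        return EditResult("ok", f"removed {alt.kind} {alt.id}",
                          deleted=[alt.id], modified=touched)

    def _recompute_scaffold(self, seqid: str, ts: str) -> list[str]:
        """Cascade of an alteration edit: refresh CDS for transcripts on
        the scaffold; an alteration can change splice dinucleotides from
        inside an intron, so QC is always computed on demand from the
        current virtual sequence."""
        touched = []
        for t in self.transcripts():
            if t.seqid != seqid:
                continue
            before = (t.cds, t.cds_partial)
            self.recompute_cds(t)
            if (t.cds, t.cds_partial) != before:
                t.modified = ts
                touched.append(t.id)
        return touched


def _coalesce_exons(exons: list[Exon], fresh_id) -> list[Exon]:
    """Union of exon intervals with overlapping or abutting ones merged.

    An exon whose interval survives unchanged keeps its id; merged
    intervals get a fresh id so ids never alias two shapes.
    """
    intervals: list[tuple[int, int, list[Exon]]] = []
    for e in sorted(exons, key=lambda e: (e.start, e.end, e.id)):
        if intervals and e.start <= intervals[-1][1]:
            s, prev_end, members = intervals[-1]
            intervals[-1] = (s, max(prev_end, e.end), members + [e])
        else:
            intervals.append((e.start, e.end, [e]))
    out: list[Exon] = []
    for s, e, members in intervals:
        keeper = next((m for m in members if m.start == s and m.end == e), None)
        if keeper is not None and len(members) == 1:
            out.append(keeper)
        elif keeper is not None:
            out.append(Exon(keeper.id, s, e))
        else:
            out.append(Exon(fresh_id("exon"), s, e))
    return out


def _nearest(center: int, window: int, lo: int, hi: int, pred) -> Optional[int]:
    """Nearest x to ``center`` with ``lo <= x <= hi`` and pred(x), scanning
    distance 0,1,... and preferring the left candidate on ties."""
    for dist in range(window + 1):
        for x in (center - dist, center + dist):
            if lo <= x <= hi and pred(x):
                return x
    return None
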