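"""Sequence-level computations: translation, longest-ORF search, six-frame
translation, per-exon reading frames, splice-site QC and edge matching.

Longest-ORF rule
----------------
The spliced mRNA is scanned 5'→3' in all three forward frames for ORFs
starting at ATG.  The CDS is the longest ATG→stop span (stop codon
included in the span), ties broken by the 5'-most start.  If no in-frame
stop occurs before the transcript end the ORF extends to the end and is
flagged partial; with no ATG at all the CDS is unset and ``missing_start``
is flagged.  Only GT–AG introns count as canonical; the minor GC–AG and
AT–AC classes are reported as non-canonical (the flag is advisory, never
blocking).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.Data import CodonTable

from .model import QCReport, ReferenceSequence, Transcript, reverse_complement
from .alterations import extract_slice

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_STANDARD.forward_table)
STOP_CODONS = frozenset(_STANDARD.stop_codons)  # TAA, TAG, TGA


@dataclass(frozen=True)
class OrfResult:
    """An open reading frame on a spliced mRNA, 0-based half-open offsets.

    ``end`` points one past the stop codon when ``has_stop``; otherwise to
    the transcript end (a partial CDS).  The peptide excludes the stop.
    """

    start: int
    end: int
    has_stop: bool
    peptide: str

    @property
    def length(self) -> int:
        return self.end - self.start


def translate(cds: str) -> str:
    """Standard-code translation, codon by codon.

    Stops at the first stop codon; a trailing partial codon is ignored;
    any codon containing N translates to 'X' (assembly gaps are legal
    reference residues).
    """
    pep = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i:i + 3]
        if codon in STOP_CODONS:
            break
        pep.append(_FORWARD.get(codon, "X"))
    return "".join(pep)


def translate_display(seq: str) -> str:
    """Translation for display: stop codons render as '*', no early stop."""
    return "".join(
        "*" if seq[i:i + 3] in STOP_CODONS else _FORWARD.get(seq[i:i + 3], "X")
        for i in range(0, len(seq) - 2, 3))


def longest_orf(mrna: str) -> Optional[OrfResult]:
    """Longest ATG-anchored ORF across the three forward frames.

    Returns ``None`` when the mRNA has no ATG.  A stop-terminated span
    includes its stop codon; a stopless ORF runs to the transcript end
    and is marked partial (``has_stop`` False).
    """
    # first in-frame stop downstream of each position, per frame
    best: Optional[tuple[int, int, bool]] = None  # (length, -start) ordering
    n = len(mrna)
    stops_by_frame: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for i in range(n - 2):
        if mrna[i:i + 3] in STOP_CODONS:
            stops_by_frame[i % 3].append(i)
    for s in _find_all(mrna, "ATG"):
        frame = s % 3
        stop = next((p for p in stops_by_frame[frame] if p >= s + 3), None)
        if stop is not None:
            cand = (s, stop + 3, True)
        else:
            cand = (s, n, False)
        if best is None or _better(cand, best):
            best = cand
    if best is None:
        return None
    s, e, has_stop = best
    return OrfResult(s, e, has_stop, translate(mrna[s:e]))


def _better(a: tuple[int, int, bool], b: tuple[int, int, bool]) -> bool:
    la, lb = a[1] - a[0], b[1] - b[0]
    if la != lb:
        return la > lb
    return a[0] < b[0]  # ties: 5'-most start


def _find_all(s: str, sub: str) -> Iterable[int]:
    i = s.find(sub)
    while i != -1:
        yield i
        i = s.find(sub, i + 1)


def six_frame_translation(seq: str) -> list[str]:
    """Display peptides for frames +1,+2,+3 then -1,-2,-3.

    Reverse frames are the forward frames of the reverse complement;
    stops are rendered '*' with no early termination.
    """
    rc = reverse_complement(seq)
    return ([translate_display(seq[f:]) for f in range(3)]
            + [translate_display(rc[f:]) for f in range(3)])


def reading_frame(transcript: Transcript, exon_id: str) -> Optional[int]:
    """Reading frame (0/1/2) of an exon's first coding base.

    Defined as the number of coding bases 5' of this exon's first coding
    base, mod 3, walking exons in transcript order; ``None`` for a wholly
    non-coding exon or a transcript without CDS.  Computed on reference
    coordinates (alterations do not move the stored CDS anchors).
    """
    if transcript.cds is None:
        return None
    cs, ce = transcript.cds
    exons = transcript.sorted_exons()
    if transcript.strand == -1:
        exons = exons[::-1]
    coding_before = 0
    for e in exons:
        lo, hi = max(e.start, cs), min(e.end, ce)
        if lo >= hi:  # non-coding exon
            if e.id == exon_id:
                return None
            continue
        if e.id == exon_id:
            return coding_before % 3
        coding_before += hi - lo
    return None


def introns(transcript: Transcript) -> list[tuple[int, int]]:
    """Reference-coordinate gaps between consecutive exons, left to right."""
    exons = transcript.sorted_exons()
    return [(a.end, b.start) for a, b in zip(exons, exons[1:])]


def splice_qc(transcript: Transcript, ref: ReferenceSequence,
              alts=()) -> QCReport:
    """Flag non-canonical splice junctions plus missing-start / partial-CDS.

    For each intron the donor is the first two intronic bases and the
    acceptor the last two, read on the transcript strand of the *virtual*
    sequence — a substitution correcting a mis-called donor base clears
    the flag, exactly as a curator expects.  Intron indices are numbered
    in transcript (5'→3') order.
    """
    gaps = introns(transcript)
    dinucs: list[tuple[str, str]] = []
    for (gs, ge) in gaps:
        intron_seq = extract_slice(gs, ge, ref, alts)
        if transcript.strand == -1:
            intron_seq = reverse_complement(intron_seq)
        dinucs.append((intron_seq[:2], intron_seq[-2:]))
    if transcript.strand == -1:
        dinucs = dinucs[::-1]
    flagged = [(i, d, a) for i, (d, a) in enumerate(dinucs)
               if d != "GT" or a != "AG"]
    return QCReport(
        transcript_id=transcript.id,
        noncanonical_junctions=flagged,
        missing_start=transcript.cds is None,
        partial_cds=transcript.cds_partial,
    )


def edge_matches(selected_exons: Iterable, candidates: dict[str, Iterable]
                 ) -> list[tuple[str, int]]:
    """Exact start/end coordinate coincidences between a selected feature's
    exons and candidate features' exons, one report per matching edge.

    Used to corroborate exon boundaries against evidence tracks: a shared
    edge between an annotation and an aligned EST or prediction is strong
    support for that boundary.
    """
    edges: set[int] = set()
    for e in selected_exons:
        edges.add(e.start)
        edges.add(e.end)
    out: set[tuple[str, int]] = set()
    for cand_id, exons in candidates.items():
        for e in exons:
            if e.start in edges:
                out.add((cand_id, e.start))
            if e.end in edges:
                out.add((cand_id, e.end))
    return sorted(out)
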