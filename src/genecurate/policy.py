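"""Pluggable isoform-assignment policies.

When a transcript is created, split off, or strand-flipped, a policy
decides whether it joins an existing gene as an isoform or founds a new
gene:

``no_overlap``
    every transcript gets its own gene, regardless of overlap;
``simple_overlap``
    a transcript is an isoform of a gene if its span intersects a member
    transcript's span on the same strand;
``orf_overlap``
    a transcript is an isoform only if its coding region shares at least
    one reference base with a member's coding region *in the same codon
    phase* on the same strand.

Grouping is decided at edit time; switching the active policy never
regroups existing genes retroactively.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .model import Gene, Transcript

POLICIES = ("no_overlap", "simple_overlap", "orf_overlap")


def _spans_intersect(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def coding_phase_map(t: Transcript) -> dict[int, int]:
    """Codon phase of every coding reference base of a transcript.

    Phase at a base = number of coding bases 5' of it along the
    transcript, mod 3, counted from the transcript's own CDS start.
    Reference-coordinate phases make "same frame" well defined across
    transcripts with different exon structures.
    """
    if t.cds is None:
        return {}
    cs, ce = t.cds
    exons = t.sorted_exons()
    if t.strand == -1:
        exons = exons[::-1]
    phases: dict[int, int] = {}
    count = 0
    for e in exons:
        lo, hi = max(e.start, cs), min(e.end, ce)
        if lo >= hi:
            continue
        positions = range(lo, hi) if t.strand == +1 else range(hi - 1, lo - 1, -1)
        for pos in positions:
            phases[pos] = count % 3
            count += 1
    return phases


def same_gene(t1: Transcript, t2: Transcript, policy: str) -> bool:
    """Should two transcripts on one scaffold belong to the same gene?

    Symmetric for every policy.  Strand equality is required for
    ``simple_overlap`` and ``orf_overlap`` (antisense transcripts are
    never isoforms); ``no_overlap`` is constantly false.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown isoform policy {policy!r}")
    if policy == "no_overlap":
        return False
    if t1.seqid != t2.seqid or t1.strand != t2.strand:
        return False
    if policy == "simple_overlap":
        return _spans_intersect(t1.span(), t2.span())
    # orf_overlap
    if t1.cds is None or t2.cds is None:
        return False
    p1 = coding_phase_map(t1)
    p2 = coding_phase_map(t2)
    if len(p2) < len(p1):
        p1, p2 = p2, p1
    return any(pos in p2 and p2[pos] == phase for pos, phase in p1.items())


def assign_gene(t: Transcript, genes: Iterable[Gene], policy: str
                ) -> Optional[Gene]:
    """The existing gene the transcript joins, or ``None`` for a new gene.

    Candidate genes are scanned in span order (ties by id); the first one
    containing a transcript for which :func:`same_gene` holds wins.
    Genes are never auto-merged when a transcript would bridge two of
    them — that is an explicit curator merge.
    """
    candidates = sorted((g for g in genes if g.seqid == t.seqid),
                        key=lambda g: (g.span()[0], g.id))
    for g in candidates:
        if any(same_gene(t, member, policy) for member in g.transcripts):
            return g
    return None
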