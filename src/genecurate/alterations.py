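"""Sequence-alteration layer: curator-asserted insertions, deletions and
substitutions that correct suspected assembly errors without ever mutating
the stored reference.

The set of alterations on a scaffold defines a *virtual sequence* — the
reference with all edits applied — which is the substrate for every mRNA,
CDS and peptide computation downstream.  Features stay addressed in
reference coordinates at all times; only sequence extraction consults this
layer, so alteration edits can later be folded into a new assembly without
rewriting the annotation set.

Anchoring convention: an insertion at position ``p`` inserts its residues
immediately *before* reference base ``p``.  Consequently an insertion at an
exon's start coordinate is included in that exon's transcript sequence,
while one at its end coordinate is excluded (half-open consistency).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import (
    ConflictError,
    RangeError,
    ReferenceSequence,
    Transcript,
    reverse_complement,
)

KINDS = ("insertion", "deletion", "substitution")


@dataclass(frozen=True)
class SequenceAlteration:
    """One insertion, deletion or substitution in reference coordinates.

    ``position`` is 0-based: for an insertion, the base *before which*
    residues are inserted; for a deletion or substitution, the start of
    the affected span.  ``length`` is the affected reference span (0 for
    insertions).
    """

    id: str
    kind: str
    seqid: str
    position: int
    residues: str = ""
    length: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown alteration kind {self.kind!r}")
        if self.kind == "insertion":
            if self.length != 0 or not self.residues:
                raise ValueError(
                    f"alteration {self.id}: insertion needs residues and length 0")
        elif self.kind == "deletion":
            if self.length < 1 or self.residues:
                raise ValueError(
                    f"alteration {self.id}: deletion needs length >= 1 and no residues")
        else:  # substitution
            if self.length < 1 or len(self.residues) != self.length:
                raise ValueError(
                    f"alteration {self.id}: substitution needs "
                    f"len(residues) == length >= 1")

    @property
    def span(self) -> tuple[int, int]:
        """Affected reference span (empty for insertions)."""
        return (self.position, self.position + self.length)

    def to_dict(self) -> dict:
        return {
            "id": self.id, "kind": self.kind, "seqid": self.seqid,
            "position": self.position, "residues": self.residues,
            "length": self.length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceAlteration":
        return cls(d["id"], d["kind"], d["seqid"], d["position"],
                   d.get("residues", ""), d.get("length", 0))


class AlterationSet:
    """Pairwise non-overlapping alterations, indexed by id and scaffold."""

    def __init__(self) -> None:
        self._by_id: dict[str, SequenceAlteration] = {}

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(sorted(self._by_id.values(),
                           key=lambda a: (a.seqid, a.position, a.id)))

    def __contains__(self, alt_id: str) -> bool:
        return alt_id in self._by_id

    def get(self, alt_id: str) -> SequenceAlteration:
        try:
            return self._by_id[alt_id]
        except KeyError:
            raise ConflictError(f"no alteration {alt_id!r} (stale reference)")

    def for_seqid(self, seqid: str) -> list[SequenceAlteration]:
        """Alterations on one scaffold, sorted by position."""
        return sorted((a for a in self._by_id.values() if a.seqid == seqid),
                      key=lambda a: a.position)

    def add(self, alt: SequenceAlteration, ref: ReferenceSequence) -> None:
        if alt.seqid != ref.id:
            raise RangeError(f"alteration {alt.id}: scaffold {alt.seqid!r} "
                             f"is not {ref.id!r}")
        if not (0 <= alt.position and alt.position + alt.length <= ref.length):
            raise RangeError(
                f"alteration {alt.id}: span {alt.span} outside reference "
                f"{ref.id} of length {ref.length}")
        if alt.kind == "insertion" and alt.position > ref.length:
            raise RangeError(f"alteration {alt.id}: anchor beyond reference end")
        if alt.id in self._by_id:
            raise ConflictError(f"duplicate alteration id {alt.id!r}")
        for other in self.for_seqid(alt.seqid):
            if _conflicts(alt, other):
                raise ConflictError(
                    f"alteration {alt.id} overlaps existing {other.id} "
                    f"at {other.span}")
        self._by_id[alt.id] = alt

    def remove(self, alt_id: str) -> SequenceAlteration:
        alt = self.get(alt_id)
        del self._by_id[alt_id]
        return alt

    def to_list(self) -> list[dict]:
        return [a.to_dict() for a in self]

    @classmethod
    def from_list(cls, items: list[dict]) -> "AlterationSet":
        s = cls()
        for d in items:
            s._by_id[d["id"]] = SequenceAlteration.from_dict(d)
        return s


def _conflicts(a: SequenceAlteration, b: SequenceAlteration) -> bool:
    """Affected spans overlap; two insertions at one anchor conflict, and an
    insertion strictly inside another alteration's span conflicts (inserting
    into a deleted/substituted region has no defined meaning)."""
    a0, a1 = a.span
    b0, b1 = b.span
    if a.kind == "insertion" and b.kind == "insertion":
        return a0 == b0
    if a.kind == "insertion":
        return b0 < a0 < b1
    if b.kind == "insertion":
        return a0 < b0 < a1
    return a0 < b1 and b0 < a1


# ---------------------------------------------------------------------------
# Virtual sequence and coordinate mapping
# ---------------------------------------------------------------------------

def virtual_sequence(ref: ReferenceSequence,
                     alts: list[SequenceAlteration] | AlterationSet) -> str:
    """The reference with all alterations applied, sorted by position."""
    parts: list[str] = []
    cursor = 0
    for alt in _sorted_for(ref, alts):
        parts.append(ref.residues[cursor:alt.position])
        if alt.kind == "insertion":
            parts.append(alt.residues)
            cursor = alt.position
        elif alt.kind == "substitution":
            parts.append(alt.residues)
            cursor = alt.position + alt.length
        else:  # deletion
            cursor = alt.position + alt.length
    parts.append(ref.residues[cursor:])
    return "".join(parts)


def _sort_key(a: SequenceAlteration) -> tuple:
    # insertion anchored at p precedes the (possibly deleted/substituted)
    # reference base p in the virtual string
    return (a.position, 0 if a.kind == "insertion" else 1, a.id)


def _sorted_for(ref: ReferenceSequence, alts) -> list[SequenceAlteration]:
    if isinstance(alts, AlterationSet):
        return sorted(alts.for_seqid(ref.id), key=_sort_key)
    return sorted((a for a in alts if a.seqid == ref.id), key=_sort_key)


def virtual_cut(pos: int, alts: list[SequenceAlteration]) -> int:
    """Virtual index of the cut *before* reference position ``pos``,
    counting insertions anchored strictly left of ``pos`` only.

    Slicing the virtual sequence at ``[virtual_cut(s), virtual_cut(e))``
    therefore includes an insertion anchored at ``s`` and excludes one
    anchored at ``e`` — exactly the exon-extraction convention.
    """
    out = pos
    for a in alts:
        if a.kind == "insertion":
            if a.position < pos:
                out += len(a.residues)
        elif a.kind == "deletion":
            out -= min(max(pos - a.position, 0), a.length)
        # substitutions preserve length
    return out


def map_ref_to_virtual(pos: int, ref: ReferenceSequence,
                       alts: list[SequenceAlteration] | AlterationSet
                       ) -> Optional[int]:
    """Virtual coordinate of reference base ``pos``, or ``None`` if the
    base is removed by a deletion.

    The mapping restricted to non-deleted positions is strictly
    increasing.  An insertion anchored at ``pos`` precedes base ``pos`` in
    the virtual string, so it shifts the mapped coordinate.
    """
    if not (0 <= pos < ref.length):
        raise RangeError(f"position {pos} outside reference {ref.id} "
                         f"of length {ref.length}")
    salts = _sorted_for(ref, alts)
    for a in salts:
        if a.kind == "deletion" and a.position <= pos < a.position + a.length:
            return None
    out = virtual_cut(pos, salts)
    for a in salts:
        if a.kind == "insertion" and a.position == pos:
            out += len(a.residues)
    return out


def extract_slice(start: int, end: int, ref: ReferenceSequence,
                  alts: list[SequenceAlteration] | AlterationSet) -> str:
    """Virtual-sequence content of the reference interval ``[start, end)``:
    deleted bases omitted, substituted bases replaced, insertions anchored
    in ``[start, end)`` included (an insertion at ``end`` is excluded)."""
    salts = _sorted_for(ref, alts)
    vseq = virtual_sequence(ref, salts)
    return vseq[virtual_cut(start, salts):virtual_cut(end, salts)]


def extract_spliced(transcript: Transcript, ref: ReferenceSequence,
                    alts: list[SequenceAlteration] | AlterationSet) -> str:
    """Spliced transcript sequence (mRNA), 5'→3' on the transcript strand,
    computed through the virtual layer."""
    salts = _sorted_for(ref, alts)
    vseq = virtual_sequence(ref, salts)
    mrna = "".join(vseq[virtual_cut(e.start, salts):virtual_cut(e.end, salts)]
                   for e in transcript.sorted_exons())
    if transcript.strand == -1:
        mrna = reverse_complement(mrna)
    return mrna


def mrna_to_ref(transcript: Transcript, ref: ReferenceSequence,
                alts: list[SequenceAlteration] | AlterationSet
                ) -> list[Optional[int]]:
    """Per-base provenance of the spliced mRNA: for each mRNA offset the
    originating reference coordinate, or ``None`` for inserted bases.

    Substituted bases keep their reference coordinate.  Used to anchor a
    longest-ORF result (mRNA offsets) back onto the reference.
    """
    salts = _sorted_for(ref, alts)
    coords: list[Optional[int]] = []
    for e in transcript.sorted_exons():
        coords.extend(_interval_provenance(e.start, e.end, salts))
    if transcript.strand == -1:
        coords.reverse()
    return coords


def _interval_provenance(start: int, end: int,
                         alts: list[SequenceAlteration]) -> list[Optional[int]]:
    out: list[Optional[int]] = []
    pos = start
    # walk reference positions, interleaving insertions at their anchors
    ins_at = {a.position: a for a in alts if a.kind == "insertion"}
    deleted: set[int] = set()
    for a in alts:
        if a.kind == "deletion":
            deleted.update(range(a.position, a.position + a.length))
    while pos < end:
        a = ins_at.get(pos)
        if a is not None:
            out.extend([None] * len(a.residues))
        if pos not in deleted:
            out.append(pos)
        pos += 1
    return out
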