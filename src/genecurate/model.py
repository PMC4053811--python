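"""Core genome model: reference scaffolds and the gene → transcript → exon
hierarchy that every editing operation manipulates.

Coordinate convention
---------------------
All internal coordinates are 0-based half-open ``[start, end)`` on the
reference scaffold.  GFF3 I/O converts to and from the 1-based closed
external convention (see :mod:`genecurate.io_formats`).

Strand is a property of transcripts and genes (+1 / -1); exons carry no
strand of their own, so flipping a transcript's strand never touches its
exon coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

VALID_RESIDUES = frozenset("ACGTN")
_RESIDUE_RE = re.compile(r"[^ACGTN]")

#: Introns shorter than this cannot hold a GT..AG pair; they are flagged by
#: QC but never forbidden by validation.
MIN_CANONICAL_INTRON = 4


class GenecurateError(Exception):
    """Base class for all package errors."""


class RangeError(GenecurateError):
    """A coordinate fell outside the reference or a feature's bounds."""


class ConflictError(GenecurateError):
    """A request referenced a feature that no longer exists, or collided
    with existing state (stale reference / overlapping alteration)."""


class InvalidOperationError(GenecurateError):
    """The operation's preconditions are not met on the current state."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ReferenceSequence:
    """An immutable named scaffold of DNA residues.

    Sequence alterations never mutate the reference; they live in a
    separate layer (:mod:`genecurate.alterations`) that yields a *virtual*
    sequence for all transcript and peptide calculations.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        m = _RESIDUE_RE.search(self.residues)
        if m:
            raise ValueError(
                f"reference {self.id!r}: illegal residue {m.group()!r} "
                f"at offset {m.start()}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Exon:
    """A half-open exon interval on the reference."""

    id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_dict(self) -> dict:
        return {"id": self.id, "start": self.start, "end": self.end}

    @classmethod
    def from_dict(cls, d: dict) -> "Exon":
        return cls(d["id"], d["start"], d["end"])


@dataclass
class Transcript:
    """An exon chain with an optional CDS, owned by a user.

    ``cds`` is a reference-coordinate interval ``(cds_start, cds_end)``
    covering the translated span (start codon through stop codon, clipped
    to the transcript if the stop is absent).  ``cds_partial`` marks a CDS
    with no in-frame stop before the transcript end.  ``manual_start``
    pins the translation start to a genomic position: structural edits
    then re-extend the CDS from that anchor instead of re-running the
    longest-ORF search.
    """

    id: str
    seqid: str
    strand: int  # +1 or -1
    exons: list[Exon] = field(default_factory=list)
    cds: Optional[tuple[int, int]] = None
    cds_partial: bool = False
    manual_start: Optional[int] = None
    owner: str = "anonymous"
    created: str = ""
    modified: str = ""
    comments: list[str] = field(default_factory=list)
    dbxrefs: list[str] = field(default_factory=list)

    def span(self) -> tuple[int, int]:
        """Minimal half-open interval covering all exons."""
        if not self.exons:
            raise InvalidOperationError(f"transcript {self.id} has no exons")
        return (min(e.start for e in self.exons), max(e.end for e in self.exons))

    def sorted_exons(self) -> list[Exon]:
        return sorted(self.exons, key=lambda e: e.start)

    def exon_by_id(self, exon_id: str) -> Exon:
        for e in self.exons:
            if e.id == exon_id:
                return e
        raise ConflictError(f"transcript {self.id}: no exon {exon_id!r}")

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "seqid": self.seqid,
            "strand": self.strand,
            "exons": [e.to_dict() for e in self.sorted_exons()],
            "cds": list(self.cds) if self.cds else None,
            "cds_partial": self.cds_partial,
            "manual_start": self.manual_start,
            "owner": self.owner,
            "created": self.created,
            "modified": self.modified,
            "comments": list(self.comments),
            "dbxrefs": list(self.dbxrefs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Transcript":
        return cls(
            id=d["id"],
            seqid=d["seqid"],
            strand=d["strand"],
            exons=[Exon.from_dict(e) for e in d["exons"]],
            cds=tuple(d["cds"]) if d.get("cds") else None,
            cds_partial=d.get("cds_partial", False),
            manual_start=d.get("manual_start"),
            owner=d.get("owner", "anonymous"),
            created=d.get("created", ""),
            modified=d.get("modified", ""),
            comments=list(d.get("comments", [])),
            dbxrefs=list(d.get("dbxrefs", [])),
        )


@dataclass
class Gene:
    """A non-empty group of same-strand transcripts (isoforms)."""

    id: str
    seqid: str
    strand: int
    transcripts: list[Transcript] = field(default_factory=list)
    name: str = ""
    comments: list[str] = field(default_factory=list)
    dbxrefs: list[str] = field(default_factory=list)

    def span(self) -> tuple[int, int]:
        spans = [t.span() for t in self.transcripts]
        return (min(s for s, _ in spans), max(e for _, e in spans))

    def transcript_by_id(self, tx_id: str) -> Transcript:
        for t in self.transcripts:
            if t.id == tx_id:
                return t
        raise ConflictError(f"gene {self.id}: no transcript {tx_id!r}")

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "seqid": self.seqid,
            "strand": self.strand,
            "transcripts": [t.to_dict() for t in sorted(
                self.transcripts, key=lambda t: (t.span()[0], t.id))],
            "name": self.name,
            "comments": list(self.comments),
            "dbxrefs": list(self.dbxrefs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Gene":
        return cls(
            id=d["id"],
            seqid=d["seqid"],
            strand=d["strand"],
            transcripts=[Transcript.from_dict(t) for t in d["transcripts"]],
            name=d.get("name", ""),
            comments=list(d.get("comments", [])),
            dbxrefs=list(d.get("dbxrefs", [])),
        )


@dataclass
class QCReport:
    """Advisory per-transcript quality flags.

    A junction is listed iff its donor dinucleotide is not ``GT`` or its
    acceptor is not ``AG``, read on the transcript strand of the virtual
    sequence.  Flags never block edits: curators must be able to keep
    non-canonical models.
    """

    transcript_id: str
    noncanonical_junctions: list[tuple[int, str, str]] = field(default_factory=list)
    missing_start: bool = False
    partial_cds: bool = False

    @property
    def clean(self) -> bool:
        return (not self.noncanonical_junctions
                and not self.missing_start and not self.partial_cds)


def span(feature) -> tuple[int, int]:
    """Minimal half-open interval covering a Gene's or Transcript's children."""
    return feature.span()


def validate(gene: Gene, ref: ReferenceSequence) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the gene is well-formed.  Engine operations
    guarantee this holds after every successful edit (cascade closure).
    """
    violations: list[str] = []
    if not gene.transcripts:
        violations.append(f"gene {gene.id}: has zero transcripts")
        return violations
    if gene.strand not in (+1, -1):
        violations.append(f"gene {gene.id}: strand must be +1 or -1")
    for t in gene.transcripts:
        if t.strand != gene.strand:
            violations.append(
                f"transcript {t.id}: strand {t.strand} differs from "
                f"gene {gene.id} strand {gene.strand}")
        if t.seqid != gene.seqid:
            violations.append(
                f"transcript {t.id}: scaffold {t.seqid!r} differs from "
                f"gene {gene.id} scaffold {gene.seqid!r}")
        if not t.exons:
            violations.append(f"transcript {t.id}: has zero exons")
            continue
        exons = t.sorted_exons()
        for e in exons:
            if not (0 <= e.start < e.end <= ref.length):
                violations.append(
                    f"exon {e.id}: interval [{e.start},{e.end}) outside "
                    f"reference {ref.id} of length {ref.length}")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                violations.append(
                    f"transcript {t.id}: exons {a.id} [{a.start},{a.end}) and "
                    f"{b.id} [{b.start},{b.end}) overlap")
            elif b.start == a.end:
                violations.append(
                    f"transcript {t.id}: exons {a.id} and {b.id} abut with "
                    f"no intronic base between them")
        if t.cds is not None:
            cs, ce = t.cds
            if not (cs < ce):
                violations.append(f"transcript {t.id}: empty CDS [{cs},{ce})")
            else:
                ts, te = t.span()
                if cs < ts or ce > te:
                    violations.append(
                        f"transcript {t.id}: CDS [{cs},{ce}) outside "
                        f"transcript span [{ts},{te})")
                # every CDS endpoint base must fall in an exon
                if not _covered(cs, exons) or not _covered(ce - 1, exons):
                    violations.append(
                        f"transcript {t.id}: CDS outside exons "
                        f"([{cs},{ce}) endpoint in an intron)")
    return violations


def _covered(pos: int, exons: Iterable[Exon]) -> bool:
    return any(e.start <= pos < e.end for e in exons)


def validate_all(genes: Iterable[Gene], refs: dict[str, ReferenceSequence]) -> list[str]:
    out: list[str] = []
    for g in genes:
        if g.seqid not in refs:
            out.append(f"gene {g.id}: unknown scaffold {g.seqid!r}")
            continue
        out.extend(validate(g, refs[g.seqid]))
    return out
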