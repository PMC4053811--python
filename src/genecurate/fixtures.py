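"""Synthetic-data generator: reference scaffolds with planted gene models,
perturbed MAKER-style "prediction" evidence tracks, and a ready-made
assembly-error scenario — so the whole engine is testable without
downloading anything.

Planted genes are clean by construction: GT..AG introns, an ATG-initiated
stop-terminated CDS covering most of the spliced transcript, and no other
ATG anywhere in the mRNA, which makes the longest-ORF search provably
recover exactly the planted CDS.  Evidence features are copies of the
truth with controlled damage (boundary jitter, dropped exons, fused
neighbouring genes, frame-breaking one-base boundary shifts), emulating
the disagreement between gene predictors on a real assembly.

The ``assembly_error_scenario`` bundle reproduces the classic curation
narrative on a fragmented NGS assembly: a mis-called base corrupts a
splice donor (flagged non-canonical); a substitution alteration corrects
it (flag clears); an insertion alteration inside the coding region
frameshifts the CDS into a premature stop (CDS truncates); a compensating
deletion restores the frame (truncation reverses).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .alterations import SequenceAlteration
from .io_formats import (
    EvidenceFeature,
    write_evidence_gff3,
    write_fasta,
    write_gff3,
)
from .model import Exon, Gene, ReferenceSequence, Transcript, reverse_complement

FIXTURE_TIME = "2013-01-01T00:00:00Z"
FIXTURE_USER = "fixture"

STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOPS and a + b + c != "ATG")


@dataclass
class FixtureSpec:
    """Knobs of the generator; defaults model a small fragmented assembly
    with a handful of multi-exon genes per scaffold."""

    seed: int = 0
    scaffold_count: int = 2
    genes_per_scaffold: int = 3
    exons_per_gene: tuple[int, int] = (2, 5)
    intron_length: tuple[int, int] = (20, 60)
    utr_length: tuple[int, int] = (5, 20)
    codons: tuple[int, int] = (40, 90)
    minus_strand_prob: float = 0.4
    intergenic: tuple[int, int] = (50, 150)
    # perturbation menu (per evidence transcript)
    jitter_prob: float = 0.5
    jitter_max: int = 5
    exon_drop_prob: float = 0.25
    fusion_prob: float = 0.15
    frame_indel_prob: float = 0.2

    def __post_init__(self) -> None:
        if self.intron_length[0] < 4:
            raise ValueError("introns must be >= 4 bases to hold GT..AG")


@dataclass
class PerturbedEvidence:
    """One evidence feature plus bookkeeping of which truth edges survive."""

    feature: EvidenceFeature
    source_tx: str
    kept_edges: set[int] = field(default_factory=set)
    moved_edges: set[int] = field(default_factory=set)
    perturbations: list[str] = field(default_factory=list)


@dataclass
class Scenario:
    """The four-panel assembly-error bundle on its own scaffold."""

    ref: ReferenceSequence
    gene: Gene
    substitution: SequenceAlteration   # corrects the corrupted donor
    insertion: SequenceAlteration      # frameshift -> premature stop
    deletion: SequenceAlteration       # compensating, restores the frame
    script: list[str] = field(default_factory=list)


@dataclass
class Fixture:
    spec: FixtureSpec
    refs: dict[str, ReferenceSequence]
    truth: list[Gene]
    evidence: list[PerturbedEvidence]
    scenario: Scenario

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.refs, outdir / "reference.fa")
        write_gff3(self.truth, [], self.refs, outdir / "truth.gff3")
        write_evidence_gff3([p.feature for p in self.evidence], self.refs,
                            outdir / "evidence.gff3")
        write_fasta({self.scenario.ref.id: self.scenario.ref},
                    outdir / "scenario.fa")
        write_gff3([self.scenario.gene], [],
                   {self.scenario.ref.id: self.scenario.ref},
                   outdir / "scenario.gff3")
        (outdir / "scenario.script").write_text(
            "\n".join(self.scenario.script) + "\n")


# ---------------------------------------------------------------------------
# clean gene construction
# ---------------------------------------------------------------------------

def _constrained_base(rng: random.Random, tail: str) -> str:
    """Random base that never completes an ATG trigram with the running
    2-base tail — the single-ATG guarantee of planted transcripts."""
    choices = "ACGT" if tail != "AT" else "ACT"
    return rng.choice(choices)


def _constrained_run(rng: random.Random, n: int, tail: str) -> str:
    out = []
    for _ in range(n):
        b = _constrained_base(rng, tail)
        out.append(b)
        tail = (tail + b)[-2:]
    return "".join(out)


def _sense_codon(rng: random.Random, tail: str) -> str:
    while True:
        codon = rng.choice(_SENSE_CODONS)
        window = tail + codon
        if "ATG" not in window:
            return codon


@dataclass
class _PlantedGene:
    region: str                      # plus-strand genomic region sequence
    exons: list[tuple[int, int]]     # region-local, plus-strand coords
    cds: tuple[int, int]             # region-local planted CDS interval
    strand: int


def _plant_gene(rng: random.Random, spec: FixtureSpec) -> _PlantedGene:
    u5 = rng.randint(*spec.utr_length)
    u3 = rng.randint(*spec.utr_length)
    ncod = rng.randint(*spec.codons)
    mrna = _constrained_run(rng, u5, "NN")
    mrna += "ATG"
    for _ in range(ncod):
        mrna += _sense_codon(rng, mrna[-2:])
    stop = rng.choice(STOPS)
    while "ATG" in mrna[-2:] + stop:
        stop = rng.choice(STOPS)
    mrna += stop
    mrna += _constrained_run(rng, u3, mrna[-2:])
    cds_m = (u5, u5 + 3 * ncod + 6)  # ATG .. stop inclusive, mRNA offsets

    n_exons = rng.randint(*spec.exons_per_gene)
    n_exons = min(n_exons, max(1, len(mrna) // 12))
    cuts = sorted(rng.sample(range(8, len(mrna) - 8), n_exons - 1)) \
        if n_exons > 1 else []
    while any(b - a < 8 for a, b in zip([0] + cuts, cuts + [len(mrna)])):
        cuts = sorted(rng.sample(range(8, len(mrna) - 8), n_exons - 1))
    pieces = [mrna[a:b] for a, b in zip([0] + cuts, cuts + [len(mrna)])]

    region_parts: list[str] = []
    exons: list[tuple[int, int]] = []
    pos = 0
    for i, piece in enumerate(pieces):
        exons.append((pos, pos + len(piece)))
        region_parts.append(piece)
        pos += len(piece)
        if i < len(pieces) - 1:
            ilen = rng.randint(*spec.intron_length)
            intron = "GT" + "".join(rng.choice("ACGT")
                                    for _ in range(ilen - 4)) + "AG"
            region_parts.append(intron)
            pos += ilen
    region = "".join(region_parts)

    cds_g = (_mrna_to_region(cds_m[0], exons),
             _mrna_to_region(cds_m[1] - 1, exons) + 1)
    strand = -1 if rng.random() < spec.minus_strand_prob else +1
    if strand == -1:
        n = len(region)
        region = reverse_complement(region)
        exons = sorted((n - e, n - s) for s, e in exons)
        cds_g = (n - cds_g[1], n - cds_g[0])
    return _PlantedGene(region, exons, cds_g, strand)


def _mrna_to_region(offset: int, exons: list[tuple[int, int]]) -> int:
    walked = 0
    for s, e in exons:
        if offset < walked + (e - s):
            return s + (offset - walked)
        walked += e - s
    raise ValueError(f"mRNA offset {offset} beyond exons")


# ---------------------------------------------------------------------------
# evidence perturbation
# ---------------------------------------------------------------------------

def _all_edges(exons: list[tuple[int, int]]) -> set[int]:
    return {c for s, e in exons for c in (s, e)}


def _perturb(rng: random.Random, spec: FixtureSpec, t: Transcript,
             reflen: int, neighbour: Transcript | None) -> PerturbedEvidence:
    exons = [(e.start, e.end) for e in t.sorted_exons()]
    truth_edges = _all_edges(exons)
    moved: set[int] = set()
    applied: list[str] = []

    if len(exons) >= 3 and rng.random() < spec.exon_drop_prob:
        drop = rng.randrange(1, len(exons) - 1)
        exons.pop(drop)
        applied.append("exon_drop")

    def shift_edge(max_shift: int, label: str) -> None:
        i = rng.randrange(len(exons))
        side = rng.choice((0, 1))
        delta = rng.choice([d for d in range(-max_shift, max_shift + 1) if d])
        s, e = exons[i]
        ns, ne = (s + delta, e) if side == 0 else (s, e + delta)
        if ns < 0 or ne > reflen or ne - ns < 2:
            return
        prev_e = exons[i - 1][1] if i > 0 else -1
        next_s = exons[i + 1][0] if i + 1 < len(exons) else reflen + 2
        if ns <= prev_e or ne >= next_s:
            return
        moved.add(s if side == 0 else e)
        exons[i] = (ns, ne)
        applied.append(label)

    if rng.random() < spec.jitter_prob:
        shift_edge(spec.jitter_max, "jitter")
    if rng.random() < spec.frame_indel_prob:
        shift_edge(1, "frame_indel")

    if neighbour is not None and rng.random() < spec.fusion_prob:
        exons = sorted(set(exons)
                       | {(e.start, e.end) for e in neighbour.sorted_exons()})
        applied.append("fusion")

    feature = EvidenceFeature(id=f"pred-{t.id}", ftype="match",
                              seqid=t.seqid, strand=t.strand, exons=exons)
    kept = (_all_edges(exons) & truth_edges) - moved
    return PerturbedEvidence(feature=feature, source_tx=t.id,
                             kept_edges=kept, moved_edges=moved,
                             perturbations=applied)


# ---------------------------------------------------------------------------
# the four-panel assembly-error scenario (fixed content, seed-independent)
# ---------------------------------------------------------------------------

def assembly_error_scenario() -> Scenario:
    """Hand-designed two-exon gene with a mis-called donor base.

    Layout on scaffold ``scenario`` (0-based):
    flank [0,10) — exon1 [10,45) — intron [45,63) — exon2 [63,91) —
    flank [91,101).  The intron starts ``GC`` (corrupted donor; acceptor
    ``AG`` is intact).  The spliced mRNA is::

        CCTCC ATG GAG CAT AAC GAA CTG GAC TTC CTC GAA   (exon 1)
        GAT CTC CAC CTT GAA TTC TAA CCTTCTC              (exon 2)

    with the single ATG at mRNA offset 5 and the planted CDS of 51 bases
    (17 codons including the stop).  The rescue substitution writes T
    over the C at reference 46 (donor GC → GT); the insertion of a C
    before reference 21 shifts the frame onto an immediate TAA; deleting
    the base at reference 23 restores the frame and with it the full CDS.
    """
    exon1_mrna = "CCTCC" + "ATGGAGCATAACGAACTGGACTTCCTCGAA"
    exon2_mrna = "GATCTCCACCTTGAATTC" + "TAA" + "CCTTCTC"
    intron = "GC" + "TCTCTCTCTCTCTC" + "AG"
    flank5, flank3 = "CGCGCGCGCG", "CGCGCGCGCG"
    residues = flank5 + exon1_mrna + intron + exon2_mrna + flank3
    ref = ReferenceSequence("scenario", residues)

    e1 = (len(flank5), len(flank5) + len(exon1_mrna))                 # [10,45)
    e2 = (e1[1] + len(intron), e1[1] + len(intron) + len(exon2_mrna))  # [63,91)
    cds = (e1[0] + 5, e2[0] + len("GATCTCCACCTTGAATTC") + 3)           # [15,84)
    tx = Transcript(
        id="scen-mrna", seqid=ref.id, strand=+1,
        exons=[Exon("scen-exon1", *e1), Exon("scen-exon2", *e2)],
        cds=cds, owner=FIXTURE_USER, created=FIXTURE_TIME,
        modified=FIXTURE_TIME)
    gene = Gene(id="scen-gene", seqid=ref.id, strand=+1, transcripts=[tx],
                name="scenario-gene")

    donor_c = e1[1] + 1  # the mis-called C, second intronic base (ref 46)
    substitution = SequenceAlteration("scen-sub", "substitution", ref.id,
                                      donor_c, "T", 1)
    insertion = SequenceAlteration("scen-ins", "insertion", ref.id,
                                   e1[0] + 11, "C", 0)
    deletion = SequenceAlteration("scen-del", "deletion", ref.id,
                                  e1[0] + 13, "", 1)
    script = [
        "qc",
        f"add-alteration substitution {ref.id} {substitution.position} "
        f"--residues {substitution.residues}",
        "qc",
        f"add-alteration insertion {ref.id} {insertion.position} "
        f"--residues {insertion.residues}",
        "qc",
        f"add-alteration deletion {ref.id} {deletion.position} --length 1",
        "qc",
    ]
    return Scenario(ref=ref, gene=gene, substitution=substitution,
                    insertion=insertion, deletion=deletion, script=script)


# ---------------------------------------------------------------------------
# top-level generation
# ---------------------------------------------------------------------------

def generate(spec: FixtureSpec) -> Fixture:
    """Deterministic fixture bundle for a given spec (same seed, same bytes)."""
    rng = random.Random(spec.seed)
    refs: dict[str, ReferenceSequence] = {}
    truth: list[Gene] = []
    for si in range(spec.scaffold_count):
        seqid = f"scf{si + 1}"
        parts: list[str] = []
        pos = 0
        scaffold_genes: list[Gene] = []
        for gi in range(spec.genes_per_scaffold):
            spacer = "".join(rng.choice("ACGT")
                             for _ in range(rng.randint(*spec.intergenic)))
            parts.append(spacer)
            pos += len(spacer)
            planted = _plant_gene(rng, spec)
            gid = f"gene-{seqid}-{gi + 1}"
            tid = f"mrna-{seqid}-{gi + 1}"
            tx = Transcript(
                id=tid, seqid=seqid, strand=planted.strand,
                exons=[Exon(f"{tid}-e{k + 1}", pos + s, pos + e)
                       for k, (s, e) in enumerate(planted.exons)],
                cds=(pos + planted.cds[0], pos + planted.cds[1]),
                owner=FIXTURE_USER, created=FIXTURE_TIME,
                modified=FIXTURE_TIME)
            scaffold_genes.append(Gene(id=gid, seqid=seqid,
                                       strand=planted.strand,
                                       transcripts=[tx]))
            parts.append(planted.region)
            pos += len(planted.region)
        tail = "".join(rng.choice("ACGT")
                       for _ in range(rng.randint(*spec.intergenic)))
        parts.append(tail)
        refs[seqid] = ReferenceSequence(seqid, "".join(parts))
        truth.extend(scaffold_genes)

    evidence: list[PerturbedEvidence] = []
    for g, nxt in zip(truth, truth[1:] + [None]):
        t = g.transcripts[0]
        neighbour = None
        if (nxt is not None and nxt.seqid == g.seqid
                and nxt.strand == g.strand):
            neighbour = nxt.transcripts[0]
        evidence.append(_perturb(rng, spec, t, refs[g.seqid].length,
                                 neighbour))

    return Fixture(spec=spec, refs=refs, truth=truth, evidence=evidence,
                   scenario=assembly_error_scenario())
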