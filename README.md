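# genecurate

A headless, scriptable **gene-model curation engine** for manual genome
annotation. It implements the server-side editing logic that annotation
curators rely on — structural edits to protein-coding gene models with all
their cascading consequences — without any browser or GUI attached, so the
same operations can be driven from Python, from the command line, or from
replayable edit scripts.

Who it is for: annotation teams and tool developers who need deterministic,
testable curation semantics — merge/split/duplicate/delete of transcripts
and exons, boundary dragging, strand flipping, manual translation starts —
where every edit automatically keeps the gene model consistent.

## What the engine computes

**Cascading recomputation.** Every structural edit re-derives the coding
region of each touched transcript. The CDS is the *longest open reading
frame* of the spliced mRNA: scanning 5'→3' in all three forward frames for
ORFs anchored at ATG, the CDS is the longest ATG→stop span (ties broken by
the 5'-most start). A stopless ORF runs to the transcript end and is
flagged `partial`; with no ATG the CDS is unset and `missing_start` is
flagged. A curator can pin the translation start manually; later edits then
re-extend the CDS in frame from that anchor instead of re-running the
search.

**Sequence alterations and the virtual sequence.** Fragmented NGS
assemblies contain base-level errors — indels that disrupt reading frames,
mis-called splice dinucleotides. Curators annotate suspected errors as
*insertion / deletion / substitution* features. These never mutate the
stored reference; instead they define a **virtual sequence** (the
reference with all alterations applied) that is the substrate for every
mRNA, CDS and peptide computation. A substitution that repairs a donor
dinucleotide immediately clears the splice-site warning; an insertion
inside an exon can frameshift the CDS into a premature stop, and a
compensating deletion reverses the truncation.

**Splice-site QC.** For every intron the donor (first two intronic bases)
and acceptor (last two) are read on the transcript strand of the virtual
sequence; any junction that is not GT..AG is flagged. Flags are advisory,
never blocking.

**Isoform policies.** Whether a new transcript joins an existing gene is
decided by a pluggable rule: `no_overlap` (one gene per transcript),
`simple_overlap` (span overlap on the same strand), or `orf_overlap`
(coding regions share ≥1 base at the same codon phase on the same strand).

**Serialized edits, undo/redo, journal.** Edit requests are applied one at
a time in arrival order. Each request is atomic — a conflicting request
(e.g. a boundary change on an exon another user just deleted) leaves the
annotation set byte-identical — and each success records exactly one
history entry covering the whole cascade. The history supports undo, redo,
point-in-time reconstruction, and persists to a newline-delimited JSON
journal that survives crashes.

**I/O.** FASTA references in; GFF3 annotations, evidence and alterations
in/out (deterministic, byte-reproducible exports); BED6/BED12 evidence in;
per-transcript FASTA exports (genomic / cDNA / CDS / peptide) computed
through the virtual layer.

## Worked example

A 30-base scaffold with a two-exon gene (exons `[0,9)` and `[17,26)`, a
canonical `GTAAGTAG` intron between them):

```python
from genecurate import AnnotationEngine, ReferenceSequence

ref = ReferenceSequence("chr", "ATGGCCAAAGTAAGTAGGGGTTTTAACGCG")
eng = AnnotationEngine({"chr": ref}, policy="simple_overlap")
eng.perform("create_transcript_from_evidence", seqid="chr", strand=+1,
            exons=[(0, 9), (17, 26)])
t = eng.transcripts()[0]
print(eng.mrna(t))       # ATGGCCAAAGGGTTTTAA
print(t.cds)             # (0, 26)
print(eng.qc(t).clean)   # True
```

The spliced mRNA is `ATGGCCAAAGGGTTTTAA`; the longest ORF covers it
entirely (`ATG GCC AAA GGG TTT TAA`), so the CDS spans reference
coordinates `(0, 26)` and the peptide export is `MAKGF` — methionine
through phenylalanine, with the stop codon excluded.

The same session from the shell:

```sh
genecurate init --ref genome.fa --policy simple_overlap
genecurate add-transcript chr + 0-9,17-26
genecurate export fasta peptides.fa --kind peptide
genecurate undo
```

Every mutating verb appends to the session journal; `genecurate history`
lists each edit with its operation, user and date, and `undo`/`redo` walk
the log. `genecurate replay script.txt` re-runs a recorded edit script
byte-reproducibly (use `--clock` to fix timestamps).

## Synthetic fixtures

`genecurate.generate(FixtureSpec(seed=...))` builds a deterministic bundle:
reference scaffolds with planted multi-exon genes (clean GT..AG introns,
unique longest ORF by construction), perturbed prediction tracks
(boundary jitter, dropped exons, gene fusions, frame-breaking shifts), and
a scripted assembly-error scenario whose corrupted donor is rescued by a
substitution and whose CDS is truncated and restored by an
insertion/deletion pair.

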