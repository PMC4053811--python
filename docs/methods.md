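# Methods

This note documents the models, conventions and numerical choices behind
genecurate, and what the synthetic fixtures do and do not demonstrate.

## Coordinate model

All internal coordinates are 0-based half-open intervals on an immutable
reference scaffold; GFF3 I/O converts to/from the 1-based closed external
convention, and BED is consumed as-is (already 0-based half-open). Strand
is a property of transcripts and genes; exons carry no strand, so flipping
a transcript never rewrites exon coordinates. Structural invariants
(exons sorted, non-overlapping, separated by ≥1 intronic base; CDS inside
the exon union; genes non-empty and strand-homogeneous) are enforced after
every engine operation: a request whose cascade would violate them is
rolled back.

Introns of any length ≥1 are legal; introns shorter than 4 bases cannot
contain a GT..AG pair and are therefore flagged by QC rather than
forbidden — curators must be able to represent what an assembly actually
shows.

## The alteration layer

Sequence alterations (insertion, deletion, substitution) are annotations
in reference coordinates; the reference string itself is never modified,
so alterations can later be folded into a re-assembly without touching the
gene models. The set must be pairwise non-overlapping; overlapping
alterations are rejected rather than merged, because merge semantics would
be lossy and untestable. Two insertions at one anchor conflict, as does an
insertion strictly inside another alteration's span (inserting into a
deleted region has no defined meaning); insertions at span boundaries are
allowed.

Anchoring: an insertion at position *p* inserts immediately before base
*p*. Consequently an insertion at an exon's start coordinate is included
in the spliced transcript and one at its end coordinate is excluded,
mirroring the half-open convention. When an insertion and another
alteration share a coordinate, the insertion applies first (it precedes
the base it anchors on). `map_ref_to_virtual` reports the physical
position of each surviving reference base in the virtual string —
an insertion anchored exactly at a base shifts that base right — and
returns "deleted" for bases removed by a deletion; restricted to surviving
bases the mapping is strictly increasing.

All sequence extraction (genomic span, spliced mRNA, CDS, peptide) reads
the virtual sequence. Features themselves remain addressed in reference
coordinates at all times; this keeps the durable coordinate frame stable
under alteration edits. An alteration anywhere on a scaffold triggers CDS
recomputation for that scaffold's transcripts (an intronic alteration can
change splice dinucleotides, so restricting the cascade to exon-overlapping
transcripts would under-invalidate); the recomputation is cheap because
annotation sets are curated regions, not whole genomes.

## ORF and QC rules

The CDS of a transcript without a pinned start is the longest
ATG-anchored ORF over the three forward frames of the spliced mRNA, the
stop codon included in the span; ties go to the 5'-most start. If no
in-frame stop precedes the transcript end the CDS extends to the end and
is flagged partial; with no ATG the CDS is unset and missing-start is
flagged. Codons containing N translate to X (assembly gaps are legal
residues); translation stops at the first stop codon, and a trailing
partial codon is ignored. Six-frame translation is display-oriented:
stops render as `*` with no early termination.

A manually set translation start is stored as a genomic position and
pinned across structural edits: the CDS re-extends in frame from the
anchor to the first stop. If an edit removes the anchored position from
the transcript (e.g. the containing exon is deleted), the anchor is
dropped and the automatic rule resumes. Strand flips and transcript
merges clear manual starts — after either operation the old anchor's
reading direction or provenance is no longer meaningful, and recomputing
is the least surprising behaviour.

Only GT–AG junctions count as canonical; the minor GC–AG and AT–AC
classes are reported as non-canonical on purpose (the flag is advisory
and curators can keep any model). Donor/acceptor dinucleotides are read
from the virtual sequence on the transcript strand, which is what lets a
substitution alteration clear a flag.

When splitting an exon, the new intron's edges snap within a window of
±10 bases (configurable) to the nearest GT (donor, snapped first) and AG
(acceptor) on the transcript strand of the virtual sequence; ties prefer
the left candidate. If no canonical pair is reachable, a minimal 2-base
intron is cut verbatim at the split point and left for QC to flag. The
window default is a compromise: wide enough to find a plausible site near
a curator's click, narrow enough not to move an edge surprisingly far.

## Isoform policies

`no_overlap` always founds a new gene. `simple_overlap` groups on span
intersection; `orf_overlap` requires ≥1 shared coding base at equal codon
phase. Both overlap policies additionally require equal strand —
antisense transcripts are never isoforms. Codon phase is computed per
transcript from its own CDS start in reference coordinates, which is the
only reading of "same frame" that is well defined across different exon
structures. "Simple overlap" uses *span* overlap (exon-level overlap is a
conceivable variant, left unimplemented). A new transcript joins the
first candidate gene in span order (ties by id); genes are never
auto-merged by assignment — bridging two genes is an explicit curator
merge. Grouping is decided at edit time; switching the active policy does
not regroup existing genes.

Two deliberate asymmetries in re-assignment: after `split_transcript`,
the 5' product keeps the original transcript id and stays in the original
gene (re-evaluating it against a gene it just vacated is ill-defined),
while the 3' product is assigned by the active policy; after
`flip_strand` the transcript is fully re-assigned, since a strand change
always breaks isoform grouping. `split_transcript` recomputes each side's
CDS independently rather than splitting the parent CDS.

## Edits, history, journal

Requests are applied strictly serially. Atomicity is implemented with
full-state snapshots (genes, alterations, id counters) taken before and
after each request: a failure restores the pre-image bit-for-bit, and a
success records one history entry holding both images. Snapshots were
chosen over inverse operations because cascades (gene deletion on last
transcript, policy re-assignment) make algebraic inverses error-prone,
and they make undo, redo and "state after edit k" exact constant-time
lookups. Annotation states are small — a curated region, not a genome —
so the memory cost is negligible.

The journal is a versioned, newline-delimited JSON log: header, initial
state, one record per entry, and explicit undo/redo marker records, so
the file is append-only and human-diffable. Replaying the records
reconstructs the history including the undo cursor; a corrupt or
truncated file fails loading with the first bad record named and no
partial state exposed. The log is global per annotation set (cross-feature
cascades cannot be localized per transcript), and undo past another
user's intervening edit is allowed — the log is a single timeline, and a
per-user undo would need merge semantics the data model does not define.

## GFF3 dialect

Output is deterministic: `##gff-version 3`, one `##sequence-region` per
scaffold, then features ordered by (scaffold, start, id) with the
`gene → mRNA → exon/CDS` hierarchy via `Parent`. CDS phase is computed
from the reading frame, never copied from input. One type token (`mRNA`)
is written; both `mRNA` and `transcript` are accepted on input, and
parentless transcript-shaped rows load as read-only evidence. Ownership
and dating use `owner`, `date_creation`, `date_last_modified`; a partial
CDS exports `partial=true`, a pinned start `manual_start`. Alterations
export as top-level `insertion`/`deletion`/`substitution` rows with a
`residues` attribute; a zero-length insertion uses `start == end` with
the site immediately right of that base. These attribute names are this
package's dialect declaration. Reserved characters in attribute values
are percent-encoded. Write→read→write is byte-identical, which the tests
exploit for atomicity and undo checks.

## Synthetic fixtures

The generator emulates a small fragmented assembly: by default two
scaffolds, three planted genes each, 2–5 exons per gene, introns of
20–60 bases, UTRs of 5–20 bases and 40–90 sense codons, with ~40% of
genes on the minus strand and 50–150 bases of intergenic spacer. Planted
transcripts contain exactly one ATG (enforced during construction), no
premature in-frame stop, and a CDS covering well over 60% of the mRNA —
which makes longest-ORF recovery of the planted CDS exact, not merely
likely. Evidence tracks are truth copies with controlled damage at
configurable rates (boundary jitter up to ±5, internal-exon drops,
fusions of neighbouring same-strand genes, one-base frame-breaking
shifts), with bookkeeping of which true edges survive so edge-matching
can be asserted exactly.

The four-panel assembly-error scenario is fixed content rather than
random: a two-exon gene whose intron starts `GC` (mis-called donor), a
substitution writing `T` over that `C` (donor becomes `GT`), an insertion
of `C` inside the coding part of exon 1 that shifts the frame onto an
immediate `TAA`, and a one-base deletion two bases downstream that
restores the frame and the full 51-base CDS. The arithmetic is documented
in `fixtures.assembly_error_scenario`.

What passing on these fixtures does **not** show: performance on
chromosome-scale scaffolds with thousands of genes; robustness to the
messiness of real predictor output (trans-splicing, overlapping
antisense loci, non-coding RNAs are all out of scope); or biological
plausibility of snapped splice sites beyond the GT/AG dinucleotide rule.

## Problem sizes

The test suite and the reproduction script use the sizes the package's
own guarantees are stated at: 1000 random reference/alteration/transcript
triples for the virtual-sequence oracle sweep, 200 random 300-base
sequences (plus every generated fixture transcript, plus exhaustive
enumeration over the reduced alphabet {A,T,G} up to length 9) for the
ORF oracle, 200 random edit scripts of 5–50 operations for closure and
atomicity, 300 random transcript pairs per policy property, and 20-edit
sessions for journal recovery. All are chosen so a full run completes in
seconds on one CPU while still exercising every operation and cascade
path.
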