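# Methods

## Problem setting

RNA-seq quantification presumes that mapped read pairs can be assigned to
gene features. On a fragmented draft genome two failure modes break this
assumption: gene sequence that is absent from the assembly (gaps, missing
chromosomes) cannot be mapped at all, and genes whose parts sit on
different sequences (an ordered chromosome plus unplaced contigs) produce
chimeric read pairs that standard counters discard. `txrecon` implements
the post-processing that reconciles a genome-guided gene model with a de
novo transcriptome assembly: de novo contigs vouch for gene parts the
genome lacks or scatters, novel sequence is collected into an artificial
chromosome, and counting is made strand-aware and chimeric-tolerant.

## Coordinate conventions

All interchange formats (GTF, SAM, 12-column tabular alignment hits) are
1-based inclusive on disk. Internally every interval is 0-based half-open;
the conversion `(start, end) -> (start - 1, end)` happens only in
`io_formats`, so there is a single place to audit off-by-one errors.
Tabular hits with a descending subject range are normalised to
`(min, max)` plus an explicit minus strand at parse time; all downstream
interval algebra assumes `start < end`.

## Read QC

A pair is kept only when both mates have median Phred quality ≥ 28
(median of an even-length list is the mean of the two central values, so
the gate is evaluated on half-integers; a median of exactly 28 passes —
"lower than 28" is read strictly). Filtering is pair-level because the
downstream assembler consumes complete pairs. Phred+33 encoding is
assumed.

## Annotation merging

Two genes are identical when they share sequence and strand and their
transcripts' intron chains match exactly as multisets; single-exon
transcripts match by ≥ 1 bp exon overlap. Identical genes are kept once.
Overlapping-but-different genes ("discordant": ≥ 1 bp exonic overlap on
the same strand) are resolved by the larger total exonic length — the
computable proxy for coverage that needs no read data; read-level coverage
would be an alternative reading, and the decision log makes every
resolution auditable. Ties keep the first annotation's gene, for
determinism.

## Contig assignment and novel-region extraction

Hits of one contig against the gene candidates are processed in
descending bitscore order (ties: ascending e-value, then subject id) — the
order is fixed for determinism. A hit is accepted when its identity is
strictly above 90% and it contributes at least 40 bp of the contig not
covered by previously accepted hits. Novelty is measured on the contig
(query) axis by default; the `axis` parameter switches to the candidate
axis, since the underlying prose is ambiguous. Note that with overlapping
hits the sequential rule is not globally monotone in its thresholds: a
tighter novelty minimum can reject an early hit, freeing coverage that
admits a different later hit. Acceptance is monotone per hit, and exactly
monotone when hits do not overlap.

Uncovered regions of assigned contigs are the maximal complement runs of
the coverage map, kept when ≥ 400 bp; runs touching the contig ends
qualify. Ambiguous bases (N) inside a run do not count toward its length,
so gap filler cannot pose as novel transcript sequence. Contigs with no
accepted hits at all are retained whole when ≥ 400 bp.

Genomically placed contigs are classified relative to a candidate's exon
chain: strictly between two consecutive features = missed internal exon;
within `vicinity_bp` upstream/downstream of the terminal feature
(strand-aware) = 5′/3′ extension; otherwise unplaced. `vicinity_bp`
defaults to 10 kb — wide enough for typical UTR distances without crossing
neighbouring toy genes; it is a config parameter, as "vicinity" is
inherently a tuning choice.

## Consensus (superTranscript) construction

Shared blocks between the running consensus and an isoform are ungapped
plus-strand local matches found per diagonal: maximal exact runs, plus
extensions that cross a gap of g mismatches only when the exact runs on
*both* sides are ≥ 5 bp and > 3·g bp. This anchored-extension rule mimics
X-drop extension but cannot glue a long genuine block to chance
micro-matches in unrelated sequence — plain "merge while identity ≥ 90%"
was observed to weld two different first exons together through a shared
core. Candidate blocks are selected greedily by descending length (ties:
leftmost on the consensus); a candidate overlapping an accepted block is
trimmed back rather than discarded, because chance 1–2 bp extensions
past exon boundaries would otherwise knock out the neighbouring block
entirely.

Folding starts from the longest isoform (ties: lexicographic id) and
proceeds in descending length. The largest colinear chain of blocks is
kept (weighted longest-increasing-subsequence; non-colinear blocks are
dropped with a warning — ungapped merging cannot represent
rearrangements, and a logged drop beats silent misassembly). Isoform
segments outside the chain are inserted: a leading segment is prepended,
an inter-block segment goes immediately before the next block, a trailing
segment is appended. An isoform with no shared blocks is appended whole:
sequence specific to a single transcript is deliberately retained.
`shared_blocks` itself accepts blocks from 1 bp (`min_block=1`), but
folding uses a 20 bp floor to keep word-size-scale chance matches from
steering the merge; both are parameters.

Provenance is maintained as an ordered tiling of the consensus
(contributing isoform + isoform interval per segment); after folding,
every input isoform is re-aligned to the final consensus so that each
isoform's block map on the finished sequence is recorded.

The artificial chromosome concatenates retained sequences separated by
250 bp of N — the footprint of one read pair (50 bp + 150 bp insert +
50 bp), so no pair can bridge two neighbouring entries — and emits one
single-exon feature per entry.

## Annotation cascade

Nucleotide tier: a subject gene qualifies when its best hit passes the
taxon threshold (same-species identity strictly > 90%; related-species
identity ≥ 75% — the inclusive/strict asymmetry follows the rule's
wording) and the union of its hits covers ≥ 50% of both the candidate and
the subject ("bidirectional"). Best total bitscore wins; two or more
surviving names raise a discordance flag (chimeric/fused candidates,
queued for review). Protein tier (for candidates the nucleotide tier left
unnamed): homology ≥ 30% (read as the positives fraction of the protein
alignment) and candidate coverage ≥ 50%; accessions map to gene names
through a static table, unmapped accessions warn and are skipped.

ORFs are scanned in the three forward frames only (stranded library). Per
stop-free codon segment one maximal ORF is reported: from the 5′ edge
when no stop precedes the segment, else from the first ATG; a segment
with neither an ATG nor a terminating stop is not an ORF. Lengths count
codons excluding the stop. The biotype cascade is total and
order-independent: miscellaneous (named, name matches the configurable
rRNA/spliceosomal/pseudogene keyword list) → named protein-coding →
putative protein (unnamed, longest ORF ≥ 100 aa, any of domain / signal
peptide / transmembrane evidence) → uncharacterized protein (ORF but no
evidence) → ncRNA. When several ORFs pass the threshold the longest is
used.

Reference comparison: union length-coverage of each candidate by
reference-gene hits, binned at zero / below 50% / at least 50%; name
concordance restricted to hits covering ≥ 50% of the candidate, decided
by the best-bitscore qualifying hit (case-insensitive, synonym table
applied), with `matched_undefined` for reference loci without a symbol.

## Fragment counting

The transcript strand of a pair follows fr-firststrand chemistry from the
FLAG fields: first-in-pair reverse ⇒ plus, first-in-pair forward ⇒ minus,
both mates same orientation ⇒ undetermined. Plus-partition fragments are
matched to plus-strand features directly — the chemistry is encoded once
in `fragment_strand` rather than stacking a second inversion on top of a
reverse-stranded counter; a fixture test asserts the equivalence on
simulated data. A pair is counted for gene G when both mates overlap
(≥ 1 bp, CIGAR-aware with N gaps excluded; `[pos, pos+50)` when no CIGAR)
exon features of G on the right strand — including mates on different
sequences when both belong to G. Pairs overlapping two or more genes are
ambiguous; chimeric pairs with no common gene are `chimeric_unresolved`
and never counted; duplicates (0x400) and multi-mapped pairs (0x100) are
excluded, the latter because the consensus builder exists precisely to
remove the redundancy that creates them. Each mapped pair receives
exactly one label, so the label counts partition the mapped pairs; the
summary reports mapped and assigned as shares of all pairs, not-assigned
as a share of mapped pairs, and the no-feature share among unassigned.

## Synthetic data

The generator emulates the study design at toy scale: 2 ordered
chromosomes and 4 unplaced contigs; 12 genes of 3–6 exons (200–400 bp)
with 100–300 bp introns and N-gap interludes; 1–3 isoforms per gene;
strand-specific 50-bp read pairs with a fixed 150-bp insert
(fr-firststrand; the insert is fixed at the mean, variance would add
nothing at this scale); mate qualities from a two-component model
(Phred 38 ± 2 vs 24 ± 2, 5% low) so the QC gate has work on both sides
of 28. A quarter of genes are fragmented (split to a contig, a second
chromosome, or two contigs); a fifth have a terminal exon run ≥ ~400 bp
— or the whole gene — absent from the genome and present only in the
transcripts. All generators are pure functions of (config, seed).

Isoform structure is constrained so the exon-block oracle is exact:
terminal exons are common to all isoforms, and each internal exon is
common, skipped by exactly one isoform, or private to exactly one
isoform, with no two private exons adjacent. Under these rules pairwise
ungapped folding provably reconstructs the full exon chain in order;
arbitrary isoform nestings can make the inter-block insertion order
ambiguous for any pairwise merger, so passing tests demonstrate
correctness of the folding machinery, not resolution of inherently
ambiguous splice architectures.

Read mapping for counting fixtures is alignment-free conversion from
simulation truth: mates inside visible exons get genomic positions with
spliced M/N CIGARs; mates whose sequence is genome-absent are located by
exact search in the artificial chromosome; mates straddling a
visible/hidden boundary or two sequences are emitted unmapped. All toy
genes sit on the plus strand — minus-strand feature handling is exercised
by unit fixtures instead. The toy aligner reports exact ungapped
plus-strand matches only (seed-and-extend, 100% identity); it stands in
for an external search tool on sequences where exactness is the truth,
not an approximation of one.

What the toy world does not model: sequencing errors, expression-level
variation, repeats and paralogy, junction-limited mappability of the
genome arm (toy "genome mapping" is spliced truth placement), and real
intron/UTR length distributions. Passing tests therefore validate the
bookkeeping and decision rules, not robustness to noisy alignments.

## Problem sizes and determinism

The end-to-end pipeline runs on 12 genes and 1000 read pairs (about
600–800 mapped), chosen so the whole suite and the acceptance script each
finish in seconds on one CPU while every fragmentation class, biotype and
chimeric-rescue path is exercised. Every random draw flows from a single
integer seed; the acceptance script derives all seeds from `--seed`.

## Known limitations

- Discordant-gene resolution uses exonic length, not read coverage; with
  read data available the choice could differ.
- The consensus builder cannot represent rearranged or antisense isoform
  structure (ungapped, plus-strand only, colinear chains); such blocks are
  dropped with a warning.
- Multi-mapped pairs are excluded rather than fractionally assigned.
- `read_sam_min` requires SAM headers (@SQ) and primary alignments; BAM
  is out of scope.
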