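# Methods

## The problem

Droplet-based single-cell RNA-seq (10x 3' gene expression) captures
transcripts through their polyA tails, so nearly all reads pile up at
the 3' end of each gene.  When a genome's 3'-UTR annotations are
incomplete, those reads fall outside every annotated gene model and are
discarded during counting, deflating or erasing the measured expression
of affected genes.  Full-length single-cell isoform sequencing
(ScISOr-Seq) — long-read sequencing of the same 10x-barcoded cDNA —
observes each transcript end to end and can therefore be used to rebuild
gene models with correct 3' ends.  `isoannot` implements that rebuild as
a testable pipeline over five stages plus a synthetic-data generator.

## Coordinate model

All in-memory coordinates are 0-based half-open in genomic ascending
order; strand is interpreted only where 5'/3' semantics matter
(donor/acceptor sites, TSS/TTS, polyA windows, end shifts).  On-disk
conventions (GTF 1-based inclusive; BED12 half-open with block offsets)
are converted exclusively in `io_formats`, so there is exactly one place
an off-by-one can live.  Writers order records deterministically
(chrom, gene start, gene id, transcript start, transcript id, exon
start) to make repeated writes byte-identical.

## Read resolution

A sense-orientation full-length read is

    [sample barcode] p5 | cDNA | polyA | rc(UMI) | rc(CB) | rc(p3) [rc(sample barcode)]

with the 10x 3' GEX v3.1 defaults: CB 16 nt, UMI 12 nt,
p5 `CCCATGTACTCTGCGTTGATACCACTGCTT`, p3 `CTACACGACGCTCTTCCGATCT`,
sample barcode `ATATAGCGCGCGTGTG`.  Primers and the sample barcode are
located by semi-global edit distance (edlib, mode HW), defaults 3 edits
for primers and 2 for the sample barcode — tolerant enough for
circular-consensus error profiles while keeping false hits negligible.
Searches are confined to terminal windows (primer length plus the
CB/UMI block plus sample-barcode slack): adapters are ligated at the
ends, and an unanchored interior search of a 22-mer at ≤3 edits would
produce occasional chance hits on kilobase-scale cDNA that masquerade
as construct structure.  `locate_primer` itself remains a whole-sequence
search and is tested against a brute-force dynamic-programming oracle.

Orientation is decided by testing both strands for the full
primer pattern; a read matching fully in both orientations is a
palindromic artifact and is rejected.  Reads are categorised
FULL_LENGTH / MISSING_5P / MISSING_3P / MISSING_BOTH / NO_POLYA /
TOO_SHORT, with every input read in exactly one category; rejects are
written to their own file.

The polyA tail is the maximal 3'-terminal suffix that begins with an A
and contains at most `max_non_a` (default 2) non-A bases, removed only
when at least `min_polya_len` (default 10) long.  When a transcript's
own 3' end is adenine-rich, those bases are indistinguishable from the
tail; the simulator's truth table therefore records the cDNA *after*
the same trimming rule (`cdna_recoverable`).  This is an
identifiability limit of oligo-dT capture, not an implementation
artifact.

Duplicate removal keys on (cell barcode, UMI) — the UMI semantics of
the 10x construct — keeping the longest cDNA, ties broken by smallest
read id.  No whitelist correction of barcodes is attempted; extraction
operates on the observed sequence.

## Collapse

Aligned reads are filtered on alignment coverage c = aligned query
bases / full query length and identity I = (aligned bases − edit
distance)/aligned bases, with inclusive thresholds c ≥ 0.99 and
I ≥ 0.95.  The edit distance comes from the NM tag (introns excluded),
with an MD-tag fallback; absence of both is an error.  Multi-exon reads
sharing an intron chain (exact by default, `junction_tol` available)
become one model spanning the widest member; mono-exon reads cluster by
single-linkage reciprocal overlap ≥ 0.5.  Ids are `PB.<locus>.<n>`,
assigned in a canonical sort order so results are independent of input
order.  No 5'-degradation merging of shorter chains into longer ones is
performed by default: exact-chain collapse is conservative and exactly
testable.

## Classification

The decision list is FSM > ISM > FUSION > NIC > NNC > INTERGENIC >
GENIC with same-strand gene priority.  FSM requires an identical intron
chain (mono-exon: reciprocal overlap ≥ 0.5 with a mono-exon reference
transcript); subcategories use strand-aware signed end differences with
`end_tol` 50 nt (reference_match / alt_5 / alt_3 / alt_3_and_5).  ISM
requires a consecutive junction sub-chain.  FUSION needs exonic overlap
with ≥ 2 mutually non-overlapping genes.  NIC reuses known donors and
acceptors in a new chain.  An isoform retaining a reference intron (one
exon fully containing it, overlapping both flanking exons) is classified
NNC/intron_retention even when its remaining junctions reuse known
sites: retention removes a junction rather than adding one, but the
resulting transcript is still absent from the catalog, and the category
system places retention inside NNC.

Artifact filters: intra-priming flags a transcript whose 3'-downstream
genomic window (20 nt) is ≥ 60% A on the transcript strand — the
signature of oligo-dT annealing to genomic adenines; RT template
switching flags a junction whose donor-side exonic 8-mer equals the
acceptor's upstream intronic 8-mer (direct repeat).  The default
removal rule drops any flagged transcript, except that FSM transcripts
are exempt from intra-priming removal (they match annotated models, and
removing them would delete genuinely annotated genes); the exemption
can be disabled.

## Merge and comparison

Merging pools transcripts from both sources and re-forms genes as
connected components linked by ≥ 1 nt of same-strand *exonic* overlap
(span overlap alone does not link, so a transcript inside another
gene's intron stays separate).  Deduplication collapses identical exon
chains keeping the reference copy.  Genes containing a reference
transcript adopt its Ensembl id and name — when several Ensembl genes
are present, the one contributing the most exonic overlap wins and the
rest go to a conflict report; isoseq-only genes get `NOVELG_%06d` ids
in (chrom, start) order.  Reference CDS records pass through verbatim;
no CDS is inferred for read-derived transcripts.  Mitochondrial gene
names receive an `MT-` prefix (idempotent).  Note that merging an
annotation with an empty one is the identity only when no two of its
genes overlap exonically on the same strand; real references violating
that are legitimately united.

End-shift comparison is gene-level, strand-aware, signed so that a
3'-UTR extension is positive and an earlier start negative on either
strand; only genes present in both annotations enter the medians
(lower median for even n, keeping summaries deterministic integers).
First/last-exon read counts use the longest transcript's terminal
exons; a read counts once per exon when any aligned block overlaps it.

## Synthetic data

The generator emulates: random genomes at a chosen GC; non-overlapping
gene models on both strands with sampled 3'-UTR lengths (defaults:
1–5 exons of 120–300 nt, introns 80–400 nt, 3'-UTRs 250–500 nt);
barcoded reads assembled exactly per the construct layout with planted
category counts (largest-remainder apportionment, so counts are exact,
not sampled), cell barcodes at pairwise Hamming distance ≥ 4, UMIs
drawn without replacement within a cell, polyA tails uniform 20–60 nt,
and uniform substitution errors; and SAM alignments synthesized
directly from the truth (M blocks split by N introns, NM from planted
errors), bypassing an external aligner.  The error model is
substitution-only so simulated CIGARs stay exact.  It does **not**
model PacBio indel profiles, expression levels, ambient RNA, doublets,
or misalignment — so passing tests demonstrate the correctness of the
pipeline's logic under its stated assumptions, not robustness to every
failure mode of real long-read data.

## Problem sizes and numerics

The bundled checks use 2,000-read batches (50 cells × 40 reads),
25–200-gene annotations on 0.15–0.7 Mb genomes, and 100-case format
round trips — sizes chosen so the full suite completes in seconds while
every comparison remains exact against truth.  Noise tolerance is
assessed at 1% substitution error, where barcode/UMI recovery is
measured against the post-error truth sequences (without whitelist
correction, pre-error recovery is bounded by the chance of an
error-free 28 nt block, ≈ 75% at 1%).  Ties are broken
lexicographically throughout (read ids, transcript ids, leftmost primer
hits) so every stage is deterministic and permutation-invariant.
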