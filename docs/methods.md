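# Methods

This note records the model, the numerical choices, and the limits of the
synthetic benchmark. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Counting and orientation

Counting is an exact in-memory hash count per library. Stranded libraries
follow the convention mate 1 = forward, mate 2 = reverse (overridable per
file); reverse-oriented reads are reverse-complemented before windowing so
k-mers are reported on the transcript strand. Unstranded libraries store
canonical k-mers. Windows overlapping a non-ACGT base are skipped entirely
— no base is ever fabricated — and quality strings are ignored (no
trimming). Only k-mers with at least `min_abundance` (default 2)
occurrences per library are recorded; dropping singletons removes the bulk
of sequencing-error k-mers at almost no cost in signal. Counting is
in-memory only; the intended scale is desk-size experiments and simulated
data, not full human libraries.

Dumps are two-column, strictly lexicographically sorted files, merged by a
single streaming k-way pass whose memory is proportional to the number of
open files. Sortedness is verified during the merge and violations are
reported with file and line.

## Recurrence filter and masking

`recurrence(x, a)` counts samples with strictly more than `a` copies of
`x`. Defaults: `a = 5`, `min_recurrence = min(replicates per condition)`.
The filter is idempotent and row-order preserving.

Masking subtracts the exact k-mer content of a user-supplied transcriptome
FASTA. In stranded mode only the annotated (sense) strand is indexed —
deliberately, so antisense k-mers survive and the asRNA event class can
exist; indexing both strands is the documented alternative and would
suppress it. Masking never edits counts, it only removes rows, and it can
be skipped (`masking: none`), which strictly enlarges the differential
output (verified as an acceptance property).

## Normalization and differential testing

Normalization factors are median-of-ratios against a geometric-mean
pseudo-reference, computed once on a seeded 30 % row subsample of the
**post-recurrence, pre-masking** matrix — computing them after masking
would bias them because masking removes precisely the best-behaved
(reference) k-mers. Rows containing any zero are excluded (their geometric
mean is degenerate), and the NFs are rescaled to geometric mean 1 for
identifiability; neither choice affects ratios between samples.

Two engines, both strictly per k-mer:

* **ttest** — Welch (unequal-variance) two-sample t-test on
  `log2(count/NF + 1)`. Base 2 with pseudocount 1 keeps zeros at zero and
  makes the statistic invariant to jointly rescaling counts and NFs.
* **glm** — negative binomial GLM, `log μ_ij = β₀ᵢ + β₁ᵢ·[j∈B] + log NF_j`,
  Wald test on β₁. The dispersion is chosen per row by maximizing the
  Cox–Reid adjusted profile likelihood on a fixed multiplicative grid
  (10⁻³…5, 17 points) seeded by method of moments; the grid doubles as the
  fallback when no interior optimum exists. The Wald statistic is referred
  to a t distribution with n−2 degrees of freedom. Both corrections are
  small-sample necessities: plain per-row ML dispersion with a normal
  reference is strongly anticonservative at n = 12. Group means are fitted
  by IRLS and floored at half a count over the group's effective library
  size (`0.5/ΣNF`); without this continuity correction an all-zero
  condition — exactly the presence/absence signal the pipeline looks for —
  drives the MLE to the boundary and the Wald statistic to zero. No
  information is shared across k-mers (unlike shrinkage-based tools), so
  chunking the matrix cannot change any p-value; chunk invariance is
  asserted in tests.

Benjamini–Hochberg adjustment is applied once, jointly over all tested
k-mers from all chunks. Under the fixed-seed calibration study (50,000
null NB rows, dispersion 0.1, abundances log-uniform 50–500 — the count
regime the recurrence filter selects for — and 50 fold-8 spikes, 6 vs 6)
the measured operating characteristics are: type-I error ≈ 0.045 (ttest)
and ≈ 0.050 (glm) at α = 0.05; after BH at 0.05, sensitivity 0.90 / 0.98
and observed FDR 0.02 / 0.06; the glm engine is uniformly at least as
powerful as the t-test, which is why it is recommended for small designs.

## Contig extension

Extension runs rounds of unique prefix–suffix merging at overlap lengths
k−1, k−2, …, down to **and including** `min_overlap` (default 15). A pair
merges only when the left contig has exactly one outgoing and the right
exactly one incoming overlap at that length; forks freeze both sides.
Within a round, merging repeats to a fixpoint; chains are walked from
their unique heads in lexicographic order, so output is deterministic.
A cycle at fixed overlap (a perfectly periodic k-mer set, e.g. a tandem
repeat expressed across copy boundaries) is broken at its
lexicographically smallest member with a warning. Contigs inherit
p-values, counts and log2FC from their lowest-p constituent k-mer (ties:
lexicographically smallest); the abundance summary `meanA/meanB` is
instead averaged over *all* constituent k-mers, because the lowest-p
k-mer is not necessarily well covered and the classification rule that
consumes the mean (lincRNA, below) should see the contig, not one k-mer.

Orientation: contigs are built on the strand of the stored k-mers;
reverse-complement overlaps are not chased in unstranded mode.

## Alignment and annotation

Contigs sharing any exact 15-mer with a shipped adapter set (either
strand) are discarded. The built-in aligner is a deliberate desk-scale
replacement for a production short-read aligner: exact 15-mer seeds over
the forward genome, candidate diagonals ranked by seed support, ungapped
extension with terminal soft-clipping, and at most one splice gap
(20–100,000 nt) requiring GT–AG on the aligned strand (CT–AC on the
genome for minus-strand alignments) or an annotated intron. The clipping
window maximizes `aligned − 5·mismatches` under a budget of 3 mismatches
per 31 aligned nt, so mismatch-dense tails (non-genomic polyA) stay
clipped. An alignment is reported when at most 30 nt total are clipped —
large enough that a 15-A tail does not unmap a polyA contig. Best = fewest
mismatches+indels, then least clipping, then unspliced before spliced,
then leftmost; all co-optimal locations are counted as `nb_hits` (cap 50).
External alignments can be ingested from SAM or a simple TSV instead; the
event logic is agnostic to the aligner.

Annotation intersects the alignment *blocks* (gaps excluded) with genes
and exons from GFF3 (converted internally to 0-based half-open). Sense
overlap sets the host gene; opposite-strand-only overlap sets the
antisense flag; in unstranded mode strand is unknown, either-strand
overlap sets the gene and antisense is never raised. `snv` = any
mismatch/indel with unique mapping; `ends_polyA` = 3′ clip ≥ 5 ending in
≥ 5 A, evaluated in contig orientation (also for minus-strand
alignments — a pinned convention).

## Gene expression, DU, and classification

Host-gene expression is the per-sample mean count of the k-mers unique to
a gene's annotated transcripts (k-mers shared by two or more genes are
excluded), taken from the pre-masking matrix and divided by NF; genes with
no unique k-mer are undefined and their DU classes unreachable. Gene DE
uses the same engine as the k-mer stage plus BH, significant at adjusted
p ≤ 0.05. The DU statistic for a genic contig is a Welch t-test on
per-sample `log2((contig/NF + 1)/(gene + 1))`; DU is called at raw
p < 0.01 (no multiplicity adjustment — the DU test is a per-contig
descriptor, not a discovery screen).

Classification applies the first matching rule in a fixed order — DU
variants before parents, specific before generic: splicing(±DU) for
uniquely mapped sense-genic contigs with a junction; polyA(±DU) for
clipped polyA tails; lincRNA for uniquely mapped intergenic contigs
> 200 nt with mean normalized count > 20 in some condition and mapped
span < 10 kb; asRNA for antisense contigs > 200 nt spanning < 10 kb;
SNV_DU additionally requires an exonic variant in a gene that is *not*
differentially expressed; intron(±DU) for junction-free intronic contigs;
repeats for ≥ 5 co-optimal hits and > 50 nt; unmapped for unaligned
contigs > 50 nt; otherwise unclassified. Loci are genes, antisense of
genes, or intervals between flanking genes; each locus reports its contig
count and lowest-adjusted-p contig.

## The simulator, and what passing does not show

The generator emulates a small two-condition experiment: a 100 kb random
genome, 20 non-overlapping genes of 2–4 exons (150–400 nt exons,
100–300 nt introns, GT–AG enforced in transcription orientation, both
strands), a 6-copy intergenic tandem repeat (300 nt unit), one reserved
unannotated intergenic region, 6 replicates per condition, 75 nt
paired-end reads, fragment size 150–250, mean 150 fragments per transcript
with NB dispersion 0.1, and zero sequencing error by default (so
masking-completeness invariants are exact; tests that need errors set the
rate explicitly). One event per class is spiked, expressed only in
condition B, so recovery is presence/absence; the SNV host instead keeps
equal totals in both conditions (2× baseline depth, alleles 100/0 vs
50/50) so the "gene not DE" rule is genuinely exercised — hosts are chosen
among unused genes with the shortest transcripts so spike k-mers clear the
recurrence filter with margin, and the SNV sits mid-exon, more than k from
any junction, so its contig aligns ungapped. Fixed seeds give
byte-identical FASTQ/FASTA/GFF3 output (gzip mtime pinned to 0).

What this does **not** demonstrate: performance on real data with
sequencing errors (error k-mers inflate the matrix and lean on the
recurrence filter), coverage bias, incomplete or wrong annotation,
overlapping genes, multi-isoform hosts, or genome/transcriptome scales
where the in-memory counter and the seed index are inadequate. The
built-in aligner is not a GSNAP/BLAST substitute on real genomes — use
SAM ingestion there. The repeat class is reported without further
subclassification, and allelic balance is not explicitly tested for the
SNV class (the DU test is a proxy).

## Problem sizes used by tests and the acceptance script

Oracle checks run ≥ 100 random small instances per primitive; the
calibration study uses 50,000 null + 50 spiked rows; end-to-end studies
use the default simulator configuration above (≈ 50k read pairs over 12
libraries). The complete test suite runs in well under a minute; the
acceptance script in ≈ 15 s.
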