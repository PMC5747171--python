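"""Event classification: host-gene expression, differential usage, rules.

Intragenic differential contigs may simply track over/under-expression of
their host gene. To separate isoform-level events (differential usage, DU)
from whole-gene differential expression, each gene is quantified from the
k-mers unique to its annotated transcripts (shared k-mers are dropped), a
gene-level DE test is run with the same engine as the k-mer stage, and each
genic contig gets a DU p-value from a Welch t-test on the per-sample
log-ratio of contig count to host-gene expression. Contigs are then
assigned to event classes by a fixed-precedence rule chain (DU variants
before their parents, specific classes before generic ones) and grouped
into loci: a gene, the antisense of a gene, or an intergenic interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from scipy import stats

from .annotate import ContigAnnotation, GenomeAnnotation
from .difftest import bh_adjust, nb_glm_pvalues, ttest_pvalues
from .kmers import KmerParams, UNSTRANDED, canonical
from .matrix import CountMatrix

DU_THRESHOLD = 0.01
GENE_DE_THRESHOLD = 0.05
LINC_MIN_LENGTH = 200
LINC_MIN_MEAN = 20.0
MAX_LOCUS_SPAN = 10_000
MIN_REPEAT_HITS = 5
MIN_UNMAPPED_LENGTH = 50

EVENT_CLASSES = [
    "splicing_DU",
    "splicing",
    "polyA_DU",
    "polyA",
    "lincRNA",
    "asRNA",
    "SNV_DU",
    "intron_DU",
    "intron",
    "repeats",
    "unmapped",
    "unclassified",
]


@dataclass
class GeneExpression:
    gene_id: str
    expression: np.ndarray | None  # normalized per-sample values, or None
    de_pvalue_adj: float | None
    is_de: bool | None


@dataclass
class LocusSummary:
    locus_id: str
    n_contigs: int
    best_contig: ContigAnnotation


def _transcript_gene_map(ann: GenomeAnnotation, db_path: str | Path) -> dict[str, str]:
    import gffutils

    db = gffutils.create_db(
        str(db_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    tx2gene: dict[str, str] = {}
    for ft in ("mRNA", "transcript"):
        try:
            feats = list(db.features_of_type(ft))
        except Exception:
            feats = []
        for f in feats:
            for parent in f.attributes.get("Parent", []):
                if parent in ann.genes:
                    tx2gene[f.id] = parent
    return tx2gene


def gene_expression(
    matrix_prefilter: CountMatrix,
    transcriptome_fasta: str | Path,
    gff3: str | Path,
    nf: dict[str, float],
    params: KmerParams,
    method: str = "ttest",
) -> dict[str, GeneExpression]:
    """Per-gene expression from gene-unique k-mers plus a gene-level DE call.

    Expression for sample j is the mean count over the gene's unique k-mers
    present in the (post-recurrence, pre-masking) matrix, divided by NF_j.
    Genes with no unique k-mer in the matrix have undefined expression and
    is_de = None.
    """
    ann = GenomeAnnotation.from_gff3(gff3)
    tx2gene = _transcript_gene_map(ann, gff3)
    k = params.k
    kmer_gene: dict[str, str | None] = {}
    for rec in SeqIO.parse(str(transcriptome_fasta), "fasta"):
        gene = tx2gene.get(rec.id, rec.id)
        seq = str(rec.seq).upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if params.strand_mode == UNSTRANDED:
                w = canonical(w)
            if w not in kmer_gene:
                kmer_gene[w] = gene
            elif kmer_gene[w] != gene:
                kmer_gene[w] = None  # shared by >= 2 genes
    row_of = {km: i for i, km in enumerate(matrix_prefilter.kmers)}
    gene_rows: dict[str, list[int]] = {}
    for km, gene in kmer_gene.items():
        if gene is None:
            continue
        i = row_of.get(km)
        if i is not None:
            gene_rows.setdefault(gene, []).append(i)
    nfv = np.array([nf[l] for l in matrix_prefilter.library_ids])
    gene_ids = sorted(set(tx2gene.values()) | set(gene_rows))
    raw_means = {}
    out: dict[str, GeneExpression] = {}
    testable: list[str] = []
    for g in gene_ids:
        rows = gene_rows.get(g)
        if not rows:
            out[g] = GeneExpression(g, None, None, None)
            continue
        mean_raw = matrix_prefilter.counts[rows].mean(axis=0)
        raw_means[g] = mean_raw
        testable.append(g)
    if testable:
        raw = np.vstack([raw_means[g] for g in testable])
        ga = matrix_prefilter.group_mask("A")
        gb = matrix_prefilter.group_mask("B")
        if method == "glm":
            p = nb_glm_pvalues(np.round(raw).astype(np.int64), nfv, ga, gb)
        else:
            p = ttest_pvalues(raw, nfv, ga, gb)
        padj = bh_adjust(p)
        for g, pa in zip(testable, padj):
            out[g] = GeneExpression(
                g,
                expression=raw_means[g] / nfv,
                de_pvalue_adj=float(pa),
                is_de=bool(pa <= GENE_DE_THRESHOLD),
            )
    return out


def du_test(
    contig_counts: np.ndarray,
    gene_expr: np.ndarray,
    nf: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
) -> float:
    """Differential-usage p-value: Welch t-test on per-sample
    log2((contig/NF + 1) / (gene + 1)) between conditions."""
    r = np.log2((contig_counts / nf + 1.0) / (gene_expr + 1.0))
    a, b = r[group_a], r[group_b]
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return 1.0 if not np.isfinite(p) else float(p)


def attach_du(
    annotations: Sequence[ContigAnnotation],
    genes: dict[str, GeneExpression],
    nf: dict[str, float],
    library_ids: Sequence[str],
    conditions: Sequence[str],
) -> None:
    """Fill du_pvalue and gene_is_de in place for genic sense contigs."""
    nfv = np.array([nf[l] for l in library_ids])
    conds = np.asarray(conditions)
    ga, gb = conds == "A", conds == "B"
    for a in annotations:
        if a.gene_id is None or a.is_antisense:
            continue
        ge = genes.get(a.gene_id)
        if ge is None or ge.expression is None:
            continue
        a.gene_is_de = ge.is_de
        a.du_pvalue = du_test(
            np.asarray(a.contig.counts, dtype=float), ge.expression, nfv, ga, gb
        )


def classify(a: ContigAnnotation) -> str:
    """Assign one event class by the first matching rule in fixed order."""
    aln = a.alignment
    mapped = aln.is_mapped
    hits1 = mapped and aln.nb_hits == 1
    sense_gene = a.gene_id is not None and not a.is_antisense
    du = a.du_pvalue is not None and a.du_pvalue < DU_THRESHOLD
    length = a.contig_length
    if du and aln.nb_junctions > 0 and sense_gene and hits1:
        return "splicing_DU"
    if aln.nb_junctions > 0 and sense_gene and hits1:
        return "splicing"
    if du and aln.clipped_3p >= 5 and a.ends_polya and hits1:
        return "polyA_DU"
    if aln.clipped_3p >= 5 and a.ends_polya and hits1:
        return "polyA"
    if (
        mapped
        and a.gene_id is None
        and not a.is_antisense
        and hits1
        and length > LINC_MIN_LENGTH
        and max(a.mean_a, a.mean_b) > LINC_MIN_MEAN
        and a.mapped_span < MAX_LOCUS_SPAN
    ):
        return "lincRNA"
    if (
        a.is_antisense
        and hits1
        and length > LINC_MIN_LENGTH
        and a.mapped_span < MAX_LOCUS_SPAN
    ):
        return "asRNA"
    if (
        du
        and sense_gene
        and hits1
        and a.snv
        and a.is_exonic
        and a.gene_is_de is False
    ):
        return "SNV_DU"
    if du and sense_gene and aln.nb_junctions == 0 and a.is_intronic and hits1:
        return "intron_DU"
    if sense_gene and aln.nb_junctions == 0 and a.is_intronic and hits1:
        return "intron"
    if mapped and aln.nb_hits >= MIN_REPEAT_HITS and length > MIN_UNMAPPED_LENGTH:
        return "repeats"
    if not mapped and length > MIN_UNMAPPED_LENGTH:
        return "unmapped"
    return "unclassified"


def group_loci(
    annotations: Sequence[ContigAnnotation], ann: GenomeAnnotation
) -> list[LocusSummary]:
    """Group contigs into gene / antisense-of-gene / intergenic loci."""
    buckets: dict[str, list[ContigAnnotation]] = {}
    gene_lists: dict[str, list] = {}
    for a in annotations:
        if a.gene_id is not None and not a.is_antisense:
            key = a.gene_id
        elif a.gene_id is not None and a.is_antisense:
            key = f"antisense:{a.gene_id}"
        elif a.alignment.is_mapped:
            chrom = a.alignment.chrom
            if chrom not in gene_lists:
                gene_lists[chrom] = ann.genes_by_chrom(chrom)
            genes = gene_lists[chrom]
            left = None
            right = None
            for g in genes:
                if g.end <= a.alignment.start:
                    left = g.gene_id
                if right is None and g.start >= a.alignment.end:
                    right = g.gene_id
            key = f"{chrom}:{left or '.'}|{right or '.'}"
        else:
            key = "unmapped"
        buckets.setdefault(key, []).append(a)
    out = []
    for key in sorted(buckets):
        members = buckets[key]
        best = min(members, key=lambda a: (a.contig.p_adj, a.contig.sequence))
        out.append(LocusSummary(locus_id=key, n_contigs=len(members), best_contig=best))
    return out
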