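"""Genomic annotation of aligned contigs.

A GFF3 annotation (1-based, inclusive) is loaded through gffutils and
converted to 0-based half-open intervals held in per-chromosome interval
trees. For each contig the primary alignment is intersected with genes and
exons to derive the feature vector consumed by the event classifier:
host gene (sense), antisense-only overlap, exonic/intronic flags, the SNV
flag (any mismatch or indel with unique mapping), and the polyA flag
(>= 5 clipped 3' bases ending in five or more A). In unstranded mode the
contig strand is unknown: gene overlap on either strand sets the host gene
and the antisense flag is never raised.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from intervaltree import IntervalTree

from .align import ContigAlignment
from .merge import Contig


@dataclass
class GeneFeature:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)


class GenomeAnnotation:
    """Gene/exon/intron lookup structures built from a GFF3 file."""

    def __init__(self, genes: Sequence[GeneFeature]):
        self.genes: dict[str, GeneFeature] = {g.gene_id: g for g in genes}
        self.gene_trees: dict[str, IntervalTree] = {}
        self.exon_trees: dict[str, IntervalTree] = {}
        self.introns: set[tuple[str, int, int]] = set()
        for g in genes:
            self.gene_trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g.gene_id
            )
            for s, e in g.exons:
                self.exon_trees.setdefault(g.chrom, IntervalTree()).addi(
                    s, e, g.gene_id
                )
            for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
                self.introns.add((g.chrom, e1, s2))

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GenomeAnnotation":
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        genes: dict[str, GeneFeature] = {}
        for feat in db.features_of_type("gene"):
            genes[feat.id] = GeneFeature(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
            )
        for exon in db.features_of_type("exon"):
            gene_id = None
            for parent in exon.attributes.get("Parent", []):
                # parent may be an mRNA; climb one level if needed
                if parent in genes:
                    gene_id = parent
                    break
                try:
                    up = db[parent]
                except gffutils.exceptions.FeatureNotFoundError:
                    continue
                for gp in up.attributes.get("Parent", []):
                    if gp in genes:
                        gene_id = gp
                        break
            if gene_id is not None:
                genes[gene_id].exons.append((exon.start - 1, exon.end))
        for g in genes.values():
            g.exons.sort()
        return cls(list(genes.values()))

    def genes_by_chrom(self, chrom: str) -> list[GeneFeature]:
        return sorted(
            (g for g in self.genes.values() if g.chrom == chrom),
            key=lambda g: g.start,
        )


@dataclass
class ContigAnnotation:
    """Feature vector of one contig feeding the event classifier."""

    contig: Contig
    alignment: ContigAlignment
    gene_id: str | None = None
    is_antisense: bool = False
    is_exonic: bool = False
    is_intronic: bool = False
    snv: bool = False
    ends_polya: bool = False
    contig_length: int = 0
    du_pvalue: float | None = None
    gene_is_de: bool | None = None

    @property
    def mapped_span(self) -> int:
        return self.alignment.span if self.alignment.is_mapped else 0

    @property
    def mean_a(self) -> float:
        return self.contig.mean_a

    @property
    def mean_b(self) -> float:
        return self.contig.mean_b


def _blocks_overlap(tree: IntervalTree | None, blocks) -> list:
    if tree is None:
        return []
    hits = []
    for s, e in blocks:
        hits.extend(tree.overlap(s, e))
    return hits


def annotate_contig(
    contig: Contig,
    alignment: ContigAlignment | None,
    ann: GenomeAnnotation,
    stranded: bool = True,
) -> ContigAnnotation:
    """Derive locus features for one contig from its primary alignment."""
    length = len(contig.sequence)
    if alignment is None or not alignment.is_mapped:
        return ContigAnnotation(
            contig=contig,
            alignment=alignment or ContigAlignment(contig_id=""),
            contig_length=length,
        )
    out = ContigAnnotation(contig=contig, alignment=alignment, contig_length=length)
    chrom = alignment.chrom
    if chrom not in ann.gene_trees and chrom not in ann.exon_trees:
        if ann.genes:
            warnings.warn(f"chromosome {chrom} absent from annotation; intergenic")
    gene_hits = _blocks_overlap(ann.gene_trees.get(chrom), alignment.blocks)
    if stranded:
        sense = [h for h in gene_hits if ann.genes[h.data].strand == alignment.strand]
        anti = [h for h in gene_hits if ann.genes[h.data].strand != alignment.strand]
    else:
        sense, anti = gene_hits, []
    if sense:
        out.gene_id = _best_gene(sense, alignment)
    elif anti:
        out.gene_id = _best_gene(anti, alignment)
        out.is_antisense = True
    if out.gene_id is not None and not out.is_antisense:
        exon_hits = [
            h
            for h in _blocks_overlap(ann.exon_trees.get(chrom), alignment.blocks)
            if h.data == out.gene_id
        ]
        out.is_exonic = bool(exon_hits)
        out.is_intronic = _has_exon_free_overlap(
            alignment.blocks, ann.genes[out.gene_id], exon_hits
        )
    out.snv = (
        alignment.nb_mismatches + alignment.nb_indels >= 1 and alignment.nb_hits == 1
    )
    tail = contig.sequence[length - alignment.clipped_3p :] if alignment.clipped_3p else ""
    out.ends_polya = alignment.clipped_3p >= 5 and tail.endswith("AAAAA")
    return out


def _best_gene(hits, alignment: ContigAlignment) -> str:
    def overlap(iv):
        return sum(
            max(0, min(iv.end, e) - max(iv.begin, s)) for s, e in alignment.blocks
        )

    return max(hits, key=lambda h: (overlap(h), h.data)).data


def _has_exon_free_overlap(blocks, gene: GeneFeature, exon_hits) -> bool:
    exons = sorted((h.begin, h.end) for h in exon_hits)
    for s, e in blocks:
        s, e = max(s, gene.start), min(e, gene.end)
        if s >= e:
            continue
        cov = s
        for xs, xe in exons:
            if xs > cov:
                break
            cov = max(cov, xe)
        if cov < e:
            return True
    return False


def emit_bed(annotations: Sequence[ContigAnnotation], path: str | Path) -> None:
    """Write mapped contigs as a BED6 display track (0-based half-open).

    The score is min(1000, round(-10*log10(p_adj))).
    """
    with open(path, "w") as fh:
        for a in annotations:
            if not a.alignment.is_mapped:
                continue
            p = max(a.contig.p_adj, 1e-300)
            score = min(1000, round(-10.0 * math.log10(p)))
            fh.write(
                "\t".join(
                    [
                        a.alignment.chrom,
                        str(a.alignment.start),
                        str(a.alignment.end),
                        a.alignment.contig_id or a.contig.label_kmer,
                        str(score),
                        a.alignment.strand,
                    ]
                )
                + "\n"
            )
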