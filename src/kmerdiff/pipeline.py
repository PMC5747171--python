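"""End-to-end pipeline orchestration.

Stage order is fixed: per-library counting -> sorted-dump join -> recurrence
filter -> normalization factors (from the pre-masking matrix) ->
transcriptome masking -> differential testing -> contig extension ->
adapter screening -> genome alignment -> annotation -> gene DE / DU ->
event classification -> locus grouping. Output files:

    filtered_counts.tsv.gz    post-recurrence count matrix
    masked-counts.tsv.gz      post-masking count matrix
    diff-counts.tsv.gz        significant k-mers with statistics
    merged-diff-counts.tsv.gz contigs with label-k-mer statistics
    contigs.tsv               per-contig annotation + event class
    loci.tsv                  per-locus summary
    contigs.bed               BED6 display track
    run.log / summary.json    parameters and per-stage row counts
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .align import GenomeIndex, adapter_screen, align_builtin
from .annotate import GenomeAnnotation, annotate_contig, emit_bed
from .difftest import DiffParams, compute_nf, de_filter
from .errors import ConfigError
from .events import attach_du, classify, gene_expression, group_loci
from .kmers import KmerParams, _open_text_write, count_library, dump_sorted
from .matrix import CountMatrix, FilterParams, apply_mask, build_mask, join_counts, recurrence_filter
from .merge import MergeParams, merge_tags

logger = logging.getLogger("kmerdiff")


@dataclass
class PipelineConfig:
    samples: list[tuple[str, list[str], str]]  # (library_id, fastq paths, condition)
    output_dir: str
    genome_fasta: str | None = None
    gff3: str | None = None
    masking: str | None = None  # transcriptome FASTA path, or None to skip
    kmer_length: int = 31
    min_abundance: int = 2
    min_recurrence: int | None = None  # default: min(replicates per condition)
    min_recurrence_abundance: int = 5
    pvalue_threshold: float = 0.05
    lib_type: str = "stranded"
    diff_method: str = "ttest"
    min_overlap: int = 15
    adapters: str | None = None
    threads: int = 1  # accepted for config compatibility; execution is serial
    seed: int = 0

    def __post_init__(self) -> None:
        conds = [c for _, _, c in self.samples]
        if conds.count("A") < 2 or conds.count("B") < 2:
            raise ConfigError("each condition needs at least 2 samples")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = [
            (s["library_id"], list(s["fastq"]), s["condition"])
            for s in raw.pop("samples")
        ]
        return cls(samples=samples, **raw)

    @property
    def kmer_params(self) -> KmerParams:
        return KmerParams(
            k=self.kmer_length,
            strand_mode=self.lib_type,
            min_abundance=self.min_abundance,
        )

    @property
    def effective_min_recurrence(self) -> int:
        if self.min_recurrence is not None:
            return self.min_recurrence
        conds = [c for _, _, c in self.samples]
        return min(conds.count("A"), conds.count("B"))


@dataclass
class PipelineResult:
    output_dir: Path
    stage_counts: dict[str, int]
    class_counts: dict[str, int]
    annotations: list
    loci: list
    nf: dict[str, float]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    counts: dict[str, int] = {}
    try:
        cfg_echo = {
            k: v for k, v in asdict(config).items() if k != "samples"
        }
        cfg_echo["samples"] = [
            {"library_id": l, "fastq": [str(p) for p in f], "condition": c}
            for l, f, c in config.samples
        ]
        logger.info("config: %s", json.dumps(cfg_echo, sort_keys=True))
        kp = config.kmer_params

        # 1. per-library counting -> sorted dumps
        dump_dir = outdir / "counts"
        dump_dir.mkdir(exist_ok=True)
        dumps = []
        for lib, fastqs, _ in config.samples:
            table = count_library(fastqs, kp, library_id=lib)
            path = dump_dir / f"{lib}.tsv.gz"
            dump_sorted(table, path)
            dumps.append(path)
            logger.info("counted %s: %d k-mers", lib, len(table.counts))

        # 2. join + recurrence filter
        sample_labels = [(l, c) for l, _, c in config.samples]
        matrix = join_counts(dumps, sample_labels)
        counts["raw"] = len(matrix.kmers)
        fp = FilterParams(
            min_recurrence=config.effective_min_recurrence,
            min_recurrence_abundance=config.min_recurrence_abundance,
        )
        filtered = recurrence_filter(matrix, fp)
        counts["filtered"] = len(filtered.kmers)
        filtered.to_tsv(outdir / "filtered_counts.tsv.gz")
        logger.info("raw %d -> filtered %d", counts["raw"], counts["filtered"])

        # 3. normalization factors from the pre-masking matrix
        nf = compute_nf(filtered, frac=0.30, seed=config.seed)
        logger.info("NF: %s", {k: round(v, 4) for k, v in nf.items()})

        # 4. masking
        if config.masking:
            mask = build_mask(config.masking, kp)
            masked = apply_mask(filtered, mask)
        else:
            masked = filtered
        counts["masked"] = len(masked.kmers)
        masked.to_tsv(outdir / "masked-counts.tsv.gz")

        # 5. differential testing
        dp = DiffParams(
            method=config.diff_method,
            pvalue_threshold=config.pvalue_threshold,
            seed=config.seed,
        )
        de_kmers = de_filter(masked, nf, dp)
        counts["diff"] = len(de_kmers)
        _write_diff(outdir / "diff-counts.tsv.gz", de_kmers, masked.library_ids)
        logger.info("masked %d -> DE %d", counts["masked"], counts["diff"])

        # 6. contig extension
        mp = MergeParams(k=config.kmer_length, min_overlap=config.min_overlap)
        contigs = merge_tags(de_kmers, mp)
        counts["contigs"] = len(contigs)
        _write_contigs(
            outdir / "merged-diff-counts.tsv.gz", contigs, masked.library_ids
        )

        # 7. adapter screen + alignment + annotation
        kept, discarded = adapter_screen(contigs, config.adapters)
        counts["adapter_discarded"] = len(discarded)
        annotations = []
        loci = []
        class_counts: dict[str, int] = {}
        if config.genome_fasta and config.gff3:
            index = GenomeIndex.from_fasta(config.genome_fasta)
            ann = GenomeAnnotation.from_gff3(config.gff3)
            stranded = config.lib_type == "stranded"
            for i, c in enumerate(kept):
                alns = align_builtin(
                    c, index, introns=ann.introns, contig_id=f"contig{i:05d}"
                )
                annotations.append(
                    annotate_contig(c, alns[0] if alns else None, ann, stranded)
                )

            # 8. gene expression / DU (needs the pre-masking matrix)
            if config.masking:
                genes = gene_expression(
                    filtered, config.masking, config.gff3, nf, kp,
                    method=config.diff_method,
                )
                attach_du(
                    annotations, genes, nf, masked.library_ids,
                    [c for _, c in masked.samples],
                )

            # 9. classify + group + emit
            for a in annotations:
                a.event_class = classify(a)
                class_counts[a.event_class] = class_counts.get(a.event_class, 0) + 1
            loci = group_loci(annotations, ann)
            _write_annotations(outdir / "contigs.tsv", annotations)
            _write_loci(outdir / "loci.tsv", loci)
            emit_bed(annotations, outdir / "contigs.bed")
            logger.info("classes: %s", class_counts)

        summary = {
            "stage_counts": counts,
            "class_counts": class_counts,
            "nf": nf,
            "runtime_s": round(time.time() - t0, 2),
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        return PipelineResult(
            output_dir=outdir,
            stage_counts=counts,
            class_counts=class_counts,
            annotations=annotations,
            loci=loci,
            nf=nf,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_diff(path, de_kmers, library_ids):
    with _open_text_write(path) as fh:
        header = "tag\tpvalue\tpadj\tmeanA\tmeanB\tlog2FC\t" + "\t".join(library_ids)
        fh.write((header + "\n").encode())
        for d in de_kmers:
            row = (
                f"{d.kmer}\t{d.p_raw:.6g}\t{d.p_adj:.6g}\t{d.mean_a:.4f}\t"
                f"{d.mean_b:.4f}\t{d.log2fc:.4f}\t"
                + "\t".join(map(str, d.counts))
            )
            fh.write((row + "\n").encode())


def _write_contigs(path, contigs, library_ids):
    with _open_text_write(path) as fh:
        header = (
            "contig\ttag\tnb_merged_kmers\tpvalue\tpadj\tlog2FC\t"
            + "\t".join(library_ids)
        )
        fh.write((header + "\n").encode())
        for c in contigs:
            row = (
                f"{c.sequence}\t{c.label_kmer}\t{c.kmer_count}\t{c.p_raw:.6g}\t"
                f"{c.p_adj:.6g}\t{c.log2fc:.4f}\t"
                + "\t".join(map(str, c.counts))
            )
            fh.write((row + "\n").encode())


def _write_annotations(path, annotations):
    cols = [
        "contig_id", "contig", "class", "chrom", "start", "end", "strand",
        "nb_hits", "nb_junctions", "nb_mismatches", "nb_indels",
        "clipped_5p", "clipped_3p", "is_mapped", "gene", "antisense",
        "exonic", "intronic", "snv", "ends_polyA", "length", "du_pvalue",
        "gene_is_de", "meanA", "meanB", "pvalue", "padj", "log2FC",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in annotations:
            al = a.alignment
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        al.contig_id, a.contig.sequence,
                        getattr(a, "event_class", "unclassified"),
                        al.chrom, al.start, al.end, al.strand, al.nb_hits,
                        al.nb_junctions, al.nb_mismatches, al.nb_indels,
                        al.clipped_5p, al.clipped_3p, al.is_mapped,
                        a.gene_id or ".", a.is_antisense, a.is_exonic,
                        a.is_intronic, a.snv, a.ends_polya, a.contig_length,
                        "." if a.du_pvalue is None else f"{a.du_pvalue:.6g}",
                        "." if a.gene_is_de is None else a.gene_is_de,
                        f"{a.contig.mean_a:.4f}", f"{a.contig.mean_b:.4f}",
                        f"{a.contig.p_raw:.6g}", f"{a.contig.p_adj:.6g}",
                        f"{a.contig.log2fc:.4f}",
                    ]
                )
                + "\n"
            )


def _write_loci(path, loci):
    with open(path, "w") as fh:
        fh.write("locus\tn_contigs\tbest_contig\tbest_padj\tbest_class\n")
        for l in loci:
            fh.write(
                f"{l.locus_id}\t{l.n_contigs}\t{l.best_contig.alignment.contig_id}\t"
                f"{l.best_contig.contig.p_adj:.6g}\t"
                f"{getattr(l.best_contig, 'event_class', 'unclassified')}\n"
            )
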