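import numpy as np
import pytest

from kmerdiff.align import ContigAlignment
from kmerdiff.annotate import ContigAnnotation, GeneFeature, GenomeAnnotation
from kmerdiff.difftest import compute_nf
from kmerdiff.events import classify, du_test, gene_expression, group_loci
from kmerdiff.kmers import KmerParams
from kmerdiff.matrix import CountMatrix
from kmerdiff.merge import Contig


def _annotation(**kw):
    defaults = dict(
        contig=Contig(
            sequence="A" * 60, kmers=[], label_kmer="", p_raw=0.001, p_adj=0.01,
            mean_a=5.0, mean_b=50.0,
        ),
        alignment=ContigAlignment(
            contig_id="c", chrom="chr1", start=100, end=160, strand="+",
            blocks=[(100, 160)], nb_hits=1, is_mapped=True,
        ),
        contig_length=60,
    )
    aln_keys = {
        "nb_junctions", "nb_hits", "clipped_3p", "is_mapped", "nb_mismatches",
        "start", "end",
    }
    ann = ContigAnnotation(**defaults)
    for key, val in kw.items():
        if key in aln_keys:
            setattr(ann.alignment, key, val)
        elif key in ("mean_a", "mean_b"):
            setattr(ann.contig, key, val)
        elif key == "length":
            ann.contig_length = val
        else:
            setattr(ann, key, val)
    return ann


class TestClassifyRules:
    def test_splicing_without_du(self):
        a = _annotation(gene_id="G1", nb_junctions=2, du_pvalue=0.5)
        assert classify(a) == "splicing"

    def test_splicing_du_precedence(self):
        a = _annotation(gene_id="G1", nb_junctions=1, du_pvalue=0.001)
        assert classify(a) == "splicing_DU"

    def test_polya_du(self):
        a = _annotation(
            gene_id="G1", clipped_3p=8, ends_polya=True, du_pvalue=0.001
        )
        assert classify(a) == "polyA_DU"

    def test_polya_without_du(self):
        a = _annotation(gene_id="G1", clipped_3p=6, ends_polya=True)
        assert classify(a) == "polyA"

    def test_lincrna(self):
        a = _annotation(length=250, end=2100, mean_a=30.0, mean_b=1.0)
        assert a.mapped_span == 2000
        assert classify(a) == "lincRNA"

    def test_lincrna_needs_expression_and_span(self):
        weak = _annotation(length=250, mean_a=2.0, mean_b=3.0)
        assert classify(weak) == "unclassified"
        wide = _annotation(length=250, end=100 + 20_000, mean_a=30.0)
        assert classify(wide) == "unclassified"

    def test_asrna(self):
        a = _annotation(gene_id="G1", is_antisense=True, length=300)
        assert classify(a) == "asRNA"

    def test_snv_du_requires_gene_not_de(self):
        base = dict(
            gene_id="G1", snv=True, is_exonic=True, du_pvalue=0.001,
            nb_mismatches=1,
        )
        assert classify(_annotation(**base, gene_is_de=False)) == "SNV_DU"
        assert classify(_annotation(**base, gene_is_de=True)) != "SNV_DU"

    def test_intron_and_intron_du(self):
        a = _annotation(gene_id="G1", is_intronic=True, du_pvalue=0.5)
        assert classify(a) == "intron"
        b = _annotation(gene_id="G1", is_intronic=True, du_pvalue=0.001)
        assert classify(b) == "intron_DU"

    def test_repeats(self):
        a = _annotation(nb_hits=6, length=80)
        assert classify(a) == "repeats"

    def test_unmapped_needs_min_length(self):
        a = _annotation(is_mapped=False, length=80)
        assert classify(a) == "unmapped"
        short = _annotation(is_mapped=False, length=40)
        assert classify(short) == "unclassified"

    def test_du_classes_unreachable_without_du(self):
        a = _annotation(
            gene_id="G1", snv=True, is_exonic=True, gene_is_de=False,
            du_pvalue=None, nb_mismatches=1,
        )
        assert classify(a) not in ("SNV_DU", "splicing_DU", "polyA_DU", "intron_DU")

    def test_pure_function(self):
        a = _annotation(gene_id="G1", nb_junctions=1)
        assert classify(a) == classify(a)


class TestDuTest:
    NF = np.ones(12)
    GA = np.arange(12) < 6
    GB = np.arange(12) >= 6

    def test_joint_scaling_invariance(self, rng):
        # gene tracks the contig so that (contig+1)/(gene+1) is constant:
        # no usage change however strongly the pair is differentially expressed
        contig = np.array([10.0] * 6 + [40.0] * 6)
        gene = 2.0 * contig + 1.0
        p = du_test(contig, gene, self.NF, self.GA, self.GB)
        assert p == 1.0

    def test_degenerate_constant_ratio(self):
        contig = np.array([8.0] * 12)
        gene = np.array([16.0] * 12)
        assert du_test(contig, gene, self.NF, self.GA, self.GB) == 1.0

    def test_condition_specific_usage_detected(self, rng):
        gene = rng.normal(100, 5, size=12)
        contig = np.concatenate([rng.normal(2, 1, 6), rng.normal(60, 8, 6)])
        contig = np.clip(contig, 0, None)
        p = du_test(contig, gene, self.NF, self.GA, self.GB)
        assert p < 0.01


class TestGeneExpression:
    def test_spiked_gene_detected_flat_gene_not(self, sim_refs, tmp_path, rng):
        _, refs = sim_refs
        params = KmerParams(k=31, min_abundance=1)
        # build a toy matrix from two genes' unique k-mers with counts
        g_up = refs.genes[0].gene_id
        g_flat = refs.genes[1].gene_id
        kmers = {}
        for g, fold in ((g_up, 8.0), (g_flat, 1.0)):
            tx = refs.transcripts[f"{g}.t1"]
            for i in range(0, len(tx) - 31 + 1, 3):
                kmers[tx[i : i + 31]] = fold
        rows = sorted(kmers)
        base = 60.0
        counts = np.zeros((len(rows), 12), dtype=np.int64)
        for i, km in enumerate(rows):
            mu = np.full(12, base)
            mu[6:] *= kmers[km]
            counts[i] = rng.poisson(mu)
        samples = [(f"a{i}", "A") for i in range(6)] + [
            (f"b{i}", "B") for i in range(6)
        ]
        matrix = CountMatrix(kmers=rows, counts=counts, samples=samples)
        nf = {l: 1.0 for l, _ in samples}
        genes = gene_expression(
            matrix, refs.transcriptome_fasta, refs.gff3, nf, params
        )
        assert genes[g_up].is_de is True
        assert genes[g_flat].is_de is False

    def test_gene_without_unique_kmers_undefined(self, tmp_path):
        # two genes sharing their entire sequence have no unique k-mers
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t1\t50\t.\t+\t.\tID=gA\n"
            "chr1\tx\tmRNA\t1\t50\t.\t+\t.\tID=gA.t;Parent=gA\n"
            "chr1\tx\texon\t1\t50\t.\t+\t.\tID=gA.e;Parent=gA.t\n"
            "chr1\tx\tgene\t101\t150\t.\t+\t.\tID=gB\n"
            "chr1\tx\tmRNA\t101\t150\t.\t+\t.\tID=gB.t;Parent=gB\n"
            "chr1\tx\texon\t101\t150\t.\t+\t.\tID=gB.e;Parent=gB.t\n"
        )
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC"
        fa = tmp_path / "t.fa"
        fa.write_text(f">gA.t\n{seq}\n>gB.t\n{seq}\n")
        matrix = CountMatrix(
            kmers=[], counts=np.zeros((0, 4), dtype=np.int64),
            samples=[("a0", "A"), ("a1", "A"), ("b0", "B"), ("b1", "B")],
        )
        nf = {l: 1.0 for l in ("a0", "a1", "b0", "b1")}
        genes = gene_expression(matrix, fa, gff, nf, KmerParams(k=31))
        assert genes["gA"].is_de is None and genes["gA"].expression is None
        assert genes["gB"].is_de is None


class TestGroupLoci:
    def _ann(self, gene_id=None, antisense=False, start=100, end=200, mapped=True, padj=0.01):
        return _annotation(
            gene_id=gene_id, is_antisense=antisense, start=start, end=end,
            is_mapped=mapped,
        )

    def test_gene_contigs_one_locus(self):
        ann = GenomeAnnotation([GeneFeature("G1", "chr1", 50, 500, "+")])
        loci = group_loci([self._ann("G1")] * 3, ann)
        assert len(loci) == 1
        assert loci[0].locus_id == "G1" and loci[0].n_contigs == 3

    def test_sense_and_antisense_are_two_loci(self):
        ann = GenomeAnnotation([GeneFeature("G1", "chr1", 50, 500, "+")])
        loci = group_loci(
            [self._ann("G1"), self._ann("G1", antisense=True)], ann
        )
        assert {l.locus_id for l in loci} == {"G1", "antisense:G1"}

    def test_intergenic_locus_named_by_flanking_genes(self):
        ann = GenomeAnnotation(
            [
                GeneFeature("GA", "chr1", 0, 80, "+"),
                GeneFeature("GB", "chr1", 300, 400, "+"),
            ]
        )
        loci = group_loci([self._ann(start=100, end=200)], ann)
        assert loci[0].locus_id == "chr1:GA|GB"
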