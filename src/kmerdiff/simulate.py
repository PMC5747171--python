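"""Synthetic two-condition RNA-seq data with spiked transcript variation.

The generator builds a random genome carrying non-overlapping multi-exon
genes on both strands (all introns flanked by GT-AG in transcription
orientation), writes the matching GFF3 annotation and spliced
transcriptome, and simulates stranded paired-end libraries for two
conditions. Baseline per-transcript fragment counts are negative binomial
with a shared dispersion. On top of the flat baseline, one differential
event per requested class is spiked in with a known fold change:

* ``splicing``  — an unannotated exon-skipping isoform (novel GT-AG junction)
* ``polyA``     — a polyadenylated 3' end carrying a non-genomic >= 10 A tail
* ``lincRNA``   — an intergenic transcript > 200 nt, unannotated
* ``asRNA``     — a transcript antisense to an annotated gene
* ``SNV``       — a condition-specific allele in a gene whose total
                  expression is equalized across conditions
* ``intron``    — a retained intron of an otherwise flat gene
* ``repeat``    — one unit of a 6-copy intergenic tandem repeat
* ``unmapped``  — an exogenous insert absent from the genome

Every spike comes with a truth record, so the full pipeline can be scored
offline against known events.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .kmers import revcomp

ALL_EVENTS = (
    "splicing",
    "polyA",
    "lincRNA",
    "asRNA",
    "SNV",
    "intron",
    "repeat",
    "unmapped",
)

# families of acceptable classes per spiked event (DU variants are the same
# biological event as their parent class)
EVENT_FAMILIES = {
    "splicing": {"splicing", "splicing_DU"},
    "polyA": {"polyA", "polyA_DU"},
    "lincRNA": {"lincRNA"},
    "asRNA": {"asRNA"},
    "SNV": {"SNV_DU"},
    "intron": {"intron", "intron_DU"},
    "repeat": {"repeats"},
    "unmapped": {"unmapped"},
}


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 100_000
    n_genes: int = 20
    n_replicates: int = 6
    read_length: int = 75
    depth: float = 150.0  # mean fragments per transcript
    nb_dispersion: float = 0.1
    error_rate: float = 0.0
    stranded: bool = True
    fold_change: float = 8.0
    spikes: tuple[str, ...] = ALL_EVENTS

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        unknown = set(self.spikes) - set(ALL_EVENTS)
        if unknown:
            raise ValueError(f"unknown spike classes: {sorted(unknown)}")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, genomic order

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class TruthRecord:
    event: str
    chrom: str
    start: int
    end: int
    sequence: str  # the novel (unmasked) sequence characterizing the event
    direction: str = "up"  # expected change in condition B


@dataclass
class References:
    genome: dict[str, str]
    genes: list[GeneModel]
    transcripts: dict[str, str]  # tx_id -> spliced sequence
    tx2gene: dict[str, str]
    repeat_region: tuple[int, int]
    repeat_unit: str
    linc_region: tuple[int, int]
    genome_fasta: Path
    gff3: Path
    transcriptome_fasta: Path

CHROM = "chr1"
REPEAT_UNIT_LEN = 300
REPEAT_COPIES = 6
LINC_LEN = 400


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _spliced(genome: str, gene: GeneModel) -> str:
    seq = "".join(genome[s:e] for s, e in gene.exons)
    return seq if gene.strand == "+" else revcomp(seq)


def make_reference(config: SimulationConfig, outdir: str | Path) -> References:
    """Generate genome FASTA, GFF3, and spliced transcriptome FASTA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome = list(_random_dna(rng, config.genome_length))

    genes: list[GeneModel] = []
    cursor = 1000
    for gi in range(config.n_genes):
        n_exons = int(rng.integers(2, 5))
        exons: list[tuple[int, int]] = []
        pos = cursor
        for xi in range(n_exons):
            elen = int(rng.integers(150, 401))
            exons.append((pos, pos + elen))
            pos += elen
            if xi < n_exons - 1:
                pos += int(rng.integers(100, 301))
        if pos + 500 > config.genome_length - (REPEAT_UNIT_LEN * REPEAT_COPIES + LINC_LEN + 3000):
            raise ValueError(
                "genes do not fit in the genome; increase genome_length"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        gene = GeneModel(f"gene{gi:02d}", CHROM, strand, exons)
        genes.append(gene)
        # force canonical splice dinucleotides in transcription orientation
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if strand == "+":
                genome[e1 : e1 + 2] = list("GT")
                genome[s2 - 2 : s2] = list("AG")
            else:
                genome[e1 : e1 + 2] = list("CT")
                genome[s2 - 2 : s2] = list("AC")
        cursor = pos + int(rng.integers(400, 900))

    # intergenic tandem repeat: 6 identical copies of a random unit
    rep_start = cursor + 500
    unit = _random_dna(rng, REPEAT_UNIT_LEN)
    array = unit * REPEAT_COPIES
    genome[rep_start : rep_start + len(array)] = list(array)
    rep_region = (rep_start, rep_start + len(array))

    # reserved intergenic region for a lincRNA spike (unannotated)
    linc_start = rep_start + len(array) + 800
    linc_region = (linc_start, linc_start + LINC_LEN)

    genome_str = "".join(genome)
    transcripts = {}
    tx2gene = {}
    for g in genes:
        tx = f"{g.gene_id}.t1"
        transcripts[tx] = _spliced(genome_str, g)
        tx2gene[tx] = g.gene_id

    genome_fasta = outdir / "genome.fa"
    with open(genome_fasta, "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, len(genome_str), 80):
            fh.write(genome_str[i : i + 80] + "\n")

    gff3 = outdir / "annotation.gff3"
    with open(gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{CHROM}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            tx = f"{g.gene_id}.t1"
            fh.write(
                f"{CHROM}\tsim\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={tx};Parent={g.gene_id}\n"
            )
            for j, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{CHROM}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={tx}.exon{j};Parent={tx}\n"
                )

    transcriptome_fasta = outdir / "transcriptome.fa"
    with open(transcriptome_fasta, "w") as fh:
        for tx in sorted(transcripts):
            fh.write(f">{tx}\n{transcripts[tx]}\n")

    return References(
        genome={CHROM: genome_str},
        genes=genes,
        transcripts=transcripts,
        tx2gene=tx2gene,
        repeat_region=rep_region,
        repeat_unit=unit,
        linc_region=linc_region,
        genome_fasta=genome_fasta,
        gff3=gff3,
        transcriptome_fasta=transcriptome_fasta,
    )


def _pick_gene(
    genes: Sequence[GeneModel],
    min_exons: int,
    used: set[str],
    key=None,
) -> GeneModel:
    """Pick an unused gene with enough exons; `key` selects the minimum
    (e.g. shortest transcript, to keep per-k-mer coverage high for spikes)."""
    eligible = [g for g in genes if len(g.exons) >= min_exons and g.gene_id not in used]
    if not eligible:
        raise ValueError("no suitable gene available for spike placement")
    g = min(eligible, key=key) if key else eligible[0]
    used.add(g.gene_id)
    return g


def _tx_len(g: GeneModel) -> int:
    return sum(e - s for s, e in g.exons)


@dataclass
class _SpikeTx:
    name: str
    sequence: str
    mean_a: float
    mean_b: float


def _build_spikes(
    config: SimulationConfig, refs: References, rng: np.random.Generator
) -> tuple[list[_SpikeTx], list[TruthRecord], dict[str, float]]:
    genome = refs.genome[CHROM]
    fold = config.fold_change
    depth = config.depth
    spikes: list[_SpikeTx] = []
    truth: list[TruthRecord] = []
    gene_depth_scale: dict[str, float] = {}
    used: set[str] = set()

    if "splicing" in config.spikes:
        g = _pick_gene(refs.genes, 3, used, key=lambda g: _tx_len(g) - (g.exons[1][1] - g.exons[1][0]))
        exons = [g.exons[0]] + list(g.exons[2:])  # skip the second genomic exon
        seq = "".join(genome[s:e] for s, e in exons)
        seq = seq if g.strand == "+" else revcomp(seq)
        spikes.append(_SpikeTx("spike_splicing", seq, 0.0, depth))
        truth.append(
            TruthRecord("splicing", CHROM, g.exons[0][1], g.exons[2][0], seq)
        )

    if "polyA" in config.spikes:
        g = _pick_gene(refs.genes, 2, used)
        tx = refs.transcripts[f"{g.gene_id}.t1"]
        seq = tx[-200:] + "A" * 15
        spikes.append(_SpikeTx("spike_polyA", seq, 0.0, depth))
        end = g.end if g.strand == "+" else g.start
        truth.append(TruthRecord("polyA", CHROM, end, end, seq))

    if "lincRNA" in config.spikes:
        s, e = refs.linc_region
        seq = genome[s:e]
        spikes.append(_SpikeTx("spike_lincRNA", seq, 0.0, depth))
        truth.append(TruthRecord("lincRNA", CHROM, s, e, seq))

    if "asRNA" in config.spikes:
        g = _pick_gene(refs.genes, 2, used)
        s, e = g.exons[0][0], min(g.exons[0][0] + 350, g.end)
        window = genome[s:e]
        seq = window if g.strand == "-" else revcomp(window)
        spikes.append(_SpikeTx("spike_asRNA", seq, 0.0, depth))
        truth.append(TruthRecord("asRNA", CHROM, s, e, seq))

    if "SNV" in config.spikes:
        g = _pick_gene(refs.genes, 2, used, key=_tx_len)
        tx_id = f"{g.gene_id}.t1"
        tx = refs.transcripts[tx_id]
        # place the allele mid-exon, > k away from any splice junction, so
        # the variant contig aligns ungapped within a single exon
        exons = g.exons if g.strand == "+" else g.exons[::-1]
        tx_pos = 0
        segments = []
        for s, e in exons:
            segments.append((tx_pos, tx_pos + (e - s)))
            tx_pos += e - s
        seg = max(segments, key=lambda se: se[1] - se[0])
        pos = (seg[0] + seg[1]) // 2
        ref_base = tx[pos]
        alt_base = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref_base]
        alt = tx[:pos] + alt_base + tx[pos + 1 :]
        # total expression equalized: the host gene gets 2x baseline depth in
        # both conditions, split 100/0 (A) vs 50/50 (B) between alleles
        gene_depth_scale[tx_id] = 0.0  # baseline replaced by the pair below
        spikes.append(_SpikeTx("spike_SNV_ref", tx, 2 * depth, depth))
        spikes.append(_SpikeTx("spike_SNV_alt", alt, 0.0, depth))
        truth.append(
            TruthRecord("SNV", CHROM, g.start, g.end, alt[pos - 30 : pos + 31])
        )

    if "intron" in config.spikes:
        g = _pick_gene(refs.genes, 2, used, key=lambda g: g.exons[1][1] - g.exons[0][0])
        (s1, e1), (s2, e2) = g.exons[0], g.exons[1]
        window = genome[s1:e2]  # exon1 + intron1 + exon2, pre-mRNA
        seq = window if g.strand == "+" else revcomp(window)
        spikes.append(_SpikeTx("spike_intron", seq, 0.0, depth))
        truth.append(TruthRecord("intron", CHROM, e1, s2, seq))

    if "repeat" in config.spikes:
        s, e = refs.repeat_region
        seq = refs.repeat_unit  # one full unit: maps at every copy
        spikes.append(_SpikeTx("spike_repeat", seq, 0.0, depth))
        truth.append(TruthRecord("repeat", CHROM, s, e, seq))

    if "unmapped" in config.spikes:
        while True:
            seq = _random_dna(rng, 300)
            if _shares_seed(seq, genome):
                continue
            break
        spikes.append(_SpikeTx("spike_unmapped", seq, 0.0, depth))
        truth.append(TruthRecord("unmapped", CHROM, -1, -1, seq))

    return spikes, truth, gene_depth_scale


def _shares_seed(seq: str, genome: str, seed_len: int = 15) -> bool:
    rc = revcomp(seq)
    for s in (seq, rc):
        for i in range(len(s) - seed_len + 1):
            if genome.find(s[i : i + seed_len]) >= 0:
                return True
    return False


def _nb_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return int(rng.poisson(lam))


def _write_fastq(path: Path, reads: list[tuple[str, str]]) -> None:
    with open(path, "wb") as raw, gzip.GzipFile(
        filename="", mode="wb", fileobj=raw, mtime=0
    ) as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n".encode())


def spike_and_simulate(
    config: SimulationConfig, refs: References, outdir: str | Path
) -> tuple[list[tuple[str, list[Path], str]], list[TruthRecord]]:
    """Simulate FASTQ libraries for both conditions; returns the sample sheet
    [(sample_id, [R1, R2], condition), ...] and the truth records."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    spikes, truth, gene_scale = _build_spikes(config, refs, rng)

    transcripts: list[tuple[str, str, float, float]] = []
    for tx_id in sorted(refs.transcripts):
        scale = gene_scale.get(tx_id, 1.0)
        transcripts.append(
            (tx_id, refs.transcripts[tx_id], config.depth * scale, config.depth * scale)
        )
    for sp in spikes:
        transcripts.append((sp.name, sp.sequence, sp.mean_a, sp.mean_b))

    sheet: list[tuple[str, list[Path], str]] = []
    rl = config.read_length
    for cond in "AB":
        for rep in range(config.n_replicates):
            sample = f"{cond}{rep + 1}"
            reads1: list[tuple[str, str]] = []
            reads2: list[tuple[str, str]] = []
            for tx_id, seq, mean_a, mean_b in transcripts:
                mean = mean_a if cond == "A" else mean_b
                n = _nb_count(rng, mean, config.nb_dispersion)
                tlen = len(seq)
                for i in range(n):
                    fl = int(rng.integers(150, 251))
                    fl = min(fl, tlen)
                    start = int(rng.integers(0, tlen - fl + 1))
                    frag = seq[start : start + fl]
                    r1 = frag[:rl]
                    r2 = revcomp(frag[-rl:])
                    if config.error_rate > 0:
                        r1 = _add_errors(rng, r1, config.error_rate)
                        r2 = _add_errors(rng, r2, config.error_rate)
                    name = f"{sample}.{tx_id}.{i}"
                    reads1.append((name + "/1", r1))
                    reads2.append((name + "/2", r2))
            p1 = outdir / f"{sample}_R1.fastq.gz"
            p2 = outdir / f"{sample}_R2.fastq.gz"
            _write_fastq(p1, reads1)
            _write_fastq(p2, reads2)
            sheet.append((sample, [p1, p2], cond))

    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("event\tchrom\tstart\tend\tdirection\tsequence\n")
        for t in truth:
            fh.write(
                f"{t.event}\t{t.chrom}\t{t.start}\t{t.end}\t{t.direction}\t{t.sequence}\n"
            )
    return sheet, truth


def _add_errors(rng: np.random.Generator, read: str, rate: float) -> str:
    out = list(read)
    n_err = rng.binomial(len(read), rate)
    if n_err == 0:
        return read
    positions = rng.choice(len(read), size=n_err, replace=False)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[int(rng.integers(0, 3))]
    return "".join(out)
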