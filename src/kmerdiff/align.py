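"""Contig alignment: adapter screening and a desk-scale splice-aware aligner.

Contigs are first screened against sequencing adapters (a contig sharing
any exact 15-mer with an adapter, on either strand, is discarded). Retained
contigs are aligned to the reference genome. The built-in aligner is a
seed-and-extend scheme for small genomes: exact 15-mer seeds locate
candidate diagonals, each diagonal is extended ungapped with terminal
soft-clipping and a mismatch budget of 3 per 31 aligned nt, and a single
splice gap (20 to 100,000 nt, canonical GT-AG on the aligned strand or
matching an annotated intron) may join two diagonals. All co-optimal
locations are reported (capped). Alignments produced by an external
aligner can be ingested from SAM instead; both routes yield the same
ContigAlignment records consumed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from math import ceil
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .kmers import revcomp
from .merge import Contig

SEED_LEN = 15
MIN_GAP = 20
MAX_GAP = 100_000
MAX_HITS = 50
MAX_CLIP = 30
MIN_SEGMENT = 15


@dataclass
class ContigAlignment:
    """Genomic placement of a contig (0-based half-open coordinates)."""

    contig_id: str
    chrom: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    blocks: list[tuple[int, int]] = field(default_factory=list)
    nb_hits: int = 0
    nb_junctions: int = 0
    nb_mismatches: int = 0
    nb_indels: int = 0
    clipped_5p: int = 0
    clipped_3p: int = 0
    is_mapped: bool = False

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def span(self) -> int:
        return self.end - self.start


def default_adapters_path() -> Path:
    return Path(str(resources.files("kmerdiff").joinpath("data/adapters.fa")))


def _seed_set(seqs: Iterable[str], seed_len: int = SEED_LEN) -> set[str]:
    out: set[str] = set()
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - seed_len + 1):
            out.add(s[i : i + seed_len])
    return out


def adapter_screen(
    contigs: Sequence[Contig], adapter_fasta: str | Path | None = None
) -> tuple[list[Contig], list[Contig]]:
    """Split contigs into (kept, discarded) by exact >= 15 nt adapter match."""
    if adapter_fasta is None:
        adapter_fasta = default_adapters_path()
    adapters = [str(r.seq) for r in SeqIO.parse(str(adapter_fasta), "fasta")]
    seeds = _seed_set(adapters) | _seed_set(revcomp(a) for a in adapters)
    kept: list[Contig] = []
    discarded: list[Contig] = []
    for c in contigs:
        seq = c.sequence
        hit = any(
            seq[i : i + SEED_LEN] in seeds for i in range(len(seq) - SEED_LEN + 1)
        )
        (discarded if hit else kept).append(c)
    return kept, discarded


class GenomeIndex:
    """Exact seed index over the forward strand of a small genome."""

    def __init__(self, genome: dict[str, str], seed_len: int = SEED_LEN):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.seed_len = seed_len
        self.seeds: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - seed_len + 1):
                self.seeds.setdefault(seq[i : i + seed_len], []).append((chrom, i))

    @classmethod
    def from_fasta(cls, path: str | Path, seed_len: int = SEED_LEN) -> "GenomeIndex":
        genome = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        return cls(genome, seed_len)


def _mismatch_budget(length: int) -> int:
    return 3 * ceil(length / 31)


MISMATCH_PENALTY = 5  # extending through a mismatch must buy >= 5 matches


def _best_window(mism: list[int], lo: int, hi: int, budget: int) -> tuple[int, int, int]:
    """Best-scoring sub-interval of [lo, hi) with <= budget mismatches.

    Score = aligned length - MISMATCH_PENALTY * mismatches, so the window
    extends through a mismatch only when enough matching sequence follows;
    mismatch-dense tails (e.g. non-genomic polyA) are left soft-clipped.
    Candidate boundaries sit just after/before a mismatch. Returns
    (start, end, n_mism).
    """
    ms = [m for m in mism if lo <= m < hi]
    n = len(ms)
    best = (0, lo, lo, 0)  # (score, start, end, n_mism)
    for i in range(n + 1):  # window starts after mismatch i-1
        start = (ms[i - 1] + 1) if i > 0 else lo
        for j in range(i, min(n, i + budget) + 1):  # contains ms[i:j]
            end = ms[j] if j < n else hi
            if end <= start:
                continue
            score = (end - start) - MISMATCH_PENALTY * (j - i)
            if score > best[0] or (score == best[0] and end - start > best[2] - best[1]):
                best = (score, start, end, j - i)
    return best[1], best[2], best[3]


def _mismatch_positions(seq: str, gseq: str, diag: int) -> tuple[list[int], int, int]:
    """Mismatches of seq against gseq at offset diag, clamped to the genome."""
    lo = max(0, -diag)
    hi = min(len(seq), len(gseq) - diag)
    mism = [i for i in range(lo, hi) if seq[i] != gseq[diag + i]]
    return mism, lo, hi


def _candidate_diagonals(
    index: GenomeIndex, seq: str
) -> list[tuple[str, int]]:
    sl = index.seed_len
    n = len(seq)
    if n < sl:
        return []
    counts: dict[tuple[str, int], int] = {}
    step = max(1, sl // 3)
    offsets = list(range(0, n - sl + 1, step))
    if offsets[-1] != n - sl:
        offsets.append(n - sl)
    for off in offsets:
        for chrom, pos in index.seeds.get(seq[off : off + sl], ()):
            key = (chrom, pos - off)
            counts[key] = counts.get(key, 0) + 1
    ranked = sorted(counts, key=lambda k: (-counts[k], k))
    return ranked[:100]


def _splice_candidates(
    index: GenomeIndex,
    seq: str,
    strand: str,
    diags: list[tuple[str, int]],
    introns: set[tuple[str, int, int]] | None,
) -> list[ContigAlignment]:
    out: list[ContigAlignment] = []
    n = len(seq)
    by_chrom: dict[str, list[int]] = {}
    for chrom, d in diags:
        by_chrom.setdefault(chrom, []).append(d)
    for chrom, ds in by_chrom.items():
        gseq = index.genome[chrom]
        ds = sorted(set(ds))
        for dl in ds:
            for dr in ds:
                gap = dr - dl
                if not MIN_GAP <= gap <= MAX_GAP:
                    continue
                mmL, loL, hiL = _mismatch_positions(seq, gseq, dl)
                mmR, loR, hiR = _mismatch_positions(seq, gseq, dr)
                # prefix mismatch counts at dl, suffix at dr
                pref = [0] * (n + 1)
                mset = set(mmL)
                for i in range(n):
                    pref[i + 1] = pref[i] + (
                        1 if (i in mset or not loL <= i < hiL) else 0
                    )
                suf = [0] * (n + 1)
                msetR = set(mmR)
                for i in range(n - 1, -1, -1):
                    suf[i] = suf[i + 1] + (
                        1 if (i in msetR or not loR <= i < hiR) else 0
                    )
                best = None
                for b in range(MIN_SEGMENT, n - MIN_SEGMENT + 1):
                    donor = dl + b
                    acceptor = dr + b
                    if donor < 0 or acceptor > len(gseq):
                        continue
                    motif = gseq[donor : donor + 2] + gseq[acceptor - 2 : acceptor]
                    ok = (
                        (strand == "+" and motif == "GTAG")
                        or (strand == "-" and motif == "CTAC")
                        or (introns is not None and (chrom, donor, acceptor) in introns)
                    )
                    if not ok:
                        continue
                    mm = pref[b] + suf[b]
                    if best is None or mm < best[0]:
                        best = (mm, b)
                if best is None:
                    continue
                mm, b = best
                if mm > _mismatch_budget(n):
                    continue
                aln = ContigAlignment(
                    contig_id="",
                    chrom=chrom,
                    start=dl,
                    end=dr + n,
                    strand=strand,
                    blocks=[(dl, dl + b), (dr + b, dr + n)],
                    nb_hits=1,
                    nb_junctions=1,
                    nb_mismatches=mm,
                    nb_indels=0,
                    clipped_5p=0,
                    clipped_3p=0,
                    is_mapped=True,
                )
                out.append(aln)
    return out


def align_builtin(
    contig: Contig | str,
    index: GenomeIndex,
    introns: set[tuple[str, int, int]] | None = None,
    contig_id: str = "",
) -> list[ContigAlignment]:
    """Align one contig; returns co-optimal alignments, best first, or []."""
    seq0 = contig.sequence if isinstance(contig, Contig) else contig
    seq0 = seq0.upper()
    n = len(seq0)
    if n < index.seed_len:
        return []
    candidates: list[ContigAlignment] = []
    for strand in "+-":
        seq = seq0 if strand == "+" else revcomp(seq0)
        diags = _candidate_diagonals(index, seq)
        budget = _mismatch_budget(n)
        for chrom, diag in diags:
            gseq = index.genome[chrom]
            mism, lo, hi = _mismatch_positions(seq, gseq, diag)
            s, e, nm = _best_window(mism, lo, hi, budget)
            if e - s < MIN_SEGMENT:
                continue
            candidates.append(
                ContigAlignment(
                    contig_id=contig_id,
                    chrom=chrom,
                    start=diag + s,
                    end=diag + e,
                    strand=strand,
                    blocks=[(diag + s, diag + e)],
                    nb_hits=1,
                    nb_junctions=0,
                    nb_mismatches=nm,
                    nb_indels=0,
                    clipped_5p=s if strand == "+" else n - e,
                    clipped_3p=n - e if strand == "+" else s,
                    is_mapped=True,
                )
            )
        spliced = _splice_candidates(index, seq, strand, diags, introns)
        for aln in spliced:
            aln.contig_id = contig_id
            candidates.append(aln)
    valid = [
        a
        for a in candidates
        if a.aligned_length >= max(index.seed_len, n - MAX_CLIP)
        and a.nb_mismatches + a.nb_indels <= _mismatch_budget(a.aligned_length)
    ]
    if not valid:
        return []
    # best = fewest mismatches+indels, then least clipping, then unspliced
    # before spliced, then leftmost (tie-break pinned for determinism)
    quality = lambda a: (
        a.nb_mismatches + a.nb_indels,
        a.clipped_5p + a.clipped_3p,
        a.nb_junctions,
    )
    key = lambda a: quality(a) + (a.chrom, a.start, a.strand)
    valid.sort(key=key)
    best = valid[0]
    bq = quality(best)
    seen: set[tuple[str, int, str]] = set()
    hits: list[ContigAlignment] = []
    for a in valid:
        if quality(a) != bq:
            break
        loc = (a.chrom, a.start, a.strand)
        if loc in seen:
            continue
        seen.add(loc)
        hits.append(a)
        if len(hits) >= MAX_HITS:
            break
    for a in hits:
        a.nb_hits = len(hits)
    return hits


def load_tabular_alignments(path: str | Path) -> dict[str, list[ContigAlignment]]:
    """Ingest external alignments from a headered TSV.

    Required columns: contig_id, chrom, start, end, strand; optional:
    nb_mismatches, nb_indels, nb_junctions, clipped_5p, clipped_3p
    (default 0). Coordinates are 0-based half-open. Hits per contig are
    counted across rows sharing a contig_id.
    """
    import csv

    out: dict[str, list[ContigAlignment]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            start, end = int(row["start"]), int(row["end"])
            aln = ContigAlignment(
                contig_id=row["contig_id"],
                chrom=row["chrom"],
                start=start,
                end=end,
                strand=row["strand"],
                blocks=[(start, end)],
                nb_hits=1,
                nb_junctions=int(row.get("nb_junctions", 0) or 0),
                nb_mismatches=int(row.get("nb_mismatches", 0) or 0),
                nb_indels=int(row.get("nb_indels", 0) or 0),
                clipped_5p=int(row.get("clipped_5p", 0) or 0),
                clipped_3p=int(row.get("clipped_3p", 0) or 0),
                is_mapped=True,
            )
            out.setdefault(aln.contig_id, []).append(aln)
    for alns in out.values():
        for a in alns:
            a.nb_hits = len(alns)
    return out


def load_sam_alignments(sam_path: str | Path) -> dict[str, list[ContigAlignment]]:
    """Ingest external alignments from a (text or BAM) SAM file.

    Mismatches come from the NM tag (minus indel bases), junctions from N
    cigar operations, clips from S/H operations. Hits per contig are counted
    across records sharing a query name.
    """
    import pysam

    out: dict[str, list[ContigAlignment]] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_name is None:
                continue
            cig = rec.cigartuples or []
            n_junc = sum(1 for op, _ in cig if op == 3)
            indels = sum(ln for op, ln in cig if op in (1, 2))
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            clips = [ln for op, ln in cig if op in (4, 5)]
            clip5 = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
            clip3 = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
            if rec.is_reverse:
                clip5, clip3 = clip3, clip5
            blocks = [(s, e) for s, e in rec.get_blocks()]
            aln = ContigAlignment(
                contig_id=rec.query_name,
                chrom=rec.reference_name or "",
                start=rec.reference_start,
                end=rec.reference_end or rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                blocks=blocks,
                nb_hits=1,
                nb_junctions=n_junc,
                nb_mismatches=max(0, int(nm) - indels),
                nb_indels=indels,
                clipped_5p=clip5,
                clipped_3p=clip3,
                is_mapped=True,
            )
            out.setdefault(rec.query_name, []).append(aln)
    for alns in out.values():
        for a in alns:
            a.nb_hits = len(alns)
    return out
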