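"""Per-library k-mer counting from FASTQ.

Reads are decomposed into overlapping windows of length k. For stranded
libraries, reads sequenced in the reverse orientation relative to the
transcript are reverse-complemented before windowing so that every k-mer is
reported on the transcript strand. For unstranded libraries each window is
replaced by its canonical form (the lexicographic minimum of the window and
its reverse complement). Windows overlapping a non-ACGT base are skipped.
Only k-mers reaching a per-library minimum abundance are recorded.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

from .errors import FastqParseError, InvalidSequenceError

_RC = str.maketrans("ACGTacgt", "TGCAtgca")
_DNA = frozenset("ACGT")

STRANDED = "stranded"
UNSTRANDED = "unstranded"


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_RC)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement.

    Raises
    ------
    InvalidSequenceError
        If the k-mer contains a character outside ACGT.
    """
    if not _DNA.issuperset(kmer):
        raise InvalidSequenceError(f"non-ACGT character in k-mer {kmer!r}")
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class KmerParams:
    """Parameters governing k-mer extraction and per-library counting.

    k is the window length in nucleotides (15 < k <= 63), strand_mode is
    'stranded' or 'unstranded', and min_abundance is the minimum per-library
    count for a k-mer to be recorded (the default 2 drops singletons, which
    are overwhelmingly sequencing errors).
    """

    k: int = 31
    strand_mode: str = STRANDED
    min_abundance: int = 2

    def __post_init__(self) -> None:
        if not 15 < self.k <= 63:
            raise ValueError(f"k must satisfy 15 < k <= 63, got {self.k}")
        if self.strand_mode not in (STRANDED, UNSTRANDED):
            raise ValueError(f"unknown strand_mode {self.strand_mode!r}")
        if self.min_abundance < 1:
            raise ValueError("min_abundance must be >= 1")


@dataclass
class KmerCountTable:
    """Counts of recorded k-mers for one library."""

    library_id: str
    counts: dict[str, int] = field(default_factory=dict)
    k: int = 31


def extract_kmers(
    seq: str, params: KmerParams, orientation: str = "forward"
) -> list[str]:
    """All k-length windows of a read, oriented per the library protocol.

    Stranded mode reverse-complements 'reverse'-orientation reads before
    windowing; unstranded mode canonicalizes each window. Windows containing
    a non-ACGT base are skipped. Reads shorter than k yield an empty list.
    """
    k = params.k
    seq = seq.upper()
    if params.strand_mode == STRANDED and orientation == "reverse":
        seq = revcomp(seq)
    n = len(seq)
    if n < k:
        return []
    bad = [i for i, c in enumerate(seq) if c not in _DNA]
    if params.strand_mode == UNSTRANDED:
        rc = revcomp(seq)
    out: list[str] = []
    if not bad:
        for i in range(n - k + 1):
            w = seq[i : i + k]
            if params.strand_mode == UNSTRANDED:
                w2 = rc[n - k - i : n - i]
                if w2 < w:
                    w = w2
            out.append(w)
        return out
    # skip every window overlapping a non-ACGT position
    import bisect

    for i in range(n - k + 1):
        j = bisect.bisect_left(bad, i)
        if j < len(bad) and bad[j] < i + k:
            continue
        w = seq[i : i + k]
        if params.strand_mode == UNSTRANDED:
            w2 = rc[n - k - i : n - i]
            if w2 < w:
                w = w2
        out.append(w)
    return out


def _iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ(.gz) file, with parse-error context."""
    idx = 0
    try:
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                idx += 1
                yield entry.sequence or ""
    except OSError as exc:  # pysam raises OSError on malformed records
        raise FastqParseError(
            f"malformed FASTQ record in {path} near record {idx + 1}: {exc}"
        ) from exc


def count_library(
    fastq_paths: Sequence[str | Path],
    params: KmerParams,
    library_id: str = "",
    mate_orientations: Sequence[str] | None = None,
) -> KmerCountTable:
    """Count k-mers of one library across its FASTQ files.

    mate_orientations gives the orientation per file; the default for
    stranded libraries is mate 1 forward, mate 2 reverse (alternating).
    Only k-mers whose total library count reaches params.min_abundance are
    kept. The result is independent of read order.
    """
    if mate_orientations is None:
        if params.strand_mode == STRANDED:
            mate_orientations = [
                "forward" if i % 2 == 0 else "reverse"
                for i in range(len(fastq_paths))
            ]
        else:
            mate_orientations = ["forward"] * len(fastq_paths)
    if len(mate_orientations) != len(fastq_paths):
        raise ValueError("one orientation per FASTQ file is required")
    counter: Counter[str] = Counter()
    for path, orient in zip(fastq_paths, mate_orientations):
        for seq in _iter_fastq(path):
            counter.update(extract_kmers(seq, params, orient))
    m = params.min_abundance
    counts = {km: c for km, c in counter.items() if c >= m}
    if not library_id:
        library_id = Path(fastq_paths[0]).name.split(".")[0] if fastq_paths else ""
    return KmerCountTable(library_id=library_id, counts=counts, k=params.k)


def _open_text_write(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        # mtime=0 keeps gzip output byte-identical across reruns
        raw = open(path, "wb")
        return gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
    return open(path, "wb")


def dump_sorted(table: KmerCountTable, path: str | Path) -> None:
    """Write a two-column (k-mer TAB count) dump in strict lexicographic order."""
    with _open_text_write(path) as fh:
        for km in sorted(table.counts):
            fh.write(f"{km}\t{table.counts[km]}\n".encode())


def load_dump(path: str | Path) -> Iterator[tuple[str, int]]:
    """Iterate (k-mer, count) pairs from a two-column dump."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            km, _, cnt = line.rstrip("\n").partition("\t")
            yield km, int(cnt)


def read_dump(path: str | Path) -> dict[str, int]:
    """Load a dump fully into a dict (small inputs / tests)."""
    return dict(load_dump(path))
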