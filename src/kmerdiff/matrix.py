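"""Count-matrix construction, recurrence filtering, and transcriptome masking.

Per-library sorted dumps are merged in a single streaming pass into one
k-mer x sample matrix. The recurrence filter drops k-mers seen above a
count threshold `a` in fewer than `min_recurrence` samples — the main
defense against sequencing errors. Masking then removes every k-mer that
occurs exactly in a reference transcriptome, leaving only sequence absent
from the reference (variants, novel junctions, intergenic transcription...).
The stage order is fixed: join -> recurrence filter -> mask.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConfigError, UnsortedInputError
from .kmers import KmerParams, KmerCountTable, STRANDED, UNSTRANDED, canonical, load_dump, _open_text_write


@dataclass(frozen=True)
class FilterParams:
    """Recurrence-filter parameters.

    A k-mer is kept iff it appears more than `min_recurrence_abundance`
    times in at least `min_recurrence` samples.
    """

    min_recurrence: int
    min_recurrence_abundance: int = 5

    def __post_init__(self) -> None:
        if self.min_recurrence < 1:
            raise ValueError("min_recurrence must be >= 1")
        if self.min_recurrence_abundance < 0:
            raise ValueError("min_recurrence_abundance must be >= 0")


@dataclass
class CountMatrix:
    """k-mer x sample integer count matrix with condition labels.

    Rows are kept in strict lexicographic k-mer order; `samples` is a list
    of (library_id, condition) with condition in {'A', 'B'}.
    """

    kmers: list[str]
    counts: np.ndarray  # shape (n_kmers, n_samples), int64
    samples: list[tuple[str, str]]

    @property
    def library_ids(self) -> list[str]:
        return [s[0] for s in self.samples]

    @property
    def conditions(self) -> np.ndarray:
        return np.array([s[1] for s in self.samples])

    def group_mask(self, condition: str) -> np.ndarray:
        return self.conditions == condition

    def subset(self, row_mask: np.ndarray) -> "CountMatrix":
        idx = np.flatnonzero(row_mask)
        return CountMatrix(
            kmers=[self.kmers[i] for i in idx],
            counts=self.counts[idx],
            samples=list(self.samples),
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write as 'tag' + one integer column per library (gzip by suffix)."""
        with _open_text_write(path) as fh:
            header = "tag\t" + "\t".join(self.library_ids) + "\n"
            fh.write(header.encode())
            for km, row in zip(self.kmers, self.counts):
                fh.write((km + "\t" + "\t".join(map(str, row)) + "\n").encode())

    @classmethod
    def from_tsv(
        cls, path: str | Path, conditions: dict[str, str]
    ) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"tag": str})
        libs = [c for c in df.columns if c != "tag"]
        return cls(
            kmers=df["tag"].tolist(),
            counts=df[libs].to_numpy(dtype=np.int64),
            samples=[(l, conditions[l]) for l in libs],
        )


def _checked_dump_iter(path: str | Path) -> Iterator[tuple[str, int]]:
    prev = None
    for lineno, (km, cnt) in enumerate(load_dump(path), start=1):
        if prev is not None and km <= prev:
            raise UnsortedInputError(
                f"{path}: line {lineno}: k-mer {km!r} out of order after {prev!r}"
            )
        prev = km
        yield km, cnt


def iter_joined(paths: Sequence[str | Path]) -> Iterator[tuple[str, list[int]]]:
    """Streaming k-way merge of sorted dumps; yields (kmer, per-file counts).

    Memory is proportional to the number of open files plus one row;
    unsorted input raises UnsortedInputError naming the file and line.
    """
    its = [_checked_dump_iter(p) for p in paths]
    heads: list[tuple[str, int] | None] = []
    for it in its:
        heads.append(next(it, None))
    n = len(its)
    while True:
        alive = [h[0] for h in heads if h is not None]
        if not alive:
            return
        km = min(alive)
        row = [0] * n
        for i, h in enumerate(heads):
            if h is not None and h[0] == km:
                row[i] = h[1]
                heads[i] = next(its[i], None)
        yield km, row


def join_counts(
    paths: Sequence[str | Path], samples: Sequence[tuple[str, str]]
) -> CountMatrix:
    """Join per-library sorted dumps into one matrix (absent counts are 0)."""
    kmers: list[str] = []
    rows: list[list[int]] = []
    for km, row in iter_joined(paths):
        kmers.append(km)
        rows.append(row)
    counts = (
        np.array(rows, dtype=np.int64)
        if rows
        else np.zeros((0, len(paths)), dtype=np.int64)
    )
    return CountMatrix(kmers=kmers, counts=counts, samples=list(samples))


def recurrence(row: Sequence[int] | np.ndarray, a: int) -> int:
    """Number of samples where the k-mer occurs strictly more than `a` times."""
    return int(np.sum(np.asarray(row) > a))


def recurrence_filter(matrix: CountMatrix, params: FilterParams) -> CountMatrix:
    """Keep exactly the rows with recurrence(row, a) >= min_recurrence."""
    rec = (matrix.counts > params.min_recurrence_abundance).sum(axis=1)
    return matrix.subset(rec >= params.min_recurrence)


def build_mask(transcriptome_fasta: str | Path, params: KmerParams) -> set[str]:
    """Set of all k-mers of a reference transcriptome under the same params.

    Stranded mode indexes only the annotated (sense) strand, so antisense
    k-mers survive masking; unstranded mode stores canonical forms.
    """
    k = params.k
    mask: set[str] = set()
    n_records = 0
    for rec in SeqIO.parse(str(transcriptome_fasta), "fasta"):
        n_records += 1
        seq = str(rec.seq).upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if params.strand_mode == UNSTRANDED:
                w = canonical(w)
            mask.add(w)
    if n_records == 0:
        warnings.warn(f"empty transcriptome FASTA {transcriptome_fasta}: empty mask")
    return mask


def apply_mask(matrix: CountMatrix, mask: set[str]) -> CountMatrix:
    """Drop rows whose k-mer occurs in the mask; counts are never altered."""
    if mask and matrix.kmers:
        k_mask = len(next(iter(mask)))
        if k_mask != len(matrix.kmers[0]):
            raise ConfigError(
                f"mask k-mer length {k_mask} != matrix k-mer length "
                f"{len(matrix.kmers[0])}"
            )
    keep = np.fromiter(
        (km not in mask for km in matrix.kmers), dtype=bool, count=len(matrix.kmers)
    )
    return matrix.subset(keep)
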