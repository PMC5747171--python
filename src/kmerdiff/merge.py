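"""Contig extension by unique prefix-suffix overlap (mergeTags).

Significant k-mers that cover the same transcriptional event (a splice
junction, an SNV, a polyA boundary...) overlap each other by up to k-1
bases. Extension proceeds in rounds of decreasing overlap length: at each
overlap length, pairs of contigs whose suffix/prefix match exactly are
merged — but only when the left member has exactly one outgoing and the
right member exactly one incoming overlap, so extension stops at every
fork. Each final contig is labeled by its constituent k-mer of lowest raw
p-value, whose statistics it inherits. Rather than assembling transcripts,
this groups the k-mers of one event into a single sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .difftest import DiffKmer


@dataclass(frozen=True)
class MergeParams:
    k: int = 31
    min_overlap: int = 15

    def __post_init__(self) -> None:
        if not 1 <= self.min_overlap < self.k:
            raise ValueError("min_overlap must satisfy 1 <= min_overlap < k")


@dataclass
class Contig:
    """A merged sequence with its constituent k-mers and label statistics."""

    sequence: str
    kmers: list[str]
    label_kmer: str
    p_raw: float
    p_adj: float
    counts: "object" = None
    mean_a: float = 0.0
    mean_b: float = 0.0
    log2fc: float = 0.0

    @property
    def kmer_count(self) -> int:
        return len(self.kmers)


def unique_overlaps(
    contigs: Iterable[str], olen: int
) -> set[tuple[str, str]]:
    """Ordered pairs (u, v) with suffix(u, olen) == prefix(v, olen), u != v,
    restricted to u with exactly one outgoing and v with exactly one
    incoming overlap at this length."""
    seqs = list(contigs)
    by_prefix: dict[str, list[str]] = {}
    for s in seqs:
        by_prefix.setdefault(s[:olen], []).append(s)
    edges: list[tuple[str, str]] = []
    outdeg: dict[str, int] = {}
    indeg: dict[str, int] = {}
    for u in seqs:
        for v in by_prefix.get(u[-olen:], ()):
            if v == u:
                continue
            edges.append((u, v))
            outdeg[u] = outdeg.get(u, 0) + 1
            indeg[v] = indeg.get(v, 0) + 1
    return {(u, v) for u, v in edges if outdeg[u] == 1 and indeg[v] == 1}


def _merge_pass(
    contigs: dict[str, list[str]], olen: int
) -> tuple[dict[str, list[str]], bool]:
    pairs = unique_overlaps(contigs.keys(), olen)
    if not pairs:
        return contigs, False
    succ = dict(pairs)
    pred = {v: u for u, v in pairs}
    merged: dict[str, list[str]] = {}
    visited: set[str] = set()
    # chains first: walk from every node that has a successor but no predecessor
    for start in sorted(succ):
        if start in pred or start in visited:
            continue
        node = start
        seq_parts = [node]
        members = list(contigs[node])
        visited.add(node)
        while node in succ:
            nxt = succ[node]
            if nxt in visited:
                break
            seq_parts.append(nxt[olen:])
            members.extend(contigs[nxt])
            visited.add(nxt)
            node = nxt
        _add(merged, "".join(seq_parts), members)
    # remaining nodes participating in pairs are cycles: break each at its
    # lexicographically smallest member
    cycle_nodes = sorted(set(succ) - visited)
    for start in cycle_nodes:
        if start in visited:
            continue
        node = start
        seq_parts = [node]
        members = list(contigs[node])
        visited.add(node)
        while succ[node] not in visited:
            node = succ[node]
            seq_parts.append(node[olen:])
            members.extend(contigs[node])
            visited.add(node)
        warnings.warn(f"overlap cycle at olen={olen} broken at {start[:12]}...")
        _add(merged, "".join(seq_parts), members)
    # untouched contigs pass through
    for s in contigs:
        if s not in visited:
            _add(merged, s, contigs[s])
    return merged, True


def _add(d: dict[str, list[str]], seq: str, members: list[str]) -> None:
    if seq in d:
        d[seq].extend(m for m in members if m not in d[seq])
    else:
        d[seq] = members


def merge_round(
    contigs: dict[str, list[str]], olen: int
) -> dict[str, list[str]]:
    """Repeat unique-overlap merging at a fixed overlap length to a fixpoint."""
    while True:
        contigs, changed = _merge_pass(contigs, olen)
        if not changed:
            return contigs


def merge_sequences(
    kmers: Sequence[str], params: MergeParams
) -> dict[str, list[str]]:
    """Run all rounds, olen = k-1 down to min_overlap, on bare sequences."""
    contigs: dict[str, list[str]] = {km: [km] for km in sorted(kmers)}
    for olen in range(params.k - 1, params.min_overlap - 1, -1):
        contigs = merge_round(contigs, olen)
    return contigs


def merge_tags(de_kmers: Sequence[DiffKmer], params: MergeParams) -> list[Contig]:
    """Extend significant k-mers into labeled contigs, sorted by p_raw."""
    if not de_kmers:
        return []
    stats = {d.kmer: d for d in de_kmers}
    if len(stats) != len(de_kmers):
        raise ValueError("duplicate k-mers in merge_tags input")
    merged = merge_sequences(list(stats), params)
    out: list[Contig] = []
    for seq in sorted(merged):
        members = merged[seq]
        label = min(members, key=lambda km: (stats[km].p_raw, km))
        d = stats[label]
        # p-values/counts/log2fc come from the label k-mer; the abundance
        # summary averages over all constituent k-mers, which is robust to
        # the label landing on a low-coverage k-mer
        out.append(
            Contig(
                sequence=seq,
                kmers=sorted(members),
                label_kmer=label,
                p_raw=d.p_raw,
                p_adj=d.p_adj,
                counts=d.counts,
                mean_a=float(sum(stats[m].mean_a for m in members) / len(members)),
                mean_b=float(sum(stats[m].mean_b for m in members) / len(members)),
                log2fc=d.log2fc,
            )
        )
    out.sort(key=lambda c: (c.p_raw, c.sequence))
    return out
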