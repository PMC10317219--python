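"""De Bruijn mini-assembly of locus-enriched read bins.

Each bin is assembled twice (two k values) and the two contig sets are merged
into unique contigs, emulating the common practice of running two independent
assemblers and deduplicating the union. Graph cleaning is deliberately simple:
short dangling tips and low-coverage bubble arms are pruned iteratively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._dna import MAX_K, canonical_kmer_ints, canonical_seq, int_to_kmer, rc_int, revcomp


@dataclass(frozen=True)
class Contig:
    contig_id: str
    locus: str
    seq: str
    k_used: int
    mean_kmer_coverage: float

    def __post_init__(self):
        if len(self.seq) < self.k_used:
            raise ValueError("contig shorter than k")
        if set(self.seq) - set("ACGT"):
            raise ValueError("contig alphabet must be ACGT")


def _count_kmers(reads: list[str], k: int, min_count: int) -> dict[int, int]:
    chunks = []
    for seq in reads:
        canon, valid, _ = canonical_kmer_ints(seq, k)
        if canon.size:
            chunks.append(canon[valid])
    if not chunks:
        return {}
    allk = np.concatenate(chunks)
    uniq, counts = np.unique(allk, return_counts=True)
    keep = counts >= min_count
    return dict(zip(uniq[keep].tolist(), counts[keep].tolist()))


class _Graph:
    """Oriented view over a canonical k-mer count table."""

    def __init__(self, counts: dict[int, int], k: int):
        self.counts = counts
        self.k = k
        self.mask = (1 << (2 * k)) - 1
        self.shift = 2 * (k - 1)

    def present(self, kmer: int) -> bool:
        return min(kmer, rc_int(kmer, self.k)) in self.counts

    def count(self, kmer: int) -> int:
        return self.counts[min(kmer, rc_int(kmer, self.k))]

    def succs(self, kmer: int) -> list[int]:
        base = (kmer << 2) & self.mask
        return [base | b for b in range(4) if self.present(base | b)]

    def preds(self, kmer: int) -> list[int]:
        base = kmer >> 2
        return [(b << self.shift) | base for b in range(4) if self.present((b << self.shift) | base)]

    def oriented_nodes(self) -> list[int]:
        nodes = set()
        for x in self.counts:
            nodes.add(x)
            nodes.add(rc_int(x, self.k))
        return sorted(nodes)


@dataclass
class _Unitig:
    path: tuple[int, ...]  # oriented k-mer ints
    seq: str
    coverage: float
    end_preds: tuple[int, ...]  # predecessors of first node
    end_succs: tuple[int, ...]  # successors of last node


def _spell(path: list[int], k: int) -> str:
    seq = [int_to_kmer(path[0], k)]
    for node in path[1:]:
        seq.append("ACGT"[node & 3])
    return "".join(seq)


def _build_unitigs(graph: _Graph) -> list[_Unitig]:
    k = graph.k
    nodes = graph.oriented_nodes()
    visited: set[int] = set()
    raw: list[list[int]] = []

    def is_start(n: int) -> bool:
        preds = graph.preds(n)
        if len(preds) != 1:
            return True
        return len(graph.succs(preds[0])) != 1

    for n in nodes:
        if n in visited or not is_start(n):
            continue
        path = [n]
        visited.add(n)
        while True:
            succs = graph.succs(path[-1])
            if len(succs) != 1:
                break
            nxt = succs[0]
            if len(graph.preds(nxt)) != 1 or nxt in visited or nxt == path[0]:
                break
            path.append(nxt)
            visited.add(nxt)
        raw.append(path)
    # leftover nodes belong to simple cycles
    for n in nodes:
        if n in visited:
            continue
        path = [n]
        visited.add(n)
        while True:
            succs = graph.succs(path[-1])
            nxt = succs[0]
            if nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
        raw.append(path)

    seen: set[str] = set()
    unitigs = []
    for path in raw:
        seq = _spell(path, k)
        canon = canonical_seq(seq)
        if canon in seen:
            continue
        seen.add(canon)
        cov = float(np.mean([graph.count(x) for x in path]))
        unitigs.append(
            _Unitig(
                path=tuple(path),
                seq=seq,
                coverage=cov,
                end_preds=tuple(sorted(graph.preds(path[0]))),
                end_succs=tuple(sorted(graph.succs(path[-1]))),
            )
        )
    return unitigs


def assemble_bin(
    reads: list[str],
    k: int,
    min_kmer_count: int = 2,
    locus: str = "bin",
    tip_len_factor: int = 2,
    bubble_frac: float = 0.1,
    max_prune_rounds: int = 8,
) -> list[Contig]:
    """Assemble one locus bin into unitig contigs at a single k.

    Builds a de Bruijn graph over canonical k-mers with count >= min_kmer_count,
    iteratively prunes dangling tips shorter than tip_len_factor*k and bubble
    arms below bubble_frac of the dominant arm's coverage, then emits maximal
    non-branching paths of length >= k+10. Deterministic: nodes are iterated in
    lexicographic (packed-integer) order.
    """
    if not reads:
        return []
    if k % 2 == 0 or k < 3 or k > MAX_K:
        raise ValueError(f"k must be odd and in 3..{MAX_K}, got {k}")
    if k >= max(len(r) for r in reads):
        return []

    counts = _count_kmers(reads, k, min_kmer_count)
    unitigs: list[_Unitig] = []
    for _ in range(max_prune_rounds):
        if not counts:
            return []
        graph = _Graph(counts, k)
        unitigs = _build_unitigs(graph)
        drop: list[_Unitig] = []
        # tips: dangling at exactly one end, short, and weak relative to the
        # branch node they hang off (so genuine sequence ends survive)
        for u in unitigs:
            dangling = (not u.end_preds, not u.end_succs)
            if dangling.count(True) == 1 and len(u.seq) < tip_len_factor * k:
                anchor = max(graph.count(x) for x in (u.end_preds or u.end_succs))
                if u.coverage < bubble_frac * anchor:
                    drop.append(u)
        # bubble arms: attached at both ends but carrying a small fraction of
        # the coverage flowing through their flanking branch nodes
        for u in unitigs:
            if u.end_preds and u.end_succs:
                side_in = max(graph.count(p) for p in u.end_preds)
                side_out = max(graph.count(s) for s in u.end_succs)
                if u.coverage < bubble_frac * min(side_in, side_out):
                    drop.append(u)
        if not drop:
            break
        for u in drop:
            for node in u.path:
                counts.pop(min(node, rc_int(node, k)), None)

    out = []
    kept = sorted(
        (u for u in unitigs if len(u.seq) >= k + 10),
        key=lambda u: (-len(u.seq), canonical_seq(u.seq)),
    )
    for i, u in enumerate(kept):
        out.append(
            Contig(
                contig_id=f"{locus}_k{k}_c{i:04d}",
                locus=locus,
                seq=u.seq,
                k_used=k,
                mean_kmer_coverage=round(u.coverage, 3),
            )
        )
    return out


def merge_unique_contigs(set_a: list[Contig], set_b: list[Contig]) -> list[Contig]:
    """Union of two contig sets with exact / reverse-complement / containment
    duplicates collapsed; the longest representative survives, ties broken
    lexicographically. Idempotent and commutative."""
    pool = list(set_a) + list(set_b)
    pool.sort(key=lambda c: (-len(c.seq), canonical_seq(c.seq), c.contig_id))
    kept: list[Contig] = []
    for cand in pool:
        rc = revcomp(cand.seq)
        contained = False
        for rep in kept:
            if cand.seq in rep.seq or rc in rep.seq:
                contained = True
                break
        if not contained:
            kept.append(cand)
    return kept
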