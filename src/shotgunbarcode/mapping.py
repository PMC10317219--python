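"""Ungapped seed-and-extend read mapping shared by OTU validation and the
organelle fallback.

A read maps to a reference when an exact k_seed match anchors an ungapped
extension with identity >= min_identity over the overlapping span. Every read
maps to at most one reference of the set it is mapped against: ties on
identity go to the longer overlap, then to the lexicographically smaller
reference id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._dna import batch_canonical_kmers, canonical_kmer_ints, encode


@dataclass
class MappingResult:
    ref_lengths: dict[str, int]
    pileups: dict[str, np.ndarray]
    spans: dict[str, list[tuple[int, int]]]  # mapped intervals per reference
    reads_mapped: dict[str, int]
    n_reads: int = 0

    def coverage(self, ref_id: str) -> float:
        pile = self.pileups[ref_id]
        return float((pile > 0).mean()) if pile.size else 0.0

    def mean_depth(self, ref_id: str) -> float:
        pile = self.pileups[ref_id]
        return float(pile.mean()) if pile.size else 0.0


class SeedIndex:
    """Canonical k_seed-mer positions over a set of reference sequences."""

    def __init__(self, refs: dict[str, str], k_seed: int = 15):
        self.k = k_seed
        self.refs = dict(sorted(refs.items()))
        self.codes = {rid: encode(seq) for rid, seq in self.refs.items()}
        self.index: dict[int, list[tuple[str, int, bool]]] = {}
        for rid, seq in self.refs.items():
            canon, valid, is_fwd = canonical_kmer_ints(seq, k_seed)
            for pos in np.flatnonzero(valid):
                self.index.setdefault(int(canon[pos]), []).append(
                    (rid, int(pos), bool(is_fwd[pos]))
                )
        self.sorted_kmers = np.array(sorted(self.index), dtype=np.int64)


def _extend(read_codes: np.ndarray, ref_codes: np.ndarray, offset: int) -> tuple[float, int, int, int]:
    """Ungapped comparison of a read placed at `offset` on the reference.

    Returns (identity, overlap_length, ref_start, ref_end) over the
    overlapping span.
    """
    rl = read_codes.size
    start = max(0, offset)
    end = min(ref_codes.size, offset + rl)
    if end <= start:
        return 0.0, 0, 0, 0
    a = read_codes[start - offset : end - offset]
    b = ref_codes[start:end]
    matches = int(np.count_nonzero((a == b) & (a < 4)))
    return matches / (end - start), end - start, start, end


def map_reads(
    reads: list[tuple[str, str]],
    refs: dict[str, str],
    k_seed: int = 15,
    min_identity: float = 0.95,
    max_candidates: int = 16,
    chunk_size: int = 40000,
) -> MappingResult:
    """Map (read_id, sequence) records against a reference set.

    Competitive: each read is assigned to its single best reference (by
    identity, then overlap length, then reference id) when that best placement
    reaches min_identity.
    """
    idx = SeedIndex(refs, k_seed)
    result = MappingResult(
        ref_lengths={rid: len(seq) for rid, seq in idx.refs.items()},
        pileups={rid: np.zeros(len(seq) + 1, dtype=np.int64) for rid, seq in idx.refs.items()},
        spans={rid: [] for rid in idx.refs},
        reads_mapped={rid: 0 for rid in idx.refs},
        n_reads=len(reads),
    )
    if not reads or not refs:
        _finalize(result)
        return result

    k = k_seed
    rc_cache: dict[str, np.ndarray] = {}
    for lo in range(0, len(reads), chunk_size):
        chunk = reads[lo : lo + chunk_size]
        seqs = [seq for _, seq in chunk]
        canon, valid, is_fwd, offsets = batch_canonical_kmers(seqs, k)
        hit = np.zeros(canon.size, dtype=bool)
        if canon.size:
            pos = np.searchsorted(idx.sorted_kmers, canon)
            hit = (
                valid
                & (pos < idx.sorted_kmers.size)
                & (idx.sorted_kmers[np.minimum(pos, idx.sorted_kmers.size - 1)] == canon)
            )
        for ri, (rid_read, seq) in enumerate(chunk):
            n_win = len(seq) - k + 1
            if n_win <= 0:
                continue
            base = offsets[ri]
            local_hits = np.flatnonzero(hit[base : base + n_win])
            if local_hits.size == 0:
                continue
            read_codes = encode(seq)
            candidates: set[tuple[str, bool, int]] = set()
            for j in local_hits:
                j = int(j)
                for ref_id, rpos, ref_fwd in idx.index[int(canon[base + j])]:
                    read_fwd = bool(is_fwd[base + j])
                    same_strand = read_fwd == ref_fwd
                    if same_strand:
                        cand = (ref_id, True, rpos - j)
                    else:
                        cand = (ref_id, False, rpos - (len(seq) - k - j))
                    candidates.add(cand)
                    if len(candidates) >= max_candidates:
                        break
                if len(candidates) >= max_candidates:
                    break
            best = None
            for ref_id, forward, offset in sorted(candidates):
                if forward:
                    codes = read_codes
                else:
                    codes = rc_cache.get(seq)
                    if codes is None:
                        rev = read_codes[::-1]
                        codes = np.where(rev >= 4, np.uint8(4), (3 - rev).astype(np.uint8))
                        rc_cache[seq] = codes
                ident, ov, start, end = _extend(codes, idx.codes[ref_id], offset)
                key = (-ident, -ov, ref_id)
                if best is None or key < best[0]:
                    best = (key, ref_id, start, end, ident)
            if best is not None and best[4] >= min_identity:
                _, ref_id, start, end, _ = best
                result.pileups[ref_id][start] += 1
                result.pileups[ref_id][end] -= 1
                result.spans[ref_id].append((start, end))
                result.reads_mapped[ref_id] += 1
        rc_cache.clear()
    _finalize(result)
    return result


def _finalize(result: MappingResult) -> None:
    for rid, diff in result.pileups.items():
        result.pileups[rid] = np.cumsum(diff)[:-1]
        result.spans[rid].sort()
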