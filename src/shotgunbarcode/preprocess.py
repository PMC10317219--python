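"""Adapter clipping and quality trimming of read pairs.

Semantics follow the familiar LEADING / TRAILING / SLIDINGWINDOW / MINLEN
trimming style with deliberately gentle defaults; a pair is dropped whenever
either mate falls below the length floor (no orphan stream is kept, because
every downstream stage is pair-oriented).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReadPair:
    pair_id: str
    seq1: str
    qual1: str  # Phred+33
    seq2: str
    qual2: str

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError("sequence/quality length mismatch")


@dataclass(frozen=True)
class TrimParams:
    adapter_seq: str | None = None
    window: int = 4
    window_min_q: int = 15
    min_len: int = 50
    leading_q: int = 3
    trailing_q: int = 3

    def __post_init__(self):
        for v in (self.window, self.window_min_q, self.min_len, self.leading_q, self.trailing_q):
            if v < 0:
                raise ValueError("trim parameters must be non-negative")


def _phred(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]


def clip_adapter(
    seq: str,
    qual: str,
    adapter: str,
    min_overlap: int = 8,
    max_mismatch_rate: float = 0.1,
) -> tuple[str, str]:
    """Remove a 3' adapter (or adapter prefix) from a read.

    The read suffix starting at the leftmost position where a prefix of the
    adapter aligns with at least min_overlap bases and a mismatch rate of at
    most max_mismatch_rate is removed; qualities are clipped in lockstep. A
    read without a match is returned unchanged.
    """
    if len(seq) != len(qual):
        raise ValueError("sequence/quality length mismatch")
    adapter = adapter.upper()
    n = len(seq)
    for pos in range(0, n - min_overlap + 1):
        span = min(len(adapter), n - pos)
        if span < min_overlap:
            break
        budget = int(max_mismatch_rate * span)
        mism = 0
        for off in range(span):
            if seq[pos + off] != adapter[off]:
                mism += 1
                if mism > budget:
                    break
        else:
            return seq[:pos], qual[:pos]
    return seq, qual


def _trim_one(seq: str, qual: str, params: TrimParams) -> tuple[str, str]:
    q = _phred(qual)
    start, end = 0, len(q)
    changed = True
    while changed and start < end:
        changed = False
        while start < end and q[start] < params.leading_q:
            start += 1
            changed = True
        while end > start and q[end - 1] < params.trailing_q:
            end -= 1
            changed = True
        w = params.window
        if w > 0 and end - start >= w:
            # fast path: if no base is below the window mean threshold no
            # window can fail
            if min(q[start:end]) < params.window_min_q:
                for i in range(start, end - w + 1):
                    if sum(q[i : i + w]) / w < params.window_min_q:
                        end = i
                        changed = True
                        break
    return seq[start:end], qual[start:end]


def quality_trim_pair(pair: ReadPair, params: TrimParams) -> ReadPair | None:
    """Trim both mates; returns None (pair dropped) if either mate ends up
    shorter than min_len. Trimming is idempotent."""
    s1, q1 = pair.seq1, pair.qual1
    s2, q2 = pair.seq2, pair.qual2
    if params.adapter_seq:
        s1, q1 = clip_adapter(s1, q1, params.adapter_seq)
        s2, q2 = clip_adapter(s2, q2, params.adapter_seq)
    s1, q1 = _trim_one(s1, q1, params)
    s2, q2 = _trim_one(s2, q2, params)
    if len(s1) < params.min_len or len(s2) < params.min_len:
        return None
    return ReadPair(pair.pair_id, s1, q1, s2, q2)


def trim_pairs(pairs, params: TrimParams) -> tuple[list[ReadPair], dict]:
    """Trim a stream of pairs; returns survivors and a small summary dict."""
    kept = []
    n_in = 0
    bases_in = 0
    bases_out = 0
    for pair in pairs:
        n_in += 1
        bases_in += len(pair.seq1) + len(pair.seq2)
        trimmed = quality_trim_pair(pair, params)
        if trimmed is not None:
            kept.append(trimmed)
            bases_out += len(trimmed.seq1) + len(trimmed.seq2)
    summary = {
        "pairs_in": n_in,
        "pairs_out": len(kept),
        "pairs_dropped": n_in - len(kept),
        "bases_removed": bases_in - bases_out,
    }
    return kept, summary
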