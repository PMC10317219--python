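"""Low-level DNA utilities: complementation, 2-bit k-mer encoding, IUPAC matching.

k-mers are packed into int64 (A=0, C=1, G=2, T=3, most significant base first),
so integer order equals lexicographic order for equal k. This caps k at 31.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtn", "TGCANYRSWMKVHDBtgcan")

# ASCII byte -> 2-bit code; anything outside ACGT (e.g. N) maps to 4 = invalid
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

MAX_K = 31


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """GC content in percent over ACGT positions."""
    if not seq:
        return float("nan")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    return 100.0 * gc / len(s)


def encode(seq: str | bytes) -> np.ndarray:
    """2-bit codes (uint8); non-ACGT becomes 4."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def _roll(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward k-mer ints and a validity mask for every window of `codes`."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    bad = codes >= 4
    c64 = codes.astype(np.int64)
    c64[bad] = 0
    vals = np.zeros(n, dtype=np.int64)
    for i in range(k):
        np.left_shift(vals, 2, out=vals)
        np.bitwise_or(vals, c64[i : i + n], out=vals)
    cum = np.concatenate([[0], np.cumsum(bad, dtype=np.int64)])
    valid = (cum[k:] - cum[:-k]) == 0
    return vals, valid


def kmer_ints(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward-strand k-mer integers with validity mask (False where N)."""
    if not 0 < k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")
    return _roll(encode(seq), k)


def canonical_kmer_ints(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical (min of strand pair) k-mer ints per window.

    Returns (canonical, valid, is_forward) where is_forward marks windows whose
    forward-strand k-mer equals the canonical one.
    """
    if not 0 < k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")
    codes = encode(seq)
    fwd, valid = _roll(codes, k)
    # reverse complement, rolled, then re-reversed so index i matches window i
    rc_codes = np.where(codes >= 4, np.uint8(4), (3 - codes).astype(np.uint8))[::-1]
    rev, _ = _roll(rc_codes, k)
    rev = rev[::-1]
    canon = np.minimum(fwd, rev)
    return canon, valid, fwd <= rev


def batch_canonical_kmers(seqs: list[str], k: int):
    """Canonical k-mers for many sequences in one pass.

    Sequences are joined with 'N' separators (whose windows are invalid), so
    one rolling computation covers the whole batch. Returns (canonical, valid,
    is_forward, offsets) where offsets[i] is the global window index at which
    sequence i's windows begin; sequence i owns max(len_i - k + 1, 0) windows.
    """
    if not seqs:
        empty = np.empty(0, dtype=np.int64)
        return empty, np.empty(0, dtype=bool), np.empty(0, dtype=bool), np.empty(0, dtype=np.int64)
    joined = "N".join(seqs)
    canon, valid, is_fwd = canonical_kmer_ints(joined, k)
    lens = np.fromiter((len(s) + 1 for s in seqs), dtype=np.int64, count=len(seqs))
    offsets = np.concatenate([[0], np.cumsum(lens)[:-1]])
    return canon, valid, is_fwd, offsets


def rc_int(kmer: int, k: int) -> int:
    """Reverse complement of a packed k-mer integer."""
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (kmer & 3))
        kmer >>= 2
    return out


def int_to_kmer(kmer: int, k: int) -> str:
    chars = []
    for _ in range(k):
        chars.append("ACGT"[kmer & 3])
        kmer >>= 2
    return "".join(reversed(chars))


def kmer_to_int(kmer: str) -> int:
    val = 0
    for c in kmer:
        code = _CODE[ord(c)]
        if code >= 4:
            raise ValueError(f"non-ACGT base in k-mer: {kmer!r}")
        val = (val << 2) | int(code)
    return val


def iupac_match(primer_base: str, seq_base: str) -> bool:
    """Does a (possibly degenerate) primer base match a concrete sequence base?"""
    return seq_base.upper() in IUPAC.get(primer_base.upper(), "")


def canonical_seq(seq: str) -> str:
    """Lexicographic min of a sequence and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc
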