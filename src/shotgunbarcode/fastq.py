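"""Paired FASTQ I/O (gzip-aware, Phred+33)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .preprocess import ReadPair


def _open_text(path: str | Path):
    path = str(path)
    return gzip.open(path, "rt") if path.endswith(".gz") else open(path)


def read_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Iterate synchronized read pairs from two FASTQ files."""
    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            pid = t1.split()[0].removesuffix("/1")
            yield ReadPair(pid, s1.upper(), q1, s2.upper(), q2)


def write_pairs(pairs, r1_path: str | Path, r2_path: str | Path) -> None:
    def _open_w(path):
        path = str(path)
        return gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")

    with _open_w(r1_path) as f1, _open_w(r2_path) as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{p.qual2}\n")
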