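"""OTU clustering at 100% identity, read-back mapping, and reliability filtering.

Candidates collapse only when their sequences are identical or one is an exact
substring of a longer candidate (a truncated barcode joins the full-length
cluster of the same ingredient rather than founding a spurious OTU). Shotgun
reads are then mapped back to each representative to measure sequencing depth
and coverage, and OTUs failing the reliability thresholds are flagged invalid
but kept for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dna import gc_percent
from .extraction import BarcodeCandidate
from .mapping import MappingResult, map_reads


@dataclass
class Otu:
    otu_id: str
    locus: str
    rep_seq: str
    member_count: int
    mean_depth: float = 0.0
    coverage: float = 0.0
    validated: bool = False
    partial: bool = False
    mapped_reads: int = 0
    member_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.member_count < 1:
            raise ValueError("member_count must be >= 1")

    @property
    def length(self) -> int:
        return len(self.rep_seq)

    @property
    def gc(self) -> float:
        return gc_percent(self.rep_seq)


def cluster_otus(candidates: list[BarcodeCandidate]) -> list[Otu]:
    """Cluster candidates of one locus at a 100% similarity threshold.

    Identical sequences collapse; an exact substring joins the longest
    containing candidate's cluster (representative = longest member, ties
    lexicographic); any true difference, even 1 nt, separates OTUs.
    """
    if not candidates:
        return []
    loci = {c.locus for c in candidates}
    if len(loci) > 1:
        raise ValueError(f"candidates span multiple loci: {sorted(loci)}")
    locus = loci.pop()
    ordered = sorted(candidates, key=lambda c: (-len(c.seq), c.seq, c.source_contig_id))
    clusters: list[list[BarcodeCandidate]] = []
    for cand in ordered:
        for cluster in clusters:
            if cand.seq in cluster[0].seq:
                cluster.append(cand)
                break
        else:
            clusters.append([cand])
    otus = []
    for i, cluster in enumerate(clusters):
        rep = cluster[0]
        otus.append(
            Otu(
                otu_id=f"OTU_{locus}_{i:03d}",
                locus=locus,
                rep_seq=rep.seq,
                member_count=len(cluster),
                partial=all(c.partial for c in cluster),
                member_ids=tuple(c.source_contig_id for c in cluster),
            )
        )
    return otus


def map_reads_to_otus(
    reads: list[tuple[str, str]],
    otus: list[Otu],
    k_seed: int = 15,
    min_identity: float = 0.95,
) -> MappingResult:
    """Competitively map reads onto all OTU representatives and fill each
    OTU's mean depth, coverage and mapped-read count."""
    refs = {o.otu_id: o.rep_seq for o in otus}
    result = map_reads(reads, refs, k_seed=k_seed, min_identity=min_identity)
    for otu in otus:
        otu.mean_depth = round(result.mean_depth(otu.otu_id), 4)
        otu.coverage = round(result.coverage(otu.otu_id), 4)
        otu.mapped_reads = result.reads_mapped[otu.otu_id]
    return result


def map_reads_to_otu(
    reads: list[tuple[str, str]],
    otu: Otu,
    k_seed: int = 15,
    min_identity: float = 0.95,
) -> np.ndarray:
    """Per-base pileup of reads over a single OTU representative."""
    result = map_reads_to_otus(reads, [otu], k_seed=k_seed, min_identity=min_identity)
    return result.pileups[otu.otu_id]


def filter_otus(otus: list[Otu], min_coverage: float = 0.8, min_depth: float = 5.0) -> list[Otu]:
    """Mark OTUs meeting both reliability thresholds (inclusive) as validated
    and return only those; the rest stay in the input list, flagged invalid."""
    validated = []
    for otu in otus:
        otu.validated = otu.coverage >= min_coverage and otu.mean_depth >= min_depth
        if otu.validated:
            validated.append(otu)
    return validated
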