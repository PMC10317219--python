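"""Taxonomic assignment of OTUs by overlap alignment and top-percent LCA.

Each validated OTU representative is aligned (end-gap-free dynamic
programming, exact rather than heuristic — the reference sets are tiny)
against every same-locus reference. Hits within top_percent percentage points
of the best identity vote via the lowest common ancestor of their lineages;
species-level calls below a stringent identity floor are demoted to genus to
avoid overcalling between close congeners.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .otu import Otu
from .reference import Lineage, RANKS, ReferenceDB, lca


@dataclass(frozen=True)
class Hit:
    otu_id: str
    taxon_id: str
    identity: float
    base_differences: int
    aligned_span: int

    def __post_init__(self):
        if self.aligned_span > 0:
            implied = 1.0 - self.base_differences / self.aligned_span
            if abs(implied - self.identity) > 1e-6:
                raise ValueError("identity inconsistent with base differences")


@dataclass(frozen=True)
class TaxonAssignment:
    otu_id: str
    rank: str  # a lineage rank, "root", or "unassigned"
    taxon: str
    best_identity: float
    n_hits_used: int


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -1
    try:
        a.end_insertion_score = 0
        a.end_deletion_score = 0
    except AttributeError:  # older biopython naming
        a.target_end_gap_score = 0
        a.query_end_gap_score = 0
    return a


def _alignment_stats(alignment) -> tuple[int, int]:
    """(base_differences, aligned_span) over the end-gap-free overlap.

    base differences = mismatches + internal gap columns; the span counts all
    columns from the first to the last aligned pair.
    """
    target, query = alignment.target, alignment.query
    tblocks, qblocks = alignment.aligned
    if len(tblocks) == 0:
        return 0, 0
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        aligned_cols += te - ts
        for t, q in zip(target[ts:te], query[qs:qe]):
            if t == q:
                matches += 1
    t_span = int(tblocks[-1][1] - tblocks[0][0])
    q_span = int(qblocks[-1][1] - qblocks[0][0])
    gap_cols = (t_span - aligned_cols) + (q_span - aligned_cols)
    span = aligned_cols + gap_cols
    diffs = (aligned_cols - matches) + gap_cols
    return diffs, span


def align_pair(seq_a: str, seq_b: str) -> tuple[float, int, int, float]:
    """Overlap-align two sequences; returns (identity, base_differences,
    aligned_span, score)."""
    aligner = _aligner()
    alignments = aligner.align(seq_a, seq_b)
    best = alignments[0]
    diffs, span = _alignment_stats(best)
    identity = 1.0 - diffs / span if span else 0.0
    return identity, diffs, span, float(best.score)


def align_otu(otu: Otu, refdb: ReferenceDB, min_span_frac: float = 0.6) -> list[Hit]:
    """Align an OTU representative against every same-locus reference barcode;
    hits come back sorted by identity descending.

    An overlap alignment of two unrelated sequences degenerates to a short
    perfect overhang, so an alignment only counts as a hit when its span
    covers at least min_span_frac of the shorter sequence.
    """
    hits = []
    for ref in refdb.by_locus(otu.locus):
        identity, diffs, span, _ = align_pair(otu.rep_seq, ref.barcode_seq)
        if span < min_span_frac * min(len(otu.rep_seq), len(ref.barcode_seq)):
            continue
        hits.append(
            Hit(
                otu_id=otu.otu_id,
                taxon_id=ref.taxon_id,
                identity=round(identity, 6),
                base_differences=diffs,
                aligned_span=span,
            )
        )
    hits.sort(key=lambda h: (-h.identity, h.taxon_id))
    return hits


def best_hit_genus(
    seq: str, locus: str, refdb: ReferenceDB, min_span_frac: float = 0.6
) -> str | None:
    """Genus of the best-identity reference for a sequence fragment (used by
    the chimera screen); None when nothing aligns over a meaningful span."""
    best = None
    for ref in refdb.by_locus(locus):
        identity, _, span, _ = align_pair(seq, ref.barcode_seq)
        if span < min_span_frac * min(len(seq), len(ref.barcode_seq)):
            continue
        genus = refdb.lineage_of(ref.taxon_id).genus
        key = (-identity, genus)
        if best is None or key < best[0]:
            best = (key, genus)
    return best[1] if best else None


def assign_taxon(
    hits: list[Hit],
    refdb: ReferenceDB,
    top_percent: float = 1.0,
    min_identity: float = 0.90,
    species_identity: float = 0.99,
) -> TaxonAssignment:
    """MEGAN-style top-percent LCA assignment.

    Hits below min_identity are discarded; hits within top_percent percentage
    points of the best surviving identity vote by LCA. A species-rank LCA with
    best identity below species_identity is demoted to genus.
    """
    otu_id = hits[0].otu_id if hits else "?"
    kept = [h for h in hits if h.identity >= min_identity]
    if not kept:
        return TaxonAssignment(otu_id, "unassigned", "", 0.0, 0)
    best = max(h.identity for h in kept)
    kept = [h for h in kept if h.identity >= best - top_percent / 100.0]
    lineages = [refdb.lineage_of(h.taxon_id) for h in kept]
    rank, taxon = lca(lineages)
    if rank == "species" and best < species_identity:
        rank, taxon = "genus", lineages[0].genus
    return TaxonAssignment(otu_id, rank, taxon, best, len(kept))


def assign_all(
    otus: list[Otu],
    refdb: ReferenceDB,
    top_percent: float = 1.0,
    min_identity: float = 0.90,
    species_identity: float = 0.99,
) -> dict[str, TaxonAssignment]:
    return {
        otu.otu_id: assign_taxon(
            align_otu(otu, refdb), refdb, top_percent, min_identity, species_identity
        )
        for otu in otus
    }


# --------------------------------------------------------------------------
# detection matrix and community reporting

DETECTED = "detected"
NOT_DETECTED = "not_detected"
LOCUS_ABSENT = "locus_absent"
NOT_IN_SAMPLE = "not_in_sample"

_SYMBOL = {DETECTED: "√", NOT_DETECTED: "-", LOCUS_ABSENT: "/", NOT_IN_SAMPLE: "/"}


def _species_to_taxon(refdb: ReferenceDB) -> dict[str, str]:
    return {rec.lineage.species: tid for tid, rec in refdb.taxa.items()}


def _sole_congener(refdb: ReferenceDB, genus: str) -> str | None:
    members = [tid for tid, rec in refdb.taxa.items() if rec.lineage.genus == genus]
    return members[0] if len(members) == 1 else None


def build_detection_matrix(
    assignments: list[tuple[str, Otu, TaxonAssignment]],
    samples: dict[str, set[str]],
    label_taxa: list[str],
    refdb: ReferenceDB,
) -> pd.DataFrame:
    """Per (sample, taxon, locus) detection status.

    detected: a validated, full-length OTU of that locus in that sample is
    assigned at species rank to the taxon (or at genus rank when the taxon is
    the genus's only representative in the database). locus_absent: the
    database has no such (taxon, locus). not_in_sample: the taxon was not part
    of that sample's design.
    """
    species_of = _species_to_taxon(refdb)
    detected: set[tuple[str, str, str]] = set()
    for sample_id, otu, assignment in assignments:
        if not otu.validated or otu.partial:
            continue
        tid = None
        if assignment.rank == "species":
            tid = species_of.get(assignment.taxon)
        elif assignment.rank == "genus":
            tid = _sole_congener(refdb, assignment.taxon)
        if tid is not None:
            detected.add((sample_id, tid, otu.locus))
    rows = []
    from .reference import LOCI

    for sample_id in sorted(samples):
        for tid in label_taxa:
            for locus in LOCI:
                if tid not in samples[sample_id]:
                    status = NOT_IN_SAMPLE
                elif refdb.get(tid, locus) is None:
                    status = LOCUS_ABSENT
                elif (sample_id, tid, locus) in detected:
                    status = DETECTED
                else:
                    status = NOT_DETECTED
                rows.append(
                    {
                        "sample": sample_id,
                        "taxon_id": tid,
                        "species": refdb.lineage_of(tid).species,
                        "locus": locus,
                        "status": status,
                        "symbol": _SYMBOL[status],
                    }
                )
    return pd.DataFrame(rows)


def _resolve_lineage(assignment: TaxonAssignment, refdb: ReferenceDB) -> Lineage | None:
    """Lineage context of an assignment (any DB lineage containing the taxon
    at the assigned rank)."""
    if assignment.rank not in RANKS:
        return None
    for tid in sorted(refdb.taxa):
        ln = refdb.lineage_of(tid)
        if ln.name_at(assignment.rank) == assignment.taxon:
            return ln
    return None


def community_report(
    assignments: list[tuple[str, Otu, TaxonAssignment]],
    refdb: ReferenceDB,
) -> tuple[pd.DataFrame, float | None]:
    """Fungal genus table and unlabeled/labeled plant read ratio.

    The genus table lists, per fungal genus, mapped-read counts and the
    percentage of all fungal-community reads. The ratio is
    100 * (reads of unlabeled plant taxa) / (reads of labeled plant taxa),
    or None (reported NA) when no labeled plant reads exist.
    """
    species_of = _species_to_taxon(refdb)
    fungal: dict[str, int] = {}
    labeled_reads = 0
    unlabeled_reads = 0
    for _, otu, assignment in assignments:
        reads = otu.mapped_reads
        ln = _resolve_lineage(assignment, refdb)
        if ln is None:
            continue
        rank_depth = RANKS.index(assignment.rank)
        if ln.kingdom == "Fungi" and rank_depth >= RANKS.index("genus"):
            genus = assignment.taxon if assignment.rank == "genus" else ln.genus
            fungal[genus] = fungal.get(genus, 0) + reads
        if assignment.rank == "species" and ln.kingdom == "Viridiplantae":
            tid = species_of.get(assignment.taxon)
            if tid is None:
                continue
            role = refdb.taxa[tid].role
            if role in ("labeled_ingredient", "positive_control"):
                labeled_reads += reads
            elif role == "unlabeled_plant":
                unlabeled_reads += reads
    total_fungal = sum(fungal.values())
    table = pd.DataFrame(
        [
            {
                "genus": genus,
                "reads": count,
                "percent_of_fungal": round(100.0 * count / total_fungal, 2) if total_fungal else 0.0,
            }
            for genus, count in sorted(fungal.items(), key=lambda kv: (-kv[1], kv[0]))
        ],
        columns=["genus", "reads", "percent_of_fungal"],
    )
    ratio = 100.0 * unlabeled_reads / labeled_reads if labeled_reads else None
    return table, ratio
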