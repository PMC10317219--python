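"""End-to-end pipeline orchestration, configuration, and run summaries.

Stages per sample: quality trimming -> k-mer locus enrichment -> dual-k de
Bruijn assembly with unique-contig merging -> barcode extraction -> 100% OTU
clustering with read-back depth/coverage validation -> taxonomic assignment ->
organelle-genome fallback. Cross-sample products: detection matrix, ingredient
detection calls, fungal community table, and a per-locus run summary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assembly import Contig, assemble_bin, merge_unique_contigs
from .enrichment import build_locus_index, enrich_pairs
from .extraction import BarcodeCandidate, extract_candidates, screen_bimeras
from .fastq import read_pairs
from .otu import Otu, cluster_otus, filter_otus, map_reads_to_otus
from .organelle import RegionCoverage, scan_organelles
from .preprocess import ReadPair, TrimParams, trim_pairs
from .reference import LOCI, ReferenceDB, load_organelles, load_reference_db
from .taxonomy import (
    TaxonAssignment,
    assign_all,
    build_detection_matrix,
    community_report,
)


@dataclass
class PipelineParams:
    """Every tunable stage parameter, with the package defaults."""

    trim: TrimParams = field(default_factory=TrimParams)
    enrich_k: int = 31
    enrich_min_hits: int = 3
    assembly_k: tuple[int, int] = (21, 31)
    min_kmer_count: int = 2
    #: per-bin coverage normalization: at most this many mates enter assembly
    #: (evenly subsampled, deterministic); keeps error-bubble density low in
    #: very deep bins without touching low-abundance members
    assembly_max_reads: int = 30000
    primer_max_mismatch: int = 3
    bimera_screen: bool = True
    map_k_seed: int = 15
    map_min_identity: float = 0.95
    otu_min_coverage: float = 0.8
    otu_min_depth: float = 5.0
    lca_top_percent: float = 1.0
    lca_min_identity: float = 0.90
    lca_species_identity: float = 0.99
    organelle_min_regions: int = 2
    organelle_min_region_coverage: float = 0.5


@dataclass
class RunConfig:
    refdb_fasta: str
    refdb_table: str
    samples: dict[str, tuple[str, str]]  # sample_id -> (R1, R2)
    outdir: str
    organelle_fasta: str | None = None
    organelle_features: str | None = None
    sample_composition: dict[str, list[str]] | None = None
    seed: int = 0
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        params = raw.pop("params", {})
        trim = TrimParams(**params.pop("trim", {}))
        if "assembly_k" in params:
            params["assembly_k"] = tuple(params["assembly_k"])
        samples = {sid: tuple(v) for sid, v in raw.pop("samples").items()}
        return cls(samples=samples, params=PipelineParams(trim=trim, **params), **raw)

    def validate(self) -> None:
        paths = [self.refdb_fasta, self.refdb_table]
        if self.organelle_fasta:
            paths += [self.organelle_fasta, self.organelle_features]
        for _, (r1, r2) in sorted(self.samples.items()):
            paths += [r1, r2]
        missing = [p for p in paths if p and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


@dataclass
class SampleResult:
    sample_id: str
    trim_summary: dict
    locus_tally: dict[str, int]
    contigs: list[Contig]
    candidates: list[BarcodeCandidate]
    otus: list[Otu]
    assignments: dict[str, TaxonAssignment]
    organelle_regions: list[RegionCoverage]
    organelle_calls: dict[str, bool]


@dataclass
class PipelineResult:
    samples: dict[str, SampleResult]
    detection: pd.DataFrame
    ingredient_detection: pd.DataFrame
    fungal_table: pd.DataFrame
    unlabeled_ratio: float | None
    summary: pd.DataFrame


def process_sample(
    sample_id: str,
    pairs: list[ReadPair],
    refdb: ReferenceDB,
    params: PipelineParams,
    locus_index=None,
) -> SampleResult:
    """Run every per-sample stage on an in-memory pair list."""
    trimmed, trim_summary = trim_pairs(pairs, params.trim)
    index = locus_index or build_locus_index(refdb, params.enrich_k)
    bins, _, tally = enrich_pairs(trimmed, index, params.enrich_min_hits)

    contigs: list[Contig] = []
    for locus in LOCI:
        reads = [s for p in bins.get(locus, []) for s in (p.seq1, p.seq2)]
        if not reads:
            continue
        if len(reads) > params.assembly_max_reads:
            import numpy as np

            idx = np.unique(
                np.linspace(0, len(reads) - 1, params.assembly_max_reads).astype(int)
            )
            reads = [reads[i] for i in idx]
        k1, k2 = params.assembly_k
        set_a = assemble_bin(reads, k1, params.min_kmer_count, locus=locus)
        set_b = assemble_bin(reads, k2, params.min_kmer_count, locus=locus)
        contigs.extend(merge_unique_contigs(set_a, set_b))

    candidates = extract_candidates(contigs, max_mismatch=params.primer_max_mismatch)
    if params.bimera_screen:
        candidates = screen_bimeras(candidates, refdb)

    otus: list[Otu] = []
    for locus in LOCI:
        otus.extend(cluster_otus([c for c in candidates if c.locus == locus]))

    read_tuples = [(f"{p.pair_id}/{i}", s) for p in trimmed for i, s in ((1, p.seq1), (2, p.seq2))]
    if otus:
        map_reads_to_otus(read_tuples, otus, params.map_k_seed, params.map_min_identity)
    filter_otus(otus, params.otu_min_coverage, params.otu_min_depth)

    assignments = assign_all(
        otus, refdb, params.lca_top_percent, params.lca_min_identity, params.lca_species_identity
    )
    regions, calls = scan_organelles(
        read_tuples,
        refdb.organelles,
        params.map_k_seed,
        params.map_min_identity,
        params.organelle_min_regions,
        params.organelle_min_region_coverage,
    )
    return SampleResult(
        sample_id=sample_id,
        trim_summary=trim_summary,
        locus_tally=tally,
        contigs=contigs,
        candidates=candidates,
        otus=otus,
        assignments=assignments,
        organelle_regions=regions,
        organelle_calls=calls,
    )


def summarize_run(
    contigs: list[Contig], candidates: list[BarcodeCandidate], otus: list[Otu]
) -> pd.DataFrame:
    """Per-locus run summary: unique contigs, barcodes surviving the
    annotation/chimera screen, validated OTUs, average OTU length and GC%
    (one decimal; NA for empty loci)."""
    rows = []
    for locus in LOCI:
        locus_otus = [o for o in otus if o.locus == locus and o.validated]
        n_otu = len(locus_otus)
        rows.append(
            {
                "locus": locus,
                "n_unique_contigs": sum(1 for c in contigs if c.locus == locus),
                "n_barcodes": sum(1 for c in candidates if c.locus == locus),
                "n_otus": n_otu,
                "avg_otu_length": round(sum(o.length for o in locus_otus) / n_otu, 1)
                if n_otu
                else "NA",
                "gc_percent": round(sum(o.gc for o in locus_otus) / n_otu, 1) if n_otu else "NA",
            }
        )
    return pd.DataFrame(rows)


def run_samples(
    refdb: ReferenceDB,
    sample_pairs: dict[str, list[ReadPair]],
    params: PipelineParams | None = None,
    sample_composition: dict[str, list[str]] | None = None,
) -> PipelineResult:
    """Run the full pipeline over in-memory samples and build the
    cross-sample reports."""
    params = params or PipelineParams()
    index = build_locus_index(refdb, params.enrich_k)
    results = {
        sid: process_sample(sid, pairs, refdb, params, locus_index=index)
        for sid, pairs in sorted(sample_pairs.items())
    }

    label_taxa = refdb.taxa_with_role("labeled_ingredient", "positive_control")
    composition = sample_composition or {sid: list(label_taxa) for sid in results}
    samples = {sid: set(composition.get(sid, label_taxa)) for sid in results}
    assignment_list = [
        (sid, otu, res.assignments[otu.otu_id]) for sid, res in results.items() for otu in res.otus
    ]
    detection = build_detection_matrix(assignment_list, samples, label_taxa, refdb)
    fungal_table, ratio = community_report(assignment_list, refdb)

    rows = []
    for sid, res in sorted(results.items()):
        by_barcode = detection[
            (detection["sample"] == sid) & (detection["status"] == "detected")
        ]
        for tid in sorted(samples[sid]):
            n_loci = int((by_barcode["taxon_id"] == tid).sum())
            organelle = bool(res.organelle_calls.get(tid, False))
            rows.append(
                {
                    "sample": sid,
                    "taxon_id": tid,
                    "species": refdb.lineage_of(tid).species,
                    "loci_detected": n_loci,
                    "detected_by_barcode": n_loci > 0,
                    "detected_by_organelle": organelle,
                    "detected": n_loci > 0 or organelle,
                }
            )
    ingredient_detection = pd.DataFrame(rows)

    all_contigs = [c for r in results.values() for c in r.contigs]
    all_cands = [c for r in results.values() for c in r.candidates]
    all_otus = [o for r in results.values() for o in r.otus]
    summary = summarize_run(all_contigs, all_cands, all_otus)
    return PipelineResult(
        samples=results,
        detection=detection,
        ingredient_detection=ingredient_detection,
        fungal_table=fungal_table,
        unlabeled_ratio=ratio,
        summary=summary,
    )


def _write_fasta_records(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, res in sorted(result.samples.items()):
        sdir = outdir / sid
        sdir.mkdir(exist_ok=True)
        pd.DataFrame(
            sorted(res.locus_tally.items()), columns=["locus", "pairs_enriched"]
        ).to_csv(sdir / "locus_tally.tsv", sep="\t", index=False)
        _write_fasta_records(
            sdir / "contigs.fasta",
            [
                (f"{c.contig_id}|{c.locus}|k{c.k_used}|cov{c.mean_kmer_coverage}", c.seq)
                for c in res.contigs
            ],
        )
        _write_fasta_records(
            sdir / "barcode_candidates.fasta",
            [
                (
                    f"{c.locus}|{c.source_contig_id}|{c.extraction_method}|{c.strand}"
                    + ("|partial" if c.partial else ""),
                    c.seq,
                )
                for c in res.candidates
            ],
        )
        pd.DataFrame(
            [
                {
                    "otu_id": o.otu_id,
                    "locus": o.locus,
                    "length": o.length,
                    "gc_percent": round(o.gc, 1),
                    "member_count": o.member_count,
                    "mean_depth": o.mean_depth,
                    "coverage": o.coverage,
                    "mapped_reads": o.mapped_reads,
                    "validated": o.validated,
                    "partial": o.partial,
                    "rank": res.assignments[o.otu_id].rank,
                    "taxon": res.assignments[o.otu_id].taxon,
                    "best_identity": res.assignments[o.otu_id].best_identity,
                }
                for o in res.otus
            ],
            columns=[
                "otu_id", "locus", "length", "gc_percent", "member_count", "mean_depth",
                "coverage", "mapped_reads", "validated", "partial", "rank", "taxon",
                "best_identity",
            ],
        ).to_csv(sdir / "otus.tsv", sep="\t", index=False)
        _write_fasta_records(
            sdir / "otu_representatives.fasta", [(o.otu_id, o.rep_seq) for o in res.otus]
        )
        pd.DataFrame(
            [dataclasses.asdict(rc) for rc in res.organelle_regions],
            columns=["taxon_id", "region_name", "region_kind", "reads_mapped", "coverage", "mean_depth"],
        ).round({"coverage": 4, "mean_depth": 3}).to_csv(
            sdir / "organelle_regions.tsv", sep="\t", index=False
        )
    result.detection.to_csv(outdir / "detection_matrix.tsv", sep="\t", index=False)
    result.ingredient_detection.to_csv(outdir / "ingredient_detection.tsv", sep="\t", index=False)
    result.fungal_table.to_csv(outdir / "fungal_genera.tsv", sep="\t", index=False)
    result.summary.to_csv(outdir / "run_summary.tsv", sep="\t", index=False)
    ratio = result.unlabeled_ratio
    (outdir / "community_ratio.txt").write_text(
        "unlabeled_to_labeled_plant_read_percent\t"
        + ("NA" if ratio is None else f"{ratio:.4f}")
        + "\n"
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Validate the configuration, run every sample from its FASTQ pair, write
    all outputs plus a JSON provenance record, and return the in-memory
    result. Deterministic for a fixed configuration."""
    config.validate()
    refdb = load_reference_db(config.refdb_fasta, config.refdb_table)
    if config.organelle_fasta:
        for ref in load_organelles(config.organelle_fasta, config.organelle_features).values():
            refdb.add_organelle(ref)
    sample_pairs = {
        sid: list(read_pairs(r1, r2)) for sid, (r1, r2) in sorted(config.samples.items())
    }
    result = run_samples(refdb, sample_pairs, config.params, config.sample_composition)
    write_outputs(result, config.outdir)
    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            **{k: v for k, v in dataclasses.asdict(config.params).items() if k != "trim"},
            "trim": dataclasses.asdict(config.params.trim),
        },
        "samples": {
            sid: {
                "pairs_in": res.trim_summary["pairs_in"],
                "pairs_out": res.trim_summary["pairs_out"],
                "pairs_dropped": res.trim_summary["pairs_dropped"],
                "pairs_enriched": dict(sorted(res.locus_tally.items())),
                "n_contigs": len(res.contigs),
                "n_candidates": len(res.candidates),
                "n_otus": len(res.otus),
                "n_validated_otus": sum(1 for o in res.otus if o.validated),
            }
            for sid, res in sorted(result.samples.items())
        },
    }
    Path(config.outdir, "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    return result
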