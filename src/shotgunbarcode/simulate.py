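"""Synthetic reference fixtures, mixture designs, and PCR-free shotgun reads.

This module emulates the experimental side of a shotgun-metabarcoding study of
a ten-ingredient herbal formula (eight plants, one fungus, one animal): a
local barcode reference database with realistic locus presence/absence (the
fungus carries no plastid loci, the animal only COI), toy organelle genomes
for the fallback route, a spiked positive control, low-level fungal
contaminants, and paired-end reads with insert-size and substitution-error
models plus a truth table recording every read pair's origin.
"""

from __future__ import annotations

import gzip
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._dna import decode, encode
from .extraction import DEFAULT_PRIMERS, FIVE8S_TAIL, TWENTY8S_HEAD
from .reference import (
    BarcodeReference,
    Lineage,
    OrganelleReference,
    ReferenceDB,
    TaxonRecord,
)

#: Relative per-genome copy numbers by locus class: ribosomal ITS2 sits in a
#: high-copy tandem repeat, plastid and mitochondrial loci in multi-copy
#: organelles.
DEFAULT_COPY_WEIGHTS = {"ITS2": 100.0, "psbA-trnH": 20.0, "matK": 20.0, "rbcL": 20.0, "COI": 20.0}

_PLANT_LOCI = ("ITS2", "psbA-trnH", "matK", "rbcL")

# (taxon_id, lineage names kingdom..species, role, kingdom_class, loci)
_TAXA: list[tuple[str, tuple[str, ...], str, str, tuple[str, ...]]] = [
    ("ophiopogon_japonicus",
     ("Viridiplantae", "Streptophyta", "Liliopsida", "Asparagales", "Asparagaceae", "Ophiopogon", "Ophiopogon japonicus"),
     "labeled_ingredient", "plant", _PLANT_LOCI),
    ("platycodon_grandiflorus",
     ("Viridiplantae", "Streptophyta", "Magnoliopsida", "Asterales", "Campanulaceae", "Platycodon", "Platycodon grandiflorus"),
     "labeled_ingredient", "plant", _PLANT_LOCI),
    ("canarium_album",
     ("Viridiplantae", "Streptophyta", "Magnoliopsida", "Sapindales", "Burseraceae", "Canarium", "Canarium album"),
     "labeled_ingredient", "plant", _PLANT_LOCI),
    ("scrophularia_ningpoensis",
     ("Viridiplantae", "Streptophyta", "Magnoliopsida", "Lamiales", "Scrophulariaceae", "Scrophularia", "Scrophularia ningpoensis"),
     "labeled_ingredient", "plant", _PLANT_LOCI),
    ("fritillaria_thunbergii",
     ("Viridiplantae", "Streptophyta", "Liliopsida", "Liliales", "Liliaceae", "Fritillaria", "Fritillaria thunbergii"),
     "labeled_ingredient", "plant", _PLANT_LOCI),
    ("trichosanthes_kirilowii",
     ("Viridiplantae", "Streptophyta", "Magnoliopsida", "Cucurbitales", "Cucurbitaceae", "Trichosanthes", "Trichosanthes kirilowii"),
     "labeled_ingredient", "plant", _PLANT_LOCI),
    ("wolfiporia_cocos",
     ("Fungi", "Basidiomycota", "Agaricomycetes", "Polyporales", "Polyporaceae", "Wolfiporia", "Wolfiporia cocos"),
     "labeled_ingredient", "fungus", ("ITS2",)),
    ("glycyrrhiza_uralensis",
     ("Viridiplantae", "Streptophyta", "Magnoliopsida", "Fabales", "Fabaceae", "Glycyrrhiza", "Glycyrrhiza uralensis"),
     "labeled_ingredient", "plant", _PLANT_LOCI),
    ("gallus_gallus",
     ("Metazoa", "Chordata", "Aves", "Galliformes", "Phasianidae", "Gallus", "Gallus gallus"),
     "labeled_ingredient", "animal", ("COI",)),
    ("terminalia_chebula",
     ("Viridiplantae", "Streptophyta", "Magnoliopsida", "Myrtales", "Combretaceae", "Terminalia", "Terminalia chebula"),
     "labeled_ingredient", "plant", _PLANT_LOCI),
    ("panax_quinquefolius",
     ("Viridiplantae", "Streptophyta", "Magnoliopsida", "Apiales", "Araliaceae", "Panax", "Panax quinquefolius"),
     "positive_control", "plant", _PLANT_LOCI),
    ("panax_ginseng",
     ("Viridiplantae", "Streptophyta", "Magnoliopsida", "Apiales", "Araliaceae", "Panax", "Panax ginseng"),
     "unlabeled_plant", "plant", _PLANT_LOCI),
    ("scrophularia_buergeriana",
     ("Viridiplantae", "Streptophyta", "Magnoliopsida", "Lamiales", "Scrophulariaceae", "Scrophularia", "Scrophularia buergeriana"),
     "unlabeled_plant", "plant", _PLANT_LOCI),
    ("zea_mays",
     ("Viridiplantae", "Streptophyta", "Liliopsida", "Poales", "Poaceae", "Zea", "Zea mays"),
     "unlabeled_plant", "plant", _PLANT_LOCI),
    ("schwanniomyces_occidentalis",
     ("Fungi", "Ascomycota", "Saccharomycetes", "Saccharomycetales", "Debaryomycetaceae", "Schwanniomyces", "Schwanniomyces occidentalis"),
     "contaminant", "fungus", ("ITS2",)),
    ("diaporthe_eres",
     ("Fungi", "Ascomycota", "Sordariomycetes", "Diaporthales", "Diaporthaceae", "Diaporthe", "Diaporthe eres"),
     "contaminant", "fungus", ("ITS2",)),
    ("fusarium_oxysporum",
     ("Fungi", "Ascomycota", "Sordariomycetes", "Hypocreales", "Nectriaceae", "Fusarium", "Fusarium oxysporum"),
     "contaminant", "fungus", ("ITS2",)),
]

#: Congeneric pairs: (derived taxon, source taxon, divergence fraction).
_CONGENERS = {
    "panax_ginseng": ("panax_quinquefolius", 0.03),
    "scrophularia_buergeriana": ("scrophularia_ningpoensis", 0.03),
}

_BARCODE_LEN = {"ITS2": (210, 250), "psbA-trnH": (330, 400), "matK": (760, 800), "rbcL": (680, 720), "COI": (640, 660)}

_FLANK_LEN = 250


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return decode(rng.integers(0, 4, n).astype(np.uint8))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    codes = encode(seq).copy()
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    codes[pos] = (codes[pos] + rng.integers(1, 4, n_subs)) % 4
    return decode(codes)


def _resolve_iupac(rng: np.random.Generator, seq: str) -> str:
    from ._dna import IUPAC

    out = []
    for b in seq:
        opts = IUPAC[b]
        out.append(opts if len(opts) == 1 else opts[rng.integers(0, len(opts))])
    return "".join(out)


def _make_context(rng: np.random.Generator, locus: str, barcode: str) -> str:
    """Embed a barcode between its primer sites with >=200 nt genomic flank."""
    pair = DEFAULT_PRIMERS[locus]
    if locus == "ITS2":
        fwd_site, rev_site = FIVE8S_TAIL, TWENTY8S_HEAD
    else:
        from ._dna import revcomp

        fwd_site = _resolve_iupac(rng, pair.fwd_seq)
        rev_site = revcomp(_resolve_iupac(rng, pair.rev_seq))
    left = _rand_seq(rng, _FLANK_LEN)
    right = _rand_seq(rng, _FLANK_LEN)
    return left + fwd_site + barcode + rev_site + right


def _make_organelle(
    rng: np.random.Generator, taxon_id: str, kind: str, genes: list[tuple[str, int]]
) -> OrganelleReference:
    """Toy organelle genome: named genes separated by intergenic spacers."""
    segments: list[tuple[str, str, int]] = []
    prev = "start"
    for name, length in genes:
        segments.append((f"{prev}-{name}", "intergenic", int(rng.integers(350, 700))))
        segments.append((name, "gene", length))
        prev = name
    segments.append((f"{prev}-end", "intergenic", int(rng.integers(350, 700))))
    features = []
    pos = 0
    for name, fkind, length in segments:
        features.append((name, pos, pos + length, fkind))
        pos += length
    seq = _rand_seq(rng, pos)
    return OrganelleReference(taxon_id=taxon_id, genome_kind=kind, seq=seq, features=tuple(features))


def generate_reference_fixtures(seed: int) -> tuple[ReferenceDB, dict[tuple[str, str], OrganelleReference]]:
    """Deterministic reference database emulating a ten-ingredient formula.

    Labeled roles: eight plants with the four plant barcodes, one fungus (ITS2
    only, with a toy mitochondrion carrying COX1 among its genes), one animal
    (COI only); a plant positive control; unlabeled-plant entries including
    congeners of the control and of one labeled plant; and three contaminant
    fungal genera. One labeled plant carries a toy chloroplast. Within a genus
    barcodes differ at a controlled fraction of sites.
    """
    rng = np.random.default_rng(seed)
    db = ReferenceDB()
    barcodes: dict[tuple[str, str], str] = {}
    for taxon_id, names, role, kclass, loci in _TAXA:
        db.add_taxon(TaxonRecord(taxon_id, Lineage.from_names(*names), role, kclass))
        for locus in loci:
            if taxon_id in _CONGENERS:
                src, div = _CONGENERS[taxon_id]
                base = barcodes[(src, locus)]
                n_subs = max(1, round(div * len(base)))
                barcodes[(taxon_id, locus)] = _mutate(rng, base, n_subs)
            else:
                lo, hi = _BARCODE_LEN[locus]
                barcodes[(taxon_id, locus)] = _rand_seq(rng, int(rng.integers(lo, hi + 1)))
    for taxon_id, names, role, kclass, loci in _TAXA:
        for locus in loci:
            barcode = barcodes[(taxon_id, locus)]
            db.add_barcode(
                BarcodeReference(
                    taxon_id=taxon_id,
                    locus=locus,
                    barcode_seq=barcode,
                    context_seq=_make_context(rng, locus, barcode),
                    copy_weight=DEFAULT_COPY_WEIGHTS[locus],
                )
            )
    db.add_organelle(
        _make_organelle(
            rng,
            "wolfiporia_cocos",
            "mitochondrion",
            [("nad1", 900), ("orf5", 400), ("nad2", 1000), ("COX1", 1300), ("atp8", 300), ("orf30", 350)],
        )
    )
    db.add_organelle(
        _make_organelle(
            rng,
            "terminalia_chebula",
            "chloroplast",
            [("psbA", 1060), ("ndhK", 680), ("ndhB", 1480), ("ycf2", 2000), ("rpl2", 990)],
        )
    )
    return db, dict(db.organelles)


# --------------------------------------------------------------------------
# mixture designs


@dataclass(frozen=True)
class MixtureDesign:
    sample_id: str
    components: tuple[tuple[str, float], ...]
    contaminant_fraction: float = 0.02
    background_fraction: float = 0.10

    def __post_init__(self):
        total = sum(p for _, p in self.components)
        if self.components and abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass proportions must sum to 1, got {total}")
        if not 0 <= self.contaminant_fraction < 1 or not 0 <= self.background_fraction < 1:
            raise ValueError("fractions must be in [0, 1)")

    def proportion_of(self, taxon_id: str) -> float:
        for tid, p in self.components:
            if tid == taxon_id:
                return p
        raise KeyError(taxon_id)

    def validate_against(self, db: ReferenceDB) -> None:
        for tid, _ in self.components:
            if tid not in db.taxa:
                raise ValueError(f"design taxon {tid!r} not in reference DB")


def default_mock_design(db: ReferenceDB, sample_id: str = "mock_a") -> MixtureDesign:
    """Equal mass proportions across the labeled ingredients."""
    labeled = db.taxa_with_role("labeled_ingredient")
    p = 1.0 / len(labeled)
    comps = tuple((t, p) for t in labeled)
    # renormalize exactly
    return MixtureDesign(sample_id=sample_id, components=_renorm(comps))


def pharmaceutical_design(
    db: ReferenceDB, sample_id: str = "pharma_a", unlabeled_proportion: float = 0.004
) -> MixtureDesign:
    """Labeled ingredients plus trace unlabeled plants, as in a market sample."""
    labeled = db.taxa_with_role("labeled_ingredient")
    unlabeled = db.taxa_with_role("unlabeled_plant")
    rest = 1.0 - unlabeled_proportion * len(unlabeled)
    comps = [(t, rest / len(labeled)) for t in labeled]
    comps += [(t, unlabeled_proportion) for t in unlabeled]
    return MixtureDesign(sample_id=sample_id, components=_renorm(tuple(comps)))


def _renorm(comps: tuple[tuple[str, float], ...]) -> tuple[tuple[str, float], ...]:
    total = sum(p for _, p in comps)
    return tuple((t, p / total) for t, p in comps)


def spike_positive_control(
    design: MixtureDesign, taxon_id: str, reference_taxon_id: str
) -> MixtureDesign:
    """Add a control taxon at the proportion of a reference component and
    renormalize, mirroring how a positive control is weighed into one mock."""
    if any(t == taxon_id for t, _ in design.components):
        raise ValueError(f"{taxon_id!r} already present in design")
    p_ref = design.proportion_of(reference_taxon_id)  # KeyError if absent
    comps = design.components + ((taxon_id, p_ref),)
    return replace(design, components=_renorm(comps))


# --------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class SimulationConfig:
    n_read_pairs: int
    seed: int = 0
    read_length: int = 150
    insert_mean: int = 350
    insert_sd: int = 35
    substitution_rate: float = 0.002
    organelle_copy_weight: float = 20.0
    n_decoys: int = 20
    decoy_length: int = 2000

    def __post_init__(self):
        if self.insert_mean < self.read_length:
            raise ValueError("insert_mean must be >= read_length")
        if not 0 <= self.substitution_rate <= 0.1:
            raise ValueError("substitution_rate must be in [0, 0.1]")


@dataclass
class SimulatedSample:
    sample_id: str
    pairs: list[tuple[str, str, str, str, str]]  # (pair_id, seq1, qual1, seq2, qual2)
    truth: pd.DataFrame  # pair_id, taxon_id, source, start, end, strand


def _error_rates(rate: float, read_length: int) -> np.ndarray:
    """Per-position substitution probability, doubling linearly toward the 3'
    end while preserving the configured mean."""
    pos = np.arange(read_length)
    return rate * (2.0 / 3.0) * (1.0 + pos / max(read_length - 1, 1))


def _sample_seed(seed: int, sample_id: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(sample_id.encode())]))


def simulate_sample(
    design: MixtureDesign, config: SimulationConfig, refdb: ReferenceDB
) -> SimulatedSample:
    """Simulate paired-end PCR-free shotgun reads for one mixture.

    The expected read share of each (taxon, source) is mass_proportion x
    copy_weight within the non-contaminant, non-background budget; fragments
    are drawn with Gaussian insert sizes from barcode contexts, organelle
    genomes, contaminant barcodes and random genomic decoys. Every emitted
    pair gets a truth-table row.
    """
    if config.n_read_pairs <= 0:
        raise ValueError("n_read_pairs must be positive")
    design.validate_against(refdb)
    rng = _sample_seed(config.seed, design.sample_id)
    rl = config.read_length

    # (taxon, source-label, sequence, unnormalized weight) in deterministic order
    sources: list[tuple[str, str, str, float]] = []
    for tid, prop in design.components:
        for locus in refdb.loci_of(tid):
            ref = refdb.get(tid, locus)
            sources.append((tid, f"locus:{locus}", ref.context_seq, prop * ref.copy_weight))
        for (otid, kind), org in sorted(refdb.organelles.items()):
            if otid == tid:
                sources.append((tid, f"organelle:{kind}", org.seq, prop * config.organelle_copy_weight))
    main_total = sum(w for *_, w in sources) or 1.0
    main_budget = 1.0 - design.contaminant_fraction - design.background_fraction
    probs = [w / main_total * main_budget for *_, w in sources]

    contaminants = refdb.taxa_with_role("contaminant")
    for tid in contaminants:
        for locus in refdb.loci_of(tid):
            ref = refdb.get(tid, locus)
            sources.append((tid, f"locus:{locus}", ref.context_seq, 0.0))
            probs.append(design.contaminant_fraction / len(contaminants) / len(refdb.loci_of(tid)))

    for i in range(config.n_decoys):
        decoy = _rand_seq(rng, config.decoy_length)
        sources.append(("decoy", "genomic", decoy, 0.0))
        probs.append(design.background_fraction / config.n_decoys)

    counts = rng.multinomial(config.n_read_pairs, np.asarray(probs) / sum(probs))

    pairs: list[tuple[str, str, str, str, str]] = []
    truth_rows: list[tuple[str, str, str, int, int, str]] = []
    rates = _error_rates(config.substitution_rate, rl)
    pair_no = 0
    for (tid, label, seq, _), n in zip(sources, counts):
        if n == 0:
            continue
        codes = encode(seq)
        L = codes.size
        inserts = np.clip(
            np.rint(rng.normal(config.insert_mean, config.insert_sd, n)).astype(int), rl, L
        )
        starts = np.floor(rng.random(n) * (L - inserts + 1)).astype(int)
        ends = starts + inserts
        idx1 = starts[:, None] + np.arange(rl)
        idx2 = (ends - rl)[:, None] + np.arange(rl)
        top = codes[idx1]                       # fragment 5' read, top strand
        bottom = (3 - codes[idx2])[:, ::-1]     # fragment 3' read, bottom strand
        flip = rng.random(n) < 0.5              # which physical strand R1 comes from
        r1 = np.where(flip[:, None], bottom, top)
        r2 = np.where(flip[:, None], top, bottom)
        if config.substitution_rate > 0:
            for mat in (r1, r2):
                err = rng.random((n, rl)) < rates
                n_err = int(err.sum())
                if n_err:
                    mat[err] = (mat[err] + rng.integers(1, 4, n_err)) % 4
        letters = np.frombuffer(b"ACGT", dtype=np.uint8)
        s1 = letters[r1].reshape(n, rl).view(f"S{rl}").ravel()
        s2 = letters[r2].reshape(n, rl).view(f"S{rl}").ravel()
        q1 = (rng.integers(35, 41, (n, rl)) + 33).astype(np.uint8).view(f"S{rl}").ravel()
        q2 = (rng.integers(35, 41, (n, rl)) + 33).astype(np.uint8).view(f"S{rl}").ravel()
        for i in range(n):
            pid = f"{design.sample_id}_p{pair_no:08d}"
            pair_no += 1
            pairs.append(
                (pid, s1[i].decode(), q1[i].decode(), s2[i].decode(), q2[i].decode())
            )
            truth_rows.append(
                (pid, tid, label, int(starts[i]), int(ends[i]), "-" if flip[i] else "+")
            )
    truth = pd.DataFrame(
        truth_rows, columns=["pair_id", "taxon_id", "source", "start", "end", "strand"]
    )
    return SimulatedSample(sample_id=design.sample_id, pairs=pairs, truth=truth)


def write_sample(
    sample: SimulatedSample,
    r1_path: str,
    r2_path: str,
    truth_path: str | None = None,
) -> None:
    """Write Phred+33 FASTQ (gzipped when the path ends in .gz) and truth TSV."""

    def _open(path):
        return gzip.open(path, "wt") if str(path).endswith(".gz") else open(path, "w")

    with _open(r1_path) as f1, _open(r2_path) as f2:
        for pid, s1, q1, s2, q2 in sample.pairs:
            f1.write(f"@{pid}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{pid}/2\n{s2}\n+\n{q2}\n")
    if truth_path:
        sample.truth.to_csv(truth_path, sep="\t", index=False)
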