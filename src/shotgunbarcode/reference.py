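"""Reference model: taxa, lineages, barcode and organelle references, and LCA.

The reference database is a small, fully local stand-in for the public barcode
repositories a lab would query (GenBank / BOLD / a TCM barcode library): one
FASTA of locus sequences plus a tab-separated sidecar carrying lineage, role
and per-genome copy weight for each record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

LOCI = ("ITS2", "psbA-trnH", "matK", "rbcL", "COI")

ROLES = ("labeled_ingredient", "positive_control", "contaminant", "unlabeled_plant")

KINGDOM_CLASSES = ("plant", "fungus", "animal")


@dataclass(frozen=True)
class Lineage:
    """A fixed seven-rank lineage from kingdom down to species."""

    ranks: tuple[tuple[str, str], ...]

    def __post_init__(self):
        names = tuple(r for r, _ in self.ranks)
        if names != RANKS:
            raise ValueError(f"lineage must carry ranks {RANKS}, got {names}")
        if any(not t for _, t in self.ranks):
            raise ValueError("empty taxon name in lineage")

    @classmethod
    def from_names(cls, *names: str) -> "Lineage":
        if len(names) != len(RANKS):
            raise ValueError(f"expected {len(RANKS)} names, got {len(names)}")
        return cls(tuple(zip(RANKS, names)))

    @classmethod
    def from_string(cls, s: str, sep: str = ";") -> "Lineage":
        return cls.from_names(*(p.strip() for p in s.split(sep)))

    def to_string(self, sep: str = ";") -> str:
        return sep.join(t for _, t in self.ranks)

    def name_at(self, rank: str) -> str:
        return dict(self.ranks)[rank]

    @property
    def species(self) -> str:
        return self.ranks[-1][1]

    @property
    def genus(self) -> str:
        return self.ranks[-2][1]

    @property
    def kingdom(self) -> str:
        return self.ranks[0][1]


def lca(lineages: list[Lineage]) -> tuple[str, str]:
    """Lowest common ancestor of a non-empty set of lineages.

    Returns the deepest (rank, taxon) shared by all inputs; lineages that
    disagree already at kingdom collapse to ("root", "cellular organisms").
    """
    if not lineages:
        raise ValueError("lca of empty lineage list")
    result = ("root", "cellular organisms")
    first = lineages[0]
    for depth, (rank, name) in enumerate(first.ranks):
        if all(ln.ranks[depth][1] == name for ln in lineages[1:]):
            result = (rank, name)
        else:
            break
    return result


@dataclass(frozen=True)
class TaxonRecord:
    taxon_id: str
    lineage: Lineage
    role: str
    kingdom_class: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.kingdom_class not in KINGDOM_CLASSES:
            raise ValueError(f"unknown kingdom_class {self.kingdom_class!r}")


@dataclass(frozen=True)
class BarcodeReference:
    """One barcode locus of one taxon.

    barcode_seq is the inter-primer region; context_seq embeds it together with
    the primer sites and genomic flank, and is what shotgun fragments are drawn
    from. copy_weight is the relative per-genome copy number of the locus
    (ribosomal repeats vastly outnumber single-copy plastid genes, which drives
    the per-locus read-count imbalance seen in real shotgun libraries).
    """

    taxon_id: str
    locus: str
    barcode_seq: str
    context_seq: str
    copy_weight: float = 1.0

    def __post_init__(self):
        if self.locus not in LOCI:
            raise ValueError(f"unknown locus {self.locus!r}")
        if set(self.barcode_seq) - set("ACGT"):
            raise ValueError("barcode_seq must be ACGT only")
        if self.barcode_seq not in self.context_seq:
            raise ValueError("barcode_seq must be a substring of context_seq")
        if self.copy_weight <= 0:
            raise ValueError("copy_weight must be positive")


@dataclass(frozen=True)
class OrganelleReference:
    """A whole organelle genome with gene/intergenic features (0-based half-open)."""

    taxon_id: str
    genome_kind: str  # chloroplast | mitochondrion
    seq: str
    features: tuple[tuple[str, int, int, str], ...]  # (name, start, end, kind)

    def __post_init__(self):
        if self.genome_kind not in ("chloroplast", "mitochondrion"):
            raise ValueError(f"unknown genome_kind {self.genome_kind!r}")
        n = len(self.seq)
        genes = []
        for name, start, end, kind in self.features:
            if not (0 <= start < end <= n):
                raise ValueError(f"feature {name} out of bounds [{start},{end}) on {n} nt")
            if kind not in ("gene", "intergenic"):
                raise ValueError(f"unknown feature kind {kind!r}")
            if kind == "gene":
                genes.append((start, end, name))
        genes.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(genes, genes[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping gene features {n1} and {n2}")


@dataclass
class ReferenceDB:
    """Indexed local barcode reference collection."""

    taxa: dict[str, TaxonRecord] = field(default_factory=dict)
    barcodes: dict[tuple[str, str], BarcodeReference] = field(default_factory=dict)
    organelles: dict[tuple[str, str], OrganelleReference] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.barcodes)

    def add_taxon(self, rec: TaxonRecord) -> None:
        existing = {t.lineage.species for t in self.taxa.values()}
        if rec.taxon_id not in self.taxa and rec.lineage.species in existing:
            raise ValueError(f"duplicate species {rec.lineage.species!r} in database")
        self.taxa[rec.taxon_id] = rec

    def add_barcode(self, ref: BarcodeReference) -> None:
        key = (ref.taxon_id, ref.locus)
        if key in self.barcodes:
            raise ValueError(f"duplicate (taxon, locus) pair {key}")
        if ref.taxon_id not in self.taxa:
            raise ValueError(f"barcode references unknown taxon {ref.taxon_id!r}")
        self.barcodes[key] = ref

    def add_organelle(self, ref: OrganelleReference) -> None:
        self.organelles[(ref.taxon_id, ref.genome_kind)] = ref

    def get(self, taxon_id: str, locus: str) -> BarcodeReference | None:
        return self.barcodes.get((taxon_id, locus))

    def by_locus(self, locus: str) -> list[BarcodeReference]:
        return [b for (_, loc), b in sorted(self.barcodes.items()) if loc == locus]

    def loci_of(self, taxon_id: str) -> list[str]:
        return [loc for (tid, loc) in sorted(self.barcodes) if tid == taxon_id]

    def lineage_of(self, taxon_id: str) -> Lineage:
        return self.taxa[taxon_id].lineage

    def taxa_with_role(self, *roles: str) -> list[str]:
        return sorted(t for t, rec in self.taxa.items() if rec.role in roles)

    # ------------------------------------------------------------------ I/O

    def save(self, fasta_path: str | Path, table_path: str | Path) -> None:
        records = []
        for (tid, locus), ref in sorted(self.barcodes.items()):
            records.append(
                SeqRecord(Seq(ref.context_seq), id=f"{tid}|{locus}", description="")
            )
        _write_fasta(records, fasta_path)
        lines = ["taxon_id\tlocus\tlineage\tcopy_weight\trole\tkingdom_class\tbarcode_start\tbarcode_end"]
        for (tid, locus), ref in sorted(self.barcodes.items()):
            rec = self.taxa[tid]
            start = ref.context_seq.index(ref.barcode_seq)
            lines.append(
                "\t".join(
                    [
                        tid,
                        locus,
                        rec.lineage.to_string(),
                        f"{ref.copy_weight:g}",
                        rec.role,
                        rec.kingdom_class,
                        str(start),
                        str(start + len(ref.barcode_seq)),
                    ]
                )
            )
        Path(table_path).write_text("\n".join(lines) + "\n")

    def save_organelles(self, fasta_path: str | Path, features_path: str | Path) -> None:
        records = []
        lines = ["seq_id\tstart\tend\tname\tkind"]
        for (tid, kind), ref in sorted(self.organelles.items()):
            seq_id = f"{tid}|{kind}"
            records.append(SeqRecord(Seq(ref.seq), id=seq_id, description=""))
            for name, start, end, fkind in ref.features:
                lines.append(f"{seq_id}\t{start}\t{end}\t{name}\t{fkind}")
        _write_fasta(records, fasta_path)
        Path(features_path).write_text("\n".join(lines) + "\n")


def _write_fasta(records, path: str | Path) -> None:
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


def load_reference_db(fasta_path: str | Path, table_path: str | Path) -> ReferenceDB:
    """Load barcodes + lineage sidecar into an indexed ReferenceDB.

    Every FASTA record id (``taxon|locus``) must appear in the sidecar table;
    duplicate (taxon, locus) pairs are a hard error.
    """
    rows: dict[tuple[str, str], dict] = {}
    header = None
    for line in Path(table_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if header is None:
            header = parts
            continue
        row = dict(zip(header, parts))
        key = (row["taxon_id"], row["locus"])
        if key in rows:
            raise ValueError(f"duplicate (taxon, locus) pair {key} in table")
        rows[key] = row

    db = ReferenceDB()
    n_records = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        n_records += 1
        try:
            tid, locus = rec.id.split("|", 1)
        except ValueError:
            raise ValueError(f"FASTA id {rec.id!r} is not of form taxon|locus")
        key = (tid, locus)
        if key not in rows:
            raise ValueError(f"FASTA id {rec.id!r} missing from lineage table")
        row = rows[key]
        if tid not in db.taxa:
            db.add_taxon(
                TaxonRecord(
                    taxon_id=tid,
                    lineage=Lineage.from_string(row["lineage"]),
                    role=row.get("role", "labeled_ingredient"),
                    kingdom_class=row.get("kingdom_class", "plant"),
                )
            )
        context = str(rec.seq).upper()
        start, end = int(row["barcode_start"]), int(row["barcode_end"])
        db.add_barcode(
            BarcodeReference(
                taxon_id=tid,
                locus=locus,
                barcode_seq=context[start:end],
                context_seq=context,
                copy_weight=float(row["copy_weight"]),
            )
        )
    if n_records != len(db):
        raise AssertionError("record count mismatch after load")
    return db


def load_organelles(fasta_path: str | Path, features_path: str | Path) -> dict[tuple[str, str], OrganelleReference]:
    feats: dict[str, list[tuple[str, int, int, str]]] = {}
    header = None
    for line in Path(features_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        row = dict(zip(header, parts))
        feats.setdefault(row["seq_id"], []).append(
            (row["name"], int(row["start"]), int(row["end"]), row["kind"])
        )
    out: dict[tuple[str, str], OrganelleReference] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        tid, kind = rec.id.split("|", 1)
        out[(tid, kind)] = OrganelleReference(
            taxon_id=tid,
            genome_kind=kind,
            seq=str(rec.seq).upper(),
            features=tuple(feats.get(rec.id, ())),
        )
    return out
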