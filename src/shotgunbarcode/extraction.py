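"""Barcode extraction from contigs.

psbA-trnH / matK / rbcL / COI barcodes are cut out between their primer sites
(IUPAC-aware, mismatch-tolerant, no indels). ITS2 is located instead by its
conserved ribosomal flanks: two position-weight profiles model the 3' end of
5.8S and the 5' start of 28S, and the region enclosed between high-scoring
profile hits is the ITS2 barcode. A contig that ends inside one flank yields a
candidate flagged partial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dna import IUPAC, encode, revcomp
from .assembly import Contig


@dataclass(frozen=True)
class PrimerPair:
    locus: str
    fwd_name: str
    fwd_seq: str
    rev_name: str
    rev_seq: str

    def __post_init__(self):
        for seq in (self.fwd_seq, self.rev_seq):
            if not 15 <= len(seq) <= 30:
                raise ValueError(f"primer length {len(seq)} outside 15..30: {seq}")
            if set(seq.upper()) - set(IUPAC):
                raise ValueError(f"invalid IUPAC alphabet in primer {seq!r}")


#: Standard barcode primer set. Sequences are 20-mer working versions of the
#: published universal primers for each locus (one degenerate base retained in
#: the trnH primer).
DEFAULT_PRIMERS: dict[str, PrimerPair] = {
    "ITS2": PrimerPair("ITS2", "ITS2F", "ATGCGATACTTGGTGTGAAT", "ITS3R", "ACGCTTCTCCAGACTACAAT"),
    "psbA-trnH": PrimerPair("psbA-trnH", "psbA", "GTTATGCATGAACGTAATGC", "trnH", "CGCGCATGGTGGATTCACAR"),
    "matK": PrimerPair("matK", "3F_KIM", "ACAGTACTTTTGTGTTTACG", "1R_KIM", "CCCAGTCCATCTGGAAATCT"),
    "rbcL": PrimerPair("rbcL", "1F", "ATGTCACCACAAACAGAGAC", "724R", "TCGCATGTACCTGCAGTAGC"),
    "COI": PrimerPair("COI", "LCO1490", "GGTCAACAAATCATAAAGAT", "HCO2198", "TAAACTTCAGGGTGACCAAA"),
}

#: Conserved ribosomal flanks enclosing ITS2: the ITS2F primer site sits at the
#: 3' end of 5.8S, and the reverse-complemented ITS3R site opens 28S.
FIVE8S_TAIL = DEFAULT_PRIMERS["ITS2"].fwd_seq
TWENTY8S_HEAD = revcomp(DEFAULT_PRIMERS["ITS2"].rev_seq)


@dataclass(frozen=True)
class BarcodeCandidate:
    locus: str
    seq: str
    source_contig_id: str
    extraction_method: str  # primer | flank_profile
    strand: str  # + | -
    partial: bool = False

    def __post_init__(self):
        if not self.seq:
            raise ValueError("empty barcode candidate")
        if self.extraction_method not in ("primer", "flank_profile"):
            raise ValueError(f"unknown extraction method {self.extraction_method!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


def _pwm_from_seq(seq: str, match_p: float = 0.91) -> np.ndarray:
    """Columns over ACGT: match_p on the consensus base, remainder spread."""
    pwm = np.full((len(seq), 4), (1.0 - match_p) / 3.0)
    for i, base in enumerate(seq):
        pwm[i, "ACGT".index(base)] = match_p
    return pwm


@dataclass
class FlankProfile:
    """Position-weight profiles for the two conserved flanks of ITS2."""

    pwm_five: np.ndarray  # 3' end of 5.8S
    pwm_three: np.ndarray  # 5' start of 28S
    threshold: float = 12.0
    max_barcode_len: int = 450
    _lo_five: np.ndarray = field(init=False, repr=False)
    _lo_three: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        for pwm in (self.pwm_five, self.pwm_three):
            if not (15 <= pwm.shape[0] <= 25):
                raise ValueError("profile length must be 15..25 columns")
            if not np.allclose(pwm.sum(axis=1), 1.0):
                raise ValueError("profile columns must sum to 1")
        self._lo_five = np.log(self.pwm_five / 0.25)
        self._lo_three = np.log(self.pwm_three / 0.25)

    @classmethod
    def default(cls) -> "FlankProfile":
        return cls(_pwm_from_seq(FIVE8S_TAIL), _pwm_from_seq(TWENTY8S_HEAD))


def _scan_profile(codes: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Log-odds score of every window of `codes` against the profile."""
    width = logodds.shape[0]
    n = codes.size - width + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for i in range(width):
        window = codes[i : i + n]
        col = np.where(window >= 4, -np.inf, logodds[i, np.minimum(window, 3)])
        scores = scores + col
    return scores


def find_primer_sites(
    contig_seq: str, primer: str, max_mismatch: int = 3
) -> list[tuple[int, str, int]]:
    """All (position, strand, mismatches) where the primer matches the contig.

    IUPAC degenerate codes in the primer match any of their bases; a '-'
    strand hit at position p means revcomp(primer) matches contig[p:p+len].
    No indels are considered.
    """
    primer = primer.upper()
    hits = []
    for strand, probe in (("+", primer), ("-", revcomp(primer))):
        allowed = [IUPAC.get(b, "") for b in probe]
        span = len(probe)
        for pos in range(len(contig_seq) - span + 1):
            mism = 0
            for off in range(span):
                if contig_seq[pos + off] not in allowed[off]:
                    mism += 1
                    if mism > max_mismatch:
                        break
            else:
                hits.append((pos, strand, mism))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _interprimer_one_orientation(
    seq: str, pair: PrimerPair, max_mismatch: int
) -> tuple[int, int] | None:
    """Longest (leftmost on tie) region between a + fwd-primer site and a
    downstream revcomp rev-primer site; returns (start, end) of the barcode."""
    fwd_hits = [h for h in find_primer_sites(seq, pair.fwd_seq, max_mismatch) if h[1] == "+"]
    rev_hits = [h for h in find_primer_sites(seq, pair.rev_seq, max_mismatch) if h[1] == "-"]
    best = None
    for fpos, _, _ in fwd_hits:
        start = fpos + len(pair.fwd_seq)
        for rpos, _, _ in rev_hits:
            if rpos <= start:
                continue
            length = rpos - start
            key = (-length, start, rpos)
            if best is None or key < best[0]:
                best = (key, (start, rpos))
    return best[1] if best else None


def extract_interprimer(
    contig: Contig, primer_pair: PrimerPair, max_mismatch: int = 3
) -> BarcodeCandidate | None:
    """Cut the barcode strictly between the primer sites of its locus.

    Both contig orientations are searched; the result is canonicalized to the
    forward (F -> R) barcode orientation. The longest extractable region wins,
    ties going to the leftmost pairing.
    """
    plus = _interprimer_one_orientation(contig.seq, primer_pair, max_mismatch)
    rc = revcomp(contig.seq)
    minus = _interprimer_one_orientation(rc, primer_pair, max_mismatch)
    plus_len = plus[1] - plus[0] if plus else -1
    minus_len = minus[1] - minus[0] if minus else -1
    if plus_len <= 0 and minus_len <= 0:
        return None
    if plus_len >= minus_len:
        start, end = plus
        seq, strand = contig.seq[start:end], "+"
    else:
        start, end = minus
        seq, strand = rc[start:end], "-"
    return BarcodeCandidate(
        locus=primer_pair.locus,
        seq=seq,
        source_contig_id=contig.contig_id,
        extraction_method="primer",
        strand=strand,
    )


def _annotate_one_orientation(
    seq: str, profile: FlankProfile
) -> tuple[float, str, bool] | None:
    codes = encode(seq)
    w5 = profile.pwm_five.shape[0]
    w3 = profile.pwm_three.shape[0]
    s5 = _scan_profile(codes, profile._lo_five)
    s3 = _scan_profile(codes, profile._lo_three)
    hits5 = [(float(s5[i]), i) for i in np.flatnonzero(s5 >= profile.threshold)]
    hits3 = [(float(s3[i]), i) for i in np.flatnonzero(s3 >= profile.threshold)]
    best = None
    for sc5, i5 in hits5:
        core_start = i5 + w5
        for sc3, i3 in hits3:
            if i3 <= core_start or i3 - core_start > profile.max_barcode_len:
                continue
            key = (-(sc5 + sc3), core_start)
            if best is None or key < best[0]:
                best = (key, (core_start, i3))
    if best is not None:
        start, end = best[1]
        return (-best[0][0], seq[start:end], False)
    # partial: one flank found and the contig end truncates where the other
    # flank would sit
    if hits5:
        sc5, i5 = max(hits5, key=lambda h: (h[0], -h[1]))
        start = i5 + w5
        remaining = len(seq) - start
        if 0 < remaining < profile.max_barcode_len + w3:
            return (sc5, seq[start:], True)
    if hits3:
        sc3, i3 = max(hits3, key=lambda h: (h[0], -h[1]))
        if 0 < i3 < profile.max_barcode_len + w5:
            return (sc3, seq[:i3], True)
    return None


def annotate_its2(contig: Contig, flank_profile: FlankProfile | None = None) -> BarcodeCandidate | None:
    """Locate ITS2 between the 5.8S tail and 28S head profiles.

    Returns the enclosed region when both flanks score above threshold in
    consistent order; a candidate flagged partial when the contig truncates
    one flank; None otherwise.
    """
    profile = flank_profile or FlankProfile.default()
    plus = _annotate_one_orientation(contig.seq, profile)
    minus = _annotate_one_orientation(revcomp(contig.seq), profile)

    def rank(res, strand):
        if res is None:
            return None
        score, seq, partial = res
        # complete beats partial, then score, then + strand
        return ((0 if not partial else 1, -score, strand), seq, partial, strand)

    options = [r for r in (rank(plus, "+"), rank(minus, "-")) if r is not None]
    if not options:
        return None
    _, seq, partial, strand = min(options)
    if not seq:
        return None
    return BarcodeCandidate(
        locus="ITS2",
        seq=seq,
        source_contig_id=contig.contig_id,
        extraction_method="flank_profile",
        strand=strand,
        partial=partial,
    )


def extract_candidates(
    contigs: list[Contig],
    primers: dict[str, PrimerPair] | None = None,
    flank_profile: FlankProfile | None = None,
    max_mismatch: int = 3,
    min_len: int = 60,
) -> list[BarcodeCandidate]:
    """Run the locus-appropriate extractor over a contig list; candidates
    shorter than min_len (uninformative scraps, mostly truncated flank hits)
    are discarded."""
    primers = primers or DEFAULT_PRIMERS
    out = []
    for contig in contigs:
        if contig.locus == "ITS2":
            cand = annotate_its2(contig, flank_profile)
        else:
            pair = primers.get(contig.locus)
            if pair is None:
                continue
            cand = extract_interprimer(contig, pair, max_mismatch)
        if cand is not None and len(cand.seq) >= min_len:
            out.append(cand)
    return out


def screen_bimeras(candidates: list[BarcodeCandidate], refdb) -> list[BarcodeCandidate]:
    """Post-annotation chimera screen: drop candidates whose two halves best-hit
    references from different genera. Partial candidates are left alone (their
    halves are not independently informative)."""
    from .taxonomy import best_hit_genus

    kept = []
    for cand in candidates:
        if cand.partial or len(cand.seq) < 60:
            kept.append(cand)
            continue
        mid = len(cand.seq) // 2
        g1 = best_hit_genus(cand.seq[:mid], cand.locus, refdb)
        g2 = best_hit_genus(cand.seq[mid:], cand.locus, refdb)
        if g1 is not None and g2 is not None and g1 != g2:
            continue
        kept.append(cand)
    return kept
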