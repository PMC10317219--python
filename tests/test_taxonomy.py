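"""Overlap alignment, top-percent LCA assignment, detection matrix, community."""

import numpy as np
import pytest

from shotgunbarcode.otu import Otu
from shotgunbarcode.reference import RANKS, lca
from shotgunbarcode.taxonomy import (
    Hit,
    align_otu,
    align_pair,
    assign_taxon,
    build_detection_matrix,
    community_report,
)


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def oracle_overlap_score(a, b, match=1, mismatch=-1, open_=-2, extend=-1):
    """Independent affine-gap overlap DP: free end gaps, gap of length g costs
    open + (g-1)*extend; returns the optimal score."""
    NEG = -1e9
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    M[:, 0] = 0.0  # free leading end gaps
    M[0, :] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + extend)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + extend)
    best = max(M[n, :].max(), M[:, m].max(), 0.0)
    return best


def _otu(seq, oid="OTU_ITS2_000", locus="ITS2", validated=True, partial=False, reads=0):
    o = Otu(otu_id=oid, locus=locus, rep_seq=seq, member_count=1,
            validated=validated, partial=partial, mapped_reads=reads)
    return o


class TestAlignment:
    def test_identical_sequences(self):
        rng = np.random.default_rng(50)
        s = rand_seq(rng, 240)
        identity, diffs, span, score = align_pair(s, s)
        assert identity == 1.0 and diffs == 0 and span == 240 and score == 240

    def test_four_substitutions_counted(self):
        rng = np.random.default_rng(51)
        s = rand_seq(rng, 240)
        t = list(s)
        for pos in (30, 90, 150, 210):
            t[pos] = "ACGT"[("ACGT".index(t[pos]) + 1) % 4]
        identity, diffs, span, _ = align_pair(s, "".join(t))
        assert diffs == 4
        assert identity == pytest.approx(1 - 4 / span)

    def test_scores_match_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(52)
        for _ in range(30):
            n1, n2 = rng.integers(60, 140, 2)
            a, b = rand_seq(rng, int(n1)), rand_seq(rng, int(n2))
            *_, score = align_pair(a, b)
            assert score == pytest.approx(oracle_overlap_score(a, b))

    def test_scores_match_dp_oracle_on_related_pairs(self):
        rng = np.random.default_rng(53)
        for _ in range(20):
            a = rand_seq(rng, 160)
            b = list(a)
            for _ in range(4):
                b[int(rng.integers(0, len(b)))] = "ACGT"[rng.integers(0, 4)]
            if rng.random() < 0.5:
                pos = int(rng.integers(10, 150))
                b = b[:pos] + b[pos + 2 :]  # deletion of 2 nt
            b = "".join(b)
            *_, score = align_pair(a, b)
            assert score == pytest.approx(oracle_overlap_score(a, b))


class TestAlignOtu:
    def test_exact_reference_ranks_first(self, refdb):
        rep = refdb.get("canarium_album", "ITS2").barcode_seq
        hits = align_otu(_otu(rep), refdb)
        assert hits[0].taxon_id == "canarium_album"
        assert hits[0].identity == 1.0
        assert hits[0].base_differences == 0
        assert hits == sorted(hits, key=lambda h: (-h.identity, h.taxon_id))

    def test_unrelated_references_do_not_hit(self, refdb):
        rng = np.random.default_rng(54)
        hits = align_otu(_otu(rand_seq(rng, 230)), refdb)
        assert all(h.identity < 0.9 for h in hits)


def _hit(tid, identity, oid="OTU_ITS2_000"):
    span = 1000
    diffs = round((1 - identity) * span)
    return Hit(oid, tid, 1 - diffs / span, diffs, span)


class TestAssignTaxon:
    def test_single_perfect_hit_gives_species(self, refdb):
        a = assign_taxon([_hit("panax_quinquefolius", 1.0)], refdb)
        assert (a.rank, a.taxon) == ("species", "Panax quinquefolius")

    def test_equal_congeneric_hits_give_genus(self, refdb):
        hits = [_hit("panax_quinquefolius", 1.0), _hit("panax_ginseng", 1.0)]
        a = assign_taxon(hits, refdb)
        assert (a.rank, a.taxon) == ("genus", "Panax")
        assert a.n_hits_used == 2

    def test_top_percent_window_excludes_weaker_hit(self, refdb):
        hits = [_hit("panax_quinquefolius", 0.999), _hit("panax_ginseng", 0.985)]
        a = assign_taxon(hits, refdb, top_percent=1.0)
        # brute-force: kept = identity >= 0.999 - 0.01 -> only the first
        kept = [h for h in hits if h.identity >= 0.999 - 0.01]
        expected = lca([refdb.lineage_of(h.taxon_id) for h in kept])
        assert (a.rank, a.taxon) == expected == ("species", "Panax quinquefolius")

    def test_low_identity_species_demoted_to_genus(self, refdb):
        a = assign_taxon([_hit("panax_quinquefolius", 0.97)], refdb)
        assert (a.rank, a.taxon) == ("genus", "Panax")

    def test_no_surviving_hits_unassigned(self, refdb):
        a = assign_taxon([_hit("panax_quinquefolius", 0.5)], refdb)
        assert a.rank == "unassigned"

    def test_rank_never_deeper_than_lca_of_kept_hits(self, refdb):
        rng = np.random.default_rng(55)
        taxa = list(refdb.taxa)
        depth = {r: i for i, r in enumerate(RANKS)} | {"root": -1, "unassigned": -2}
        for _ in range(50):
            hits = sorted(
                (_hit(t, float(rng.uniform(0.9, 1.0))) for t in
                 rng.choice(taxa, size=rng.integers(1, 4), replace=False)),
                key=lambda h: -h.identity,
            )
            a = assign_taxon(hits, refdb)
            best = max(h.identity for h in hits)
            kept = [h for h in hits if h.identity >= best - 0.01]
            lca_rank = lca([refdb.lineage_of(h.taxon_id) for h in kept])[0]
            assert depth[a.rank] <= depth[lca_rank]

    def test_min_identity_floor_degrades_to_unassigned(self, refdb):
        # thresholds below the top-percent window leave the call unchanged;
        # a floor above every hit extinguishes it
        hits = [_hit("panax_quinquefolius", 0.995), _hit("panax_ginseng", 0.991)]
        low = assign_taxon(hits, refdb, min_identity=0.90)
        lower = assign_taxon(hits, refdb, min_identity=0.95)
        assert (low.rank, low.taxon) == (lower.rank, lower.taxon) == ("genus", "Panax")
        assert assign_taxon(hits, refdb, min_identity=0.999).rank == "unassigned"


class TestDetectionMatrix:
    def test_animal_plant_loci_marked_absent(self, refdb):
        matrix = build_detection_matrix([], {"s1": {"gallus_gallus"}}, ["gallus_gallus"], refdb)
        rows = matrix[matrix.taxon_id == "gallus_gallus"].set_index("locus").status
        assert rows["COI"] == "not_detected"
        for locus in ("ITS2", "psbA-trnH", "matK", "rbcL"):
            assert rows[locus] == "locus_absent"

    def test_validated_species_otu_marks_detected(self, refdb):
        rep = refdb.get("canarium_album", "rbcL").barcode_seq
        otu = _otu(rep, "OTU_rbcL_000", "rbcL")
        from shotgunbarcode.taxonomy import assign_all

        assignment = assign_all([otu], refdb)[otu.otu_id]
        matrix = build_detection_matrix(
            [("s1", otu, assignment)], {"s1": {"canarium_album"}}, ["canarium_album"], refdb
        )
        cell = matrix[(matrix.taxon_id == "canarium_album") & (matrix.locus == "rbcL")]
        assert cell.status.item() == "detected"

    def test_unvalidated_or_partial_otus_do_not_detect(self, refdb):
        rep = refdb.get("canarium_album", "rbcL").barcode_seq
        from shotgunbarcode.taxonomy import assign_all

        for otu in (_otu(rep, "OTU_rbcL_000", "rbcL", validated=False),
                    _otu(rep, "OTU_rbcL_000", "rbcL", partial=True)):
            assignment = assign_all([otu], refdb)[otu.otu_id]
            matrix = build_detection_matrix(
                [("s1", otu, assignment)], {"s1": {"canarium_album"}}, ["canarium_album"], refdb
            )
            cell = matrix[(matrix.taxon_id == "canarium_album") & (matrix.locus == "rbcL")]
            assert cell.status.item() == "not_detected"

    def test_taxon_outside_design_marked_not_in_sample(self, refdb):
        matrix = build_detection_matrix(
            [], {"s1": {"canarium_album"}}, ["canarium_album", "gallus_gallus"], refdb
        )
        assert set(matrix[matrix.taxon_id == "gallus_gallus"].status) == {"not_in_sample"}


class TestCommunityReport:
    def test_constructed_fungal_percentages(self, refdb):
        from shotgunbarcode.taxonomy import assign_all

        schwann = refdb.get("schwanniomyces_occidentalis", "ITS2").barcode_seq
        diaporthe = refdb.get("diaporthe_eres", "ITS2").barcode_seq
        otus = [
            _otu(schwann, "OTU_ITS2_000", reads=215),
            _otu(diaporthe, "OTU_ITS2_001", reads=785),
        ]
        assignments = assign_all(otus, refdb)
        table, ratio = community_report(
            [("s1", o, assignments[o.otu_id]) for o in otus], refdb
        )
        assert dict(zip(table.genus, table.percent_of_fungal)) == {
            "Schwanniomyces": 21.5,
            "Diaporthe": 78.5,
        }
        assert ratio is None  # no labeled plant reads at all -> NA

    def test_unlabeled_to_labeled_ratio(self, refdb):
        from shotgunbarcode.taxonomy import assign_all

        labeled = _otu(refdb.get("canarium_album", "ITS2").barcode_seq, "OTU_ITS2_000", reads=1000)
        unlabeled = _otu(refdb.get("zea_mays", "ITS2").barcode_seq, "OTU_ITS2_001", reads=14)
        assignments = assign_all([labeled, unlabeled], refdb)
        _, ratio = community_report(
            [("s1", o, assignments[o.otu_id]) for o in (labeled, unlabeled)], refdb
        )
        assert ratio == pytest.approx(1.4)

    def test_empty_assignments_give_empty_table(self, refdb):
        table, ratio = community_report([], refdb)
        assert table.empty
        assert ratio is None
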