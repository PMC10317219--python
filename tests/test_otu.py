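"""OTU clustering, read-back pileups, reliability filtering."""

import numpy as np
import pytest

from shotgunbarcode._dna import revcomp
from shotgunbarcode.extraction import BarcodeCandidate
from shotgunbarcode.otu import Otu, cluster_otus, filter_otus, map_reads_to_otu, map_reads_to_otus


def cand(seq, cid="c0", partial=False):
    return BarcodeCandidate("rbcL", seq, cid, "primer", "+", partial)


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def oracle_partition(seqs):
    """All-pairs containment clustering under the stated rule: in order of
    decreasing length (ties lexicographic), each sequence joins the first
    established representative that contains it, else founds its own cluster.
    Returns {representative: member_count}."""
    order = sorted(seqs, key=lambda s: (-len(s), s))
    reps: list[str] = []
    counts: dict[str, int] = {}
    for s in order:
        for r in reps:
            if s in r:
                counts[r] += 1
                break
        else:
            reps.append(s)
            counts[s] = 1
    return counts


class TestClusterOtus:
    def test_identical_sequences_collapse(self):
        rng = np.random.default_rng(40)
        x = rand_seq(rng, 200)
        otus = cluster_otus([cand(x, "a"), cand(x, "b"), cand(x, "c")])
        assert len(otus) == 1
        assert otus[0].member_count == 3

    def test_single_base_difference_separates_otus(self):
        rng = np.random.default_rng(41)
        x = rand_seq(rng, 200)
        y = x[:100] + ("A" if x[100] != "A" else "C") + x[101:]
        assert len(cluster_otus([cand(x), cand(y)])) == 2

    def test_substring_joins_longest_candidate(self):
        rng = np.random.default_rng(42)
        x = rand_seq(rng, 200)
        otus = cluster_otus([cand(x[40:160], "frag"), cand(x, "full")])
        assert len(otus) == 1
        assert otus[0].rep_seq == x
        assert otus[0].member_count == 2

    def test_partition_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(43)
        base = [rand_seq(rng, int(rng.integers(80, 200))) for _ in range(12)]
        seqs = []
        for s in base:
            seqs.append(s)
            if rng.random() < 0.6:
                seqs.append(s)  # duplicate
            if rng.random() < 0.6:
                a = int(rng.integers(0, len(s) // 3))
                seqs.append(s[a : a + 60])  # containment
        rng.shuffle(seqs)
        otus = cluster_otus([cand(s, f"c{i}") for i, s in enumerate(seqs)])
        expected = oracle_partition(seqs)
        assert {o.rep_seq: o.member_count for o in otus} == expected

    def test_member_count_conserved_and_order_invariant(self):
        rng = np.random.default_rng(44)
        seqs = [rand_seq(rng, 120) for _ in range(10)]
        seqs += [seqs[0], seqs[3][10:80]]
        cands = [cand(s, f"c{i}") for i, s in enumerate(seqs)]
        otus = cluster_otus(cands)
        assert sum(o.member_count for o in otus) == len(cands)
        shuffled = list(cands)
        rng.shuffle(shuffled)
        otus2 = cluster_otus(shuffled)
        assert {o.rep_seq: o.member_count for o in otus} == {
            o.rep_seq: o.member_count for o in otus2
        }

    def test_mixed_loci_rejected(self):
        a = cand("ACGT" * 30)
        b = BarcodeCandidate("matK", "ACGT" * 30, "c", "primer", "+")
        with pytest.raises(ValueError):
            cluster_otus([a, b])

    def test_empty_input(self):
        assert cluster_otus([]) == []


def _otu(seq, oid="OTU_rbcL_000"):
    return Otu(otu_id=oid, locus="rbcL", rep_seq=seq, member_count=1)


class TestMapReads:
    def test_zero_reads_zero_pileup(self):
        rng = np.random.default_rng(45)
        otu = _otu(rand_seq(rng, 300))
        pile = map_reads_to_otu([], otu)
        assert pile.sum() == 0
        assert otu.coverage == 0.0

    def test_tiling_reads_give_full_coverage_and_oracle_depth(self):
        rng = np.random.default_rng(46)
        rep = rand_seq(rng, 300)
        reads = []
        for start in range(0, 151, 10):
            reads.append((f"r{start}", rep[start : start + 150]))
        otu = _otu(rep)
        pile = map_reads_to_otu(reads, otu)
        # brute-force per-base counting oracle
        oracle = np.zeros(300, dtype=int)
        for start in range(0, 151, 10):
            oracle[start : start + 150] += 1
        assert np.array_equal(pile, oracle)
        assert otu.coverage == 1.0
        assert otu.mean_depth == pytest.approx(sum(len(r) for _, r in reads) / 300, abs=1e-3)

    def test_reverse_complement_reads_map(self):
        rng = np.random.default_rng(47)
        rep = rand_seq(rng, 300)
        otu = _otu(rep)
        pile = map_reads_to_otu([("r", revcomp(rep[50:200]))], otu)
        assert pile[50:200].min() == 1
        assert pile[:50].sum() == 0

    def test_read_with_many_mismatches_unmapped(self):
        rng = np.random.default_rng(48)
        rep = rand_seq(rng, 300)
        read = list(rep[50:200])
        # 20% mismatches, but leave a seed-length stretch intact
        for i in range(20, 150, 5):
            read[i] = "ACGT"[(("ACGT".index(read[i])) + 1) % 4]
        otu = _otu(rep)
        pile = map_reads_to_otu([("r", "".join(read))], otu)
        assert pile.sum() == 0

    def test_pileup_total_equals_mapped_bases(self, refdb, small_sample):
        reps = [
            _otu(refdb.get("ophiopogon_japonicus", "rbcL").barcode_seq, "OTU_rbcL_000"),
            _otu(refdb.get("canarium_album", "rbcL").barcode_seq, "OTU_rbcL_001"),
        ]
        reads = [
            (f"{p[0]}/{i}", s)
            for p in small_sample.pairs[:4000]
            for i, s in ((1, p[1]), (2, p[3]))
        ]
        result = map_reads_to_otus(reads, reps)
        for otu in reps:
            spans = result.spans[otu.otu_id]
            assert result.pileups[otu.otu_id].sum() == sum(e - s for s, e in spans)
            assert result.reads_mapped[otu.otu_id] == len(spans)

    def test_each_read_maps_to_at_most_one_otu(self):
        rng = np.random.default_rng(49)
        rep = rand_seq(rng, 300)
        otus = [_otu(rep, "OTU_rbcL_000"), _otu(rep + "ACGT", "OTU_rbcL_001")]
        result = map_reads_to_otus([("r", rep[100:250])], otus)
        total = sum(result.reads_mapped.values())
        assert total == 1
        # tie on identity -> longer overlap impossible here, so lexicographic id
        assert result.reads_mapped["OTU_rbcL_000"] == 1


class TestFilterOtus:
    @pytest.mark.parametrize(
        "coverage,depth,expected",
        [(1.0, 30.0, True), (0.3, 30.0, False), (1.0, 2.0, False), (0.8, 5.0, True)],
    )
    def test_thresholds_inclusive(self, coverage, depth, expected):
        otu = _otu("ACGT" * 50)
        otu.coverage = coverage
        otu.mean_depth = depth
        validated = filter_otus([otu])
        assert otu.validated is expected
        assert (otu in validated) is expected
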