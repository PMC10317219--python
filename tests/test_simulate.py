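"""Synthetic data generator: determinism, mixture designs, read models."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from shotgunbarcode._dna import revcomp
from shotgunbarcode.reference import ReferenceDB
from shotgunbarcode.simulate import (
    MixtureDesign,
    SimulationConfig,
    default_mock_design,
    generate_reference_fixtures,
    simulate_sample,
    spike_positive_control,
)


class TestFixtures:
    def test_fixture_generation_is_deterministic(self, tmp_path):
        db1, _ = generate_reference_fixtures(42)
        db2, _ = generate_reference_fixtures(42)
        a, b = tmp_path / "a.fasta", tmp_path / "b.fasta"
        db1.save(a, tmp_path / "a.tsv")
        db2.save(b, tmp_path / "b.tsv")
        assert a.read_bytes() == b.read_bytes()

    def test_congeneric_barcodes_differ(self, refdb):
        for a, b in [
            ("panax_quinquefolius", "panax_ginseng"),
            ("scrophularia_ningpoensis", "scrophularia_buergeriana"),
        ]:
            s1 = refdb.get(a, "ITS2").barcode_seq
            s2 = refdb.get(b, "ITS2").barcode_seq
            assert len(s1) == len(s2)
            hamming = sum(x != y for x, y in zip(s1, s2))
            assert hamming >= 1

    def test_roles_cover_the_formula_design(self, refdb):
        labeled = refdb.taxa_with_role("labeled_ingredient")
        assert len(labeled) == 10
        kinds = {refdb.taxa[t].kingdom_class for t in labeled}
        assert kinds == {"plant", "fungus", "animal"}
        assert len(refdb.taxa_with_role("contaminant")) == 3
        assert ("wolfiporia_cocos", "mitochondrion") in refdb.organelles
        mito = refdb.organelles[("wolfiporia_cocos", "mitochondrion")]
        assert any(name == "COX1" for name, *_ in mito.features)


class TestMixtureDesign:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MixtureDesign("x", (("a", 0.5), ("b", 0.6)))

    def test_spike_matches_reference_proportion(self, refdb):
        design = default_mock_design(refdb)
        spiked = spike_positive_control(design, "panax_quinquefolius", "wolfiporia_cocos")
        assert spiked.proportion_of("panax_quinquefolius") == pytest.approx(
            spiked.proportion_of("wolfiporia_cocos")
        )
        assert sum(p for _, p in spiked.components) == pytest.approx(1.0)

    def test_spike_rejects_existing_taxon(self, refdb):
        design = default_mock_design(refdb)
        with pytest.raises(ValueError):
            spike_positive_control(design, "wolfiporia_cocos", "gallus_gallus")

    def test_spike_into_empty_design_is_an_error(self):
        empty = MixtureDesign("x", ())
        with pytest.raises(KeyError):
            spike_positive_control(empty, "a", "b")


class TestSimulation:
    def test_deterministic_given_seed(self, refdb):
        design = default_mock_design(refdb)
        cfg = SimulationConfig(n_read_pairs=2000, seed=7)
        s1 = simulate_sample(design, cfg, refdb)
        s2 = simulate_sample(design, cfg, refdb)
        assert s1.pairs == s2.pairs
        assert s1.truth.equals(s2.truth)

    def test_rejects_nonpositive_pair_count(self, refdb):
        with pytest.raises(ValueError):
            simulate_sample(
                default_mock_design(refdb), SimulationConfig(n_read_pairs=0), refdb
            )

    def test_zero_proportion_taxon_emits_no_reads(self, refdb):
        design = MixtureDesign(
            "z", (("ophiopogon_japonicus", 1.0), ("zea_mays", 0.0)),
            contaminant_fraction=0.0, background_fraction=0.0,
        )
        s = simulate_sample(design, SimulationConfig(n_read_pairs=3000, seed=1), refdb)
        assert (s.truth.taxon_id == "zea_mays").sum() == 0

    def test_truth_table_has_one_row_per_pair(self, small_sample):
        assert len(small_sample.truth) == len(small_sample.pairs)
        assert small_sample.truth.pair_id.is_unique

    def test_error_free_reads_are_exact_substrings_of_origin(self, refdb, small_sample):
        origin = {}
        for (tid, locus), ref in refdb.barcodes.items():
            origin[(tid, f"locus:{locus}")] = ref.context_seq
        for (tid, kind), org in refdb.organelles.items():
            origin[(tid, f"organelle:{kind}")] = org.seq
        truth = small_sample.truth.set_index("pair_id")
        checked = 0
        for pid, s1, _, s2, _ in small_sample.pairs[:500]:
            row = truth.loc[pid]
            if row.taxon_id == "decoy":
                continue
            src = origin[(row.taxon_id, row.source)]
            fragment = src[row.start : row.end]
            for read in (s1, s2):
                assert read in fragment or revcomp(read) in fragment
            checked += 1
        assert checked > 100

    def test_copy_number_skew_drives_locus_read_ratio(self, refdb):
        # one taxon, ITS2 copy weight 100 vs matK forced to 1
        base_its2 = refdb.get("ophiopogon_japonicus", "ITS2")
        base_matk = refdb.get("ophiopogon_japonicus", "matK")
        db = ReferenceDB()
        db.add_taxon(refdb.taxa["ophiopogon_japonicus"])
        db.add_barcode(dataclasses.replace(base_its2, copy_weight=100.0))
        db.add_barcode(dataclasses.replace(base_matk, copy_weight=1.0))
        design = MixtureDesign(
            "skew", (("ophiopogon_japonicus", 1.0),),
            contaminant_fraction=0.0, background_fraction=0.0,
        )
        n = 100_000
        s = simulate_sample(design, SimulationConfig(n_read_pairs=n, seed=3), db)
        counts = s.truth.groupby("source").size()
        n_its2 = counts.get("locus:ITS2", 0)
        p = 100.0 / 101.0
        sd = np.sqrt(n * p * (1 - p))
        assert abs(n_its2 - n * p) <= 3 * sd

    def test_empirical_error_rate_matches_configuration(self, refdb):
        design = MixtureDesign(
            "err", (("gallus_gallus", 1.0),),
            contaminant_fraction=0.0, background_fraction=0.0,
        )
        rate = 0.004
        cfg = SimulationConfig(n_read_pairs=4000, seed=5, substitution_rate=rate)
        s = simulate_sample(design, cfg, refdb)
        src = refdb.get("gallus_gallus", "COI").context_seq
        truth = s.truth.set_index("pair_id")
        mismatches = bases = 0
        for pid, s1, _, s2, _ in s.pairs:
            row = truth.loc[pid]
            fragment = src[row.start : row.end]
            top, bottom = fragment[:150], revcomp(fragment[-150:])
            exp1, exp2 = (top, bottom) if row.strand == "+" else (bottom, top)
            for read, expected in ((s1, exp1), (s2, exp2)):
                mismatches += sum(a != b for a, b in zip(read, expected))
                bases += len(read)
        assert bases >= 1_000_000
        empirical = mismatches / bases
        assert abs(empirical - rate) / rate < 0.10

    def test_truth_marginals_match_design(self, refdb, mock_designs, mock_samples):
        design = mock_designs["mock_a"]
        truth = mock_samples["mock_a"].truth
        main = 1.0 - design.contaminant_fraction - design.background_fraction
        weight = {}
        for tid, prop in design.components:
            w = sum(refdb.get(tid, loc).copy_weight for loc in refdb.loci_of(tid))
            w += 20.0 * sum(1 for (otid, _) in refdb.organelles if otid == tid)
            weight[tid] = prop * w
        total = sum(weight.values())
        expected = {tid: main * w / total for tid, w in weight.items()}
        expected["decoy"] = design.background_fraction
        for tid in refdb.taxa_with_role("contaminant"):
            expected[tid] = design.contaminant_fraction / 3
        observed = truth.groupby("taxon_id").size()
        n = len(truth)
        obs = np.array([observed.get(t, 0) for t in sorted(expected)])
        exp = np.array([expected[t] * n for t in sorted(expected)])
        chi2 = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert chi2.pvalue > 0.001
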