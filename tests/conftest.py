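"""Shared fixtures: the synthetic reference database and a full two-mock-sample
pipeline run at the default study scale (expensive, session-scoped)."""

from __future__ import annotations

import dataclasses

import pytest

from shotgunbarcode.pipeline import PipelineParams, run_samples
from shotgunbarcode.preprocess import ReadPair
from shotgunbarcode.simulate import (
    SimulationConfig,
    default_mock_design,
    generate_reference_fixtures,
    simulate_sample,
    spike_positive_control,
)

CONTROL = "panax_quinquefolius"
FUNGUS = "wolfiporia_cocos"
ANIMAL = "gallus_gallus"

#: default study conditions: two mock samples (one carrying the spiked
#: positive control), 100k read pairs each, seed 42
N_PAIRS = 100_000
SEED = 42


@pytest.fixture(scope="session")
def refdb():
    db, _ = generate_reference_fixtures(SEED)
    return db


@pytest.fixture(scope="session")
def mock_designs(refdb):
    plain = default_mock_design(refdb, "mock_a")
    spiked = dataclasses.replace(
        spike_positive_control(plain, CONTROL, FUNGUS), sample_id="mock_b_spiked"
    )
    return {"mock_a": plain, "mock_b_spiked": spiked}


@pytest.fixture(scope="session")
def mock_samples(refdb, mock_designs):
    cfg = SimulationConfig(n_read_pairs=N_PAIRS, seed=SEED)
    return {
        sid: simulate_sample(design, cfg, refdb) for sid, design in mock_designs.items()
    }


@pytest.fixture(scope="session")
def small_sample(refdb, mock_designs):
    """A small error-free sample with truth labels, for oracle-based checks."""
    cfg = SimulationConfig(n_read_pairs=10_000, seed=SEED, substitution_rate=0.0)
    return simulate_sample(mock_designs["mock_a"], cfg, refdb)


@pytest.fixture(scope="session")
def mock_run(refdb, mock_designs, mock_samples):
    """Full pipeline over both mock samples at the default study scale."""
    pairs = {
        sid: [ReadPair(*p) for p in sample.pairs] for sid, sample in mock_samples.items()
    }
    composition = {
        sid: [t for t, _ in design.components] for sid, design in mock_designs.items()
    }
    return run_samples(refdb, pairs, PipelineParams(), composition)
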