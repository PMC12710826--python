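"""Shared fixtures: simulations and trained models are session-scoped so the
expensive CNN fits run once for the whole suite."""

import numpy as np
import pytest

from svcontext.cnn import CNNSpec, TrainConfig
from svcontext.models import build_windows_and_features, train_model_bundle
from svcontext.simulate import SimulationConfig, simulate_fixture

#: desk-scale architecture used by all fixture experiments (see docs/methods.md)
FIXTURE_SPEC = dict(context_length=100, stem_channels=48,
                    bottleneck_channels=16, hidden_units=64)
FIXTURE_LR = 1e-3
CONTEXT = 100


def _train(sim, seed, max_epochs):
    windows, table = build_windows_and_features(
        sim.reference, sim.records, sim.annotation_bundle(), CONTEXT, seed=seed)
    spec = CNNSpec(**FIXTURE_SPEC)
    tc = TrainConfig(learning_rate=FIXTURE_LR, batch_size=128,
                     max_epochs=max_epochs, seed=seed)
    bundle = train_model_bundle(windows, table, spec, tc, seed=seed)
    return windows, table, bundle


@pytest.fixture(scope="session")
def te_sim():
    """1000 TE insertions carrying the planted TAAAA endonuclease motif."""
    cfg = SimulationConfig(
        seed=7, chrom_length=400_000,
        n_sv_per_class={"te_insertion": 1000, "deletion_mh": 0,
                        "simple_repeat": 0, "inversion": 0})
    return simulate_fixture(cfg)


@pytest.fixture(scope="session")
def te_trained(te_sim):
    return _train(te_sim, seed=7, max_epochs=15)


@pytest.fixture(scope="session")
def mh_sim():
    """1000 deletions with 8 bp breakpoint-spanning microhomology."""
    cfg = SimulationConfig(
        seed=11, chrom_length=400_000,
        n_sv_per_class={"te_insertion": 0, "deletion_mh": 1000,
                        "simple_repeat": 0, "inversion": 0})
    return simulate_fixture(cfg)


@pytest.fixture(scope="session")
def mh_trained(mh_sim):
    return _train(mh_sim, seed=11, max_epochs=20)


@pytest.fixture(scope="session")
def mixed_sim():
    """TE insertions (sequence-determined) plus inversions (hotspot-driven)."""
    cfg = SimulationConfig(
        seed=13, chrom_length=400_000,
        n_sv_per_class={"te_insertion": 500, "deletion_mh": 0,
                        "simple_repeat": 0, "inversion": 300})
    return simulate_fixture(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """All four SV classes at the generator's default study conditions."""
    return simulate_fixture(SimulationConfig(seed=42))


@pytest.fixture
def tiny_reference():
    rng = np.random.default_rng(0)
    return {"chrT": "".join(rng.choice(list("ACGT"), size=10_000))}
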