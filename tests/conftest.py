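import numpy as np
import pytest

from utrtune import flow, synth


@pytest.fixture(scope="session")
def untransfected_ref():
    """Shared untransfected reference sample for BFP gating."""
    return synth.simulate_flow_sample(synth.FlowSimConfig(
        n_events=50_000, transfected_fraction=0.0, seed=9001))


@pytest.fixture(scope="session")
def gating():
    return flow.GatingConfig()


@pytest.fixture(scope="session")
def gated_control(untransfected_ref, gating):
    """Gated dosage-1 control sample."""
    table = synth.simulate_flow_sample(synth.FlowSimConfig(
        n_events=100_000, dosage=1.0, seed=9002))
    return flow.gate_events(table, gating, untransfected_ref)


def gate_sample(dosage, seed, n_events, ref, cfg):
    table = synth.simulate_flow_sample(synth.FlowSimConfig(
        n_events=n_events, dosage=dosage, seed=seed))
    return flow.gate_events(table, cfg, ref)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
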