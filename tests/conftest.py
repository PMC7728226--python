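import numpy as np
import pytest

from rulewarp import synth


@pytest.fixture(scope="session")
def small_session():
    """Six-block session from the default agent, with ground truth."""
    return synth.simulate_behavior(synth.AgentSpec(), n_blocks=6, seed=11)


@pytest.fixture(scope="session")
def fixture_suite():
    return synth.make_fixture_suite(seed=7)


@pytest.fixture(scope="session")
def warped_bundle():
    """A 40-block session with spikes from the representational-warping
    generator (shared by the geometry recovery tests)."""
    trials, truth = synth.simulate_behavior(synth.AgentSpec(), n_blocks=40, seed=1)
    spikes, ntruth = synth.simulate_neurons(
        trials, truth, synth.warping_tuning(), seed=2,
        with_presentation_epochs=False)
    return trials, truth, spikes, ntruth


@pytest.fixture(scope="session")
def null_bundle():
    """Same session under the state-independent (no-warping) generator."""
    trials, truth = synth.simulate_behavior(synth.AgentSpec(), n_blocks=40, seed=1)
    spikes, ntruth = synth.simulate_neurons(
        trials, truth, synth.null_tuning(), seed=2,
        with_presentation_epochs=False)
    return trials, truth, spikes, ntruth
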