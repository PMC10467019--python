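"""Shared fixtures: small simulations and the full four-condition protocol.

The protocol fixture is expensive (4 conditions x 30 trials) and session-
scoped; acceptance tests that compare conditions share it.
"""

import numpy as np
import pytest

from fdgscape import (
    ExperimentConfig,
    StimulusSpec,
    detect_spikes,
    human_like,
    make_frozen_noise,
    run_protocol,
    simulate,
)

BASE_SEED = 100  # default trial-seed origin used throughout


@pytest.fixture(scope="session")
def human_model():
    return human_like()


@pytest.fixture(scope="session")
def short_sim(human_model):
    """One 2500 ms trial of the default model at a moderate DC."""
    stim = make_frozen_noise(StimulusSpec(seed=BASE_SEED, dc_nA=0.01))
    sim = simulate(human_model, stim)
    return stim, sim


@pytest.fixture(scope="session")
def short_train(short_sim):
    _, sim = short_sim
    return detect_spikes(sim.v_mV, sim.time_ms)


@pytest.fixture(scope="session")
def protocol_reports():
    """Four-condition (Ih x {0, 0.5, 1, 2}) protocol at the default settings."""
    config = ExperimentConfig(base_seed=BASE_SEED, n_trials=30)
    return run_protocol(config)
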