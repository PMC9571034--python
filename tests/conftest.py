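"""Shared fixtures: small seeded synthetic populations and one trained
channel classifier, built once per session because simulation and
training dominate the suite's runtime."""

from __future__ import annotations

import numpy as np
import pytest

import epichannel as ec

GROUP1 = ("mean", "min", "skew", "kurt", "theta")


@pytest.fixture(scope="session")
def sim_config():
    return ec.SimulationConfig()


@pytest.fixture(scope="session")
def focal_bipolar(sim_config):
    return [
        ec.compute_lb(r)
        for r in ec.simulate_population(12, "focal", sim_config, seed=101)
    ]


@pytest.fixture(scope="session")
def normal_bipolar(sim_config):
    return [
        ec.compute_lb(r)
        for r in ec.simulate_population(12, "normal", sim_config, seed=202)
    ]


@pytest.fixture(scope="session")
def group1_sequences(focal_bipolar, normal_bipolar):
    return ec.training_sequences(
        focal_bipolar, normal_bipolar, feature_subset=GROUP1
    )


@pytest.fixture(scope="session")
def trained_results(group1_sequences):
    config = ec.NetworkConfig(hidden_units=32, seed=11)
    return ec.ChannelSequenceClassifier(group1_sequences, config).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
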