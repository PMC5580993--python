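"""Shared fixtures: small seeded synthetic datasets."""

import dataclasses

import numpy as np
import pytest

import seedfolio as sf


@pytest.fixture(scope="session")
def small_config() -> sf.GenConfig:
    return sf.GenConfig(n_varieties=12, n_farms=15, n_subregions=20, seed=1)


@pytest.fixture(scope="session")
def small_data(small_config):
    """(experiment, region, truth) at desk scale, seed 1."""
    return sf.simulate(small_config)


@pytest.fixture(scope="session")
def noiseless_config() -> sf.GenConfig:
    return sf.GenConfig(n_varieties=8, n_farms=12, n_subregions=15,
                        noise_sd=0.0, duplicate_rate=0.0,
                        missing_pi_rate=0.0, seed=5)


@pytest.fixture(scope="session")
def noiseless_data(noiseless_config):
    """Deterministic yields: noise and the random G×E term switched off."""
    truth = sf.generate_truth(noiseless_config, gxe_sd=0.0)
    experiment = sf.generate_experiment(noiseless_config, truth)
    region = sf.generate_region(noiseless_config, truth)
    return experiment, region, truth


@pytest.fixture(scope="session")
def preprocessed(small_data):
    experiment, _, _ = small_data
    table, kept = sf.preprocess(experiment, 0.9)
    X, y = sf.assemble_features(table)
    return table, X, y, kept
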