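"""Shared fixtures: the toy bank, training data, and the (expensive)
benchmark sweep, each built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from mmpc import (
    RunConfig,
    build_weight_map,
    generate_training_design,
    make_toy_bank,
    simulate_training_data,
)


@pytest.fixture(scope="session")
def bank_and_plant():
    return make_toy_bank(seed=0)


@pytest.fixture(scope="session")
def bank(bank_and_plant):
    return bank_and_plant[0]


@pytest.fixture(scope="session")
def plant(bank_and_plant):
    return bank_and_plant[1]


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def training_design(run_config):
    return generate_training_design(run_config.space)


@pytest.fixture(scope="session")
def plant_dataset(plant, training_design):
    """Noisy training data generated from the designated plant."""
    return simulate_training_data(
        plant, training_design, noise_sd=0.05, n_timepoints=8, seed=1
    )


@pytest.fixture(scope="session")
def plant_weight_map(bank, plant, plant_dataset, run_config):
    """Weight map for the two non-plant members, trained on plant data."""
    others = [m for m in bank if m.model_id != plant.model_id]
    return build_weight_map(others, plant_dataset, run_config.space)


@pytest.fixture(scope="session")
def full_sweep(bank, run_config):
    """The complete 3-plant x 10-target benchmark sweep (runs once)."""
    from mmpc.benchmark import run_benchmark

    return run_benchmark(bank, seed=1, noise_sd=0.05, cfg=run_config)
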