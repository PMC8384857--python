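import numpy as np
import pytest

from advpes import (
    AttackConfig,
    CommitteeModel,
    DoubleWell,
    TrainConfig,
    partition_normalizer,
    sample_initial_dataset,
)


@pytest.fixture(scope="session")
def double_well():
    return DoubleWell()


@pytest.fixture(scope="session")
def left_basin_dataset(double_well):
    """Initial dataset of the double-well protocol: up to 800 uniform points,
    energy filter E < -2 (keeps only the deeper left basin)."""
    return sample_initial_dataset(double_well, n_max=800, filter_max_energy=-2.0, seed=42)


@pytest.fixture(scope="session")
def trained_committee(left_basin_dataset):
    """Committee of five members fitted to left-basin data only."""
    return CommitteeModel(left_basin_dataset, TrainConfig(seed=7)).fit()


@pytest.fixture(scope="session")
def toy_normalizer(left_basin_dataset):
    return partition_normalizer(left_basin_dataset, kT=5.0)


@pytest.fixture(scope="session")
def attack_config():
    return AttackConfig(sigma_delta=0.01, kT=5.0, lr=3e-3, n_steps=600, seed=11)
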