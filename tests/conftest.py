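"""Shared fixtures: small synthetic arrays generated at test time."""

import numpy as np
import pytest

from seroarray import SimulationConfig, simulate_profiles


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    """Small noise-free, unrotated array: 30 antigens on a 2x2 subgrid layout."""
    return SimulationConfig(
        n_antigens=30,
        n_subgrid_rows=2,
        n_subgrid_cols=2,
        spots_per_subgrid=16,
        n_group1=5,
        n_group2=5,
        noise_sd=0.0,
        rotation_deg=0.0,
        background_gradient=0.0,
        seed=101,
    )


@pytest.fixture(scope="session")
def clean_sim(clean_config):
    return simulate_profiles(clean_config)


@pytest.fixture(scope="session")
def noisy_config() -> SimulationConfig:
    """Realistic small array: pixel noise sd 10, 1 degree scan rotation."""
    return SimulationConfig(
        n_antigens=60,
        n_subgrid_rows=2,
        n_subgrid_cols=2,
        spots_per_subgrid=36,
        n_group1=5,
        n_group2=5,
        noise_sd=10.0,
        rotation_deg=1.0,
        background_gradient=0.02,
        seed=202,
    )


@pytest.fixture(scope="session")
def noisy_sim(noisy_config):
    return simulate_profiles(noisy_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
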