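"""Shared fixtures: synthetic reactions with known ground truth."""

import numpy as np
import pytest

from dropstat.synth import SyntheticSpec, generate_reaction


@pytest.fixture(scope="session")
def clean_bimodal():
    """Clean two-population reaction at half-occupancy, no rain, no tails."""
    spec = SyntheticSpec(n_droplets=20000, lambda_true=0.7, seed=11)
    table, truth = generate_reaction(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def rainy_reaction():
    """Reaction with 2% of occupied droplets reading out as rain."""
    spec = SyntheticSpec(n_droplets=20000, lambda_true=0.7, rain_fraction=0.02, seed=12)
    table, truth = generate_reaction(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def trimodal_reaction():
    """Reaction with a third (co-amplification) population between the clouds."""
    spec = SyntheticSpec(
        n_droplets=20000,
        lambda_true=0.7,
        extra_population=(3000.0, 120.0, 0.3),
        seed=13,
    )
    table, truth = generate_reaction(spec)
    return spec, table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
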