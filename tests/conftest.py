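"""Shared fixtures: toy structures and conformer pools at several scales.

Session-scoped where construction is expensive; all fixtures are
deterministic (fixed seeds) so every test run sees identical inputs.
"""

import numpy as np
import pytest

from rdcsel.ga import GAConfig
from rdcsel.pool import (
    default_angle_grid,
    default_rdc_keys,
    generate_hinge_pool,
    make_toy_structure,
    precompute_pool_rdcs,
)


@pytest.fixture(scope="session")
def toy():
    """Open-state toy structure and its domain definition."""
    return make_toy_structure()


@pytest.fixture(scope="session")
def toy_closed():
    return make_toy_structure(preset="closed")


@pytest.fixture(scope="session")
def toy_keys(toy):
    structure, _ = toy
    return default_rdc_keys(structure)


@pytest.fixture(scope="session")
def small_pool(toy, toy_keys):
    """25-conformer pool with cached RDCs (exhaustive-search scale)."""
    structure, domains = toy
    pool = generate_hinge_pool(structure, domains, default_angle_grid(5, 5), rng_seed=0)
    return precompute_pool_rdcs(pool, toy_keys)


@pytest.fixture(scope="session")
def medium_pool(toy, toy_keys):
    """~400-conformer pool for distribution and validation tests."""
    structure, domains = toy
    pool = generate_hinge_pool(
        structure, domains, default_angle_grid(20, 20), jitter=0.5, rng_seed=1
    )
    return precompute_pool_rdcs(pool, toy_keys)


@pytest.fixture(scope="session")
def scaled_pool(toy, toy_keys):
    """~2000-conformer pool: the desk-scale study condition."""
    structure, domains = toy
    pool = generate_hinge_pool(
        structure, domains, default_angle_grid(45, 45), jitter=0.7, rng_seed=1
    )
    return precompute_pool_rdcs(pool, toy_keys)


@pytest.fixture()
def quick_ga():
    """GA schedule for fast unit tests (not the scaled study preset)."""
    return GAConfig(n_ensembles=100, n_steps=150, n_repeats=3, rng_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
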