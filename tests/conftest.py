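"""Shared fixtures: small synthetic worlds built once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from hydrisk.synthetic import SyntheticWorldConfig, simulate_world


@pytest.fixture(scope="session")
def world():
    """Default synthetic world (the study conditions), seed 0."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_world(SyntheticWorldConfig(seed=0))


@pytest.fixture(scope="session")
def small_world():
    """Smaller world for quick model-path tests."""
    cfg = SyntheticWorldConfig(
        seed=7,
        n_genera=30,
        species_per_genus_mean=3.0,
        grid_shape=(20, 20),
        observed_fraction=0.5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_world(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
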