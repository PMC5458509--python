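"""Shared fixtures: small simulated pools and libraries, generated fresh."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from ppiseq import simulate


@pytest.fixture(scope="session")
def small_config() -> simulate.SimConfig:
    """3x3 genotypes x 2x2 barcodes = 36 lineages, modest depth."""
    return simulate.SimConfig(
        n_bait=3,
        n_prey=3,
        barcodes_per_bait=2,
        barcodes_per_prey=2,
        fitness_map={(1, 1): 0.1, (2, 2): 0.3, (1, 2): 0.05},
        bottleneck_size=100_000,
        reads_per_barcode=100.0,
        chimera_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate.simulate_pool(small_config, seed=7)


@pytest.fixture(scope="session")
def small_library(small_sim):
    return small_sim.to_library()


@pytest.fixture(scope="session")
def sparse_chimeric_sim():
    """Half-occupied barcode cross with a high chimera rate.

    Leaves off-target landing space so chimeras are observable.
    """
    cfg = simulate.SimConfig(
        n_bait=3,
        n_prey=3,
        barcodes_per_bait=2,
        barcodes_per_prey=2,
        fitness_map={(1, 1): 0.1},
        bottleneck_size=100_000,
        reads_per_barcode=200.0,
        chimera_rate=0.1,
        library_fraction=0.5,
        seed=11,
    )
    return simulate.simulate_pool(cfg, seed=11)


@pytest.fixture(scope="session")
def experiment_config() -> simulate.SimConfig:
    return simulate.default_experiment_config()


@pytest.fixture(scope="session")
def neutral_experiment_config(experiment_config) -> simulate.SimConfig:
    return replace(experiment_config, fitness_map={})
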