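"""Shared fixtures: deterministic random sequences and simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from retropap.synthetic import SimConfig, simulate_dataset

SMALL_TREE = "((REF:0.0,ACC01:0.5,ACC02:0.5):0.0,(ACC03:1,(ACC04:1,ACC05:1):1):3);"


def rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down study conditions for fast unit tests."""
    return SimConfig(seed=5, n_chromosomes=2, chromosome_length_bp=150_000,
                     n_genes=30, n_elements=8, accession_tree=SMALL_TREE,
                     assembly_n50_target_bp=50_000)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_dataset(small_config)
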