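"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

from wgdkit import EvolutionParams, simulate_paleotetraploid


@pytest.fixture(scope="session")
def small_dataset():
    """2 chromosomes x 60 genes, paper-like divergences, fixed seed."""
    params = EvolutionParams(n_chromosomes=2, genes_per_chromosome=60, seed=7)
    return simulate_paleotetraploid(params)


@pytest.fixture(scope="session")
def lossless_dataset():
    """No fractionation, no rearrangement: every ancestral gene keeps 2 copies."""
    params = EvolutionParams(
        n_chromosomes=2, genes_per_chromosome=30, loss_probability=0.0, seed=3
    )
    return simulate_paleotetraploid(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
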