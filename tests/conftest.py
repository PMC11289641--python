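import numpy as np
import pandas as pd
import pytest

from readerdecay.normalization import CountTable
from readerdecay.synthetic import SimConfig, simulate_genome, simulate_truth


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_genes=200, seed=7)


@pytest.fixture(scope="session")
def small_world(small_config):
    """(models, sizes, truth) for a 200-gene simulation, shared per session."""
    models, sizes = simulate_genome(small_config)
    truth = simulate_truth(small_config, models)
    return models, sizes, truth


def make_table(counts: dict, samples: pd.DataFrame | None = None) -> CountTable:
    """Tiny count table from {sample: {feature: count}} mappings."""
    df = pd.DataFrame(counts, dtype=float)
    return CountTable(counts=df, samples=samples)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
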