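import numpy as np
import pytest

from combosyn.data import DatasetConfig, assemble_dataset
from combosyn.simulate import SimConfig, simulate_tables


@pytest.fixture(scope="session")
def small_tables():
    """Small synthetic tables: 6 cells, 12 drugs, 80 triples."""
    cfg = SimConfig(n_cells=6, n_drugs=12, n_triples=80, seed=11)
    return cfg, *simulate_tables(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_tables):
    _, expr, drugs, combos = small_tables
    ds = assemble_dataset(expr, drugs, combos, DatasetConfig(grid_size=32))
    return ds, expr


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
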