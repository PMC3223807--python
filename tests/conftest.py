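import numpy as np
import pytest

from funcequiv.data_model import BiomassTable, DiscreteDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """Tiny biomass table: 6 years, 3 species, strictly positive values."""
    years = np.arange(2000, 2006)
    values = np.array([
        [1.0, 10.0, 5.0],
        [2.0, 9.0, 6.0],
        [3.0, 8.0, 4.0],
        [4.0, 7.0, 8.0],
        [5.0, 6.0, 3.0],
        [6.0, 5.0, 7.0],
    ])
    return BiomassTable("toy", years, ["cod", "herring", "skate"], values)


@pytest.fixture
def binary_pair_dataset():
    """Two binary variables with a strong A -> B dependence, M = 12."""
    a = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
    b = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 0])
    return DiscreteDataset(["a", "b"], np.array([2, 2]),
                           np.column_stack([a, b]))


def make_dataset(columns: dict, arities=None) -> DiscreteDataset:
    names = list(columns)
    records = np.column_stack([np.asarray(columns[n], dtype=int)
                               for n in names])
    if arities is None:
        arities = records.max(axis=0) + 1
        arities = np.maximum(arities, 2)
    return DiscreteDataset(names, np.asarray(arities), records)
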