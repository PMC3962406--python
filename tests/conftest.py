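import numpy as np
import pytest

from octofactor import datasets
from octofactor.multivariate import ExpressionMatrix


@pytest.fixture(scope="session")
def gender_table():
    """90-protein male/female ethanol-response fixture."""
    return datasets.load_gender_table()


@pytest.fixture(scope="session")
def interaction_table():
    """45-protein ethanol vs knockout+ethanol fixture with printed labels."""
    return datasets.load_interaction_table()


@pytest.fixture(scope="session")
def regulator_network():
    return datasets.load_regulator_network()


def make_matrix(values, keys=None, mask=None):
    """ExpressionMatrix from a plain array, with throwaway protein ids."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    keys = keys or [f"{115 + j}:114" for j in range(p)]
    mask = np.zeros_like(values, dtype=bool) if mask is None else mask
    return ExpressionMatrix(values, mask, [f"prot{i}" for i in range(n)], keys)
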