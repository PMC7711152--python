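import numpy as np
import pandas as pd
import pytest

from deepamend import OtuTable, RelativeAbundanceTable
from deepamend.synth import succession_fixture


@pytest.fixture(scope="session")
def succession():
    """The canonical five-incubation fixture (table, metadata)."""
    return succession_fixture()


@pytest.fixture()
def small_table():
    """5 samples × 10 OTUs with exactly 3 dataset-wide singletons (x7, x8, x9)."""
    counts = np.array(
        [
            [10, 5, 0, 2, 1, 3, 0, 1, 0, 0],
            [8, 0, 4, 2, 1, 3, 0, 0, 0, 0],
            [6, 5, 4, 0, 1, 3, 2, 0, 1, 0],
            [10, 5, 4, 2, 1, 0, 2, 0, 0, 0],
            [10, 5, 4, 2, 0, 3, 2, 0, 0, 1],
        ],
        dtype=np.int64,
    )
    ids = [f"s{i}" for i in range(5)]
    otus = [f"x{j}" for j in range(10)]
    return OtuTable(pd.DataFrame(counts, index=ids, columns=otus))


def random_relative_table(rng, n_samples, n_otus, index_prefix="s"):
    x = rng.gamma(2.0, size=(n_samples, n_otus))
    x /= x.sum(axis=1, keepdims=True)
    return RelativeAbundanceTable(
        pd.DataFrame(x, index=[f"{index_prefix}{i}" for i in range(n_samples)])
    )
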