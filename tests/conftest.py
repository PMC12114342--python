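import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from wetmicro import AbundanceTable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def small_table():
    """4 samples x 5 taxa with simple integer counts and metadata."""
    counts = pd.DataFrame(
        [[5, 3, 2, 0, 0],
         [1, 1, 2, 5, 0],
         [0, 4, 4, 0, 2],
         [2, 2, 2, 2, 2]],
        index=["S1", "S2", "S3", "S4"],
        columns=[f"t{i}" for i in range(1, 6)],
    )
    meta = pd.DataFrame(
        {"treatment": ["CK", "CK", "L", "L"],
         "flooding": ["LO", "LO", "LO", "LO"]},
        index=counts.index,
    )
    return AbundanceTable(counts, meta)


@pytest.fixture(scope="session")
def fixture_tree():
    from wetmicro import datasets
    return datasets.load_tree()


@pytest.fixture(scope="session")
def neutral_table():
    from wetmicro import datasets
    return datasets.load_neutral_table()


@pytest.fixture(scope="session")
def selection_table():
    from wetmicro import datasets
    return datasets.load_selection_table()
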