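import numpy as np
import pandas as pd
import pytest

from phyllomatch import FunctionHierarchy, FunctionTable


@pytest.fixture
def small_table() -> FunctionTable:
    """3 samples x 4 genes, two hosts (one duplicated)."""
    df = pd.DataFrame(
        [[30, 5, 10, 5], [28, 6, 11, 5], [2, 40, 3, 5]],
        index=["s1", "s2", "s3"],
        columns=["g1", "g2", "g3", "g4"],
    )
    return FunctionTable(
        df, level="gene", sample_to_host={"s1": "hA", "s2": "hA", "s3": "hB"}
    )


@pytest.fixture
def small_hierarchy() -> FunctionHierarchy:
    return FunctionHierarchy(
        gene_to_tier3={"g1": "A", "g2": "A", "g3": "B", "g4": "B"},
        tier3_to_tier2={"A": "X", "B": "Y"},
        tier2_to_tier1={"X": "T", "Y": "T"},
    )


def random_table(rng: np.random.Generator, n_samples=None, n_functions=None) -> FunctionTable:
    """Random positive-total count table for fuzz tests."""
    n = n_samples or int(rng.integers(2, 12))
    k = n_functions or int(rng.integers(2, 20))
    counts = rng.integers(0, 50, size=(n, k))
    counts[:, 0] += 1  # ensure positive sample totals
    return FunctionTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n)],
            columns=[f"f{j}" for j in range(k)],
        )
    )
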