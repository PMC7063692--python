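import numpy as np
import pytest

from cellrplr import GroupedDataMatrix


def random_grouped_matrix(n=8, d=5, n_ref=5, seed=0):
    """Small all-random positive table with two groups (first n_ref = reference)."""
    rng = np.random.default_rng(seed)
    X = np.exp(rng.normal(2.0, 1.0, size=(n, d)))
    groups = np.array(["ctrl"] * n_ref + ["case"] * (n - n_ref))
    return GroupedDataMatrix(values=X, groups=groups)


@pytest.fixture
def small_matrix():
    return random_grouped_matrix(n=8, d=5, n_ref=5, seed=42)


@pytest.fixture
def tiny_csv(tmp_path):
    path = tmp_path / "table.csv"
    path.write_text(
        "sample,met_a,met_b,met_c,group\n"
        "s1,1.0,2.0,4.0,ctrl\n"
        "s2,1.5,2.5,3.5,ctrl\n"
        "s3,2.0,3.0,5.0,case\n"
        "s4,2.5,4.0,6.0,case\n"
    )
    return path
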