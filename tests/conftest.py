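import numpy as np
import pandas as pd
import pytest

from gd2sig.signature import GANGLIOSIDE_PANEL


@pytest.fixture
def toy_counts():
    """4 genes x 3 samples; gene g4 contains a zero and leaves the reference set."""
    return pd.DataFrame(
        {
            "s1": [10, 20, 30, 5],
            "s2": [20, 40, 60, 0],
            "s3": [15, 30, 45, 8],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene"),
    )


@pytest.fixture
def doubled_pair_counts():
    """3 all-positive genes, sample B = 2 x sample A."""
    return pd.DataFrame(
        {"A": [10, 20, 30], "B": [20, 40, 60]},
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )


@pytest.fixture
def panel_logexpr():
    """Six panel genes x 4 samples of synthetic log10 expression."""
    rng = np.random.default_rng(7)
    genes = list(GANGLIOSIDE_PANEL.genes)
    return pd.DataFrame(
        rng.uniform(0.0, 3.0, size=(len(genes), 4)),
        index=pd.Index(genes, name="gene"),
        columns=["c1", "c2", "c3", "c4"],
    )


def random_count_matrix(rng: np.random.Generator, max_genes=10, max_samples=6):
    """Random small count matrix guaranteed to contain an all-positive gene."""
    n_genes = rng.integers(2, max_genes + 1)
    n_samples = rng.integers(2, max_samples + 1)
    values = rng.integers(0, 100, size=(n_genes, n_samples))
    values[0] = rng.integers(1, 100, size=n_samples)  # ensure a reference gene
    return pd.DataFrame(
        values,
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene"),
        columns=[f"s{j}" for j in range(n_samples)],
    )
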