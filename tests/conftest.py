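import numpy as np
import pandas as pd
import pytest

from rankbag.io import LabeledDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(
    n_genes=50,
    n_samples=30,
    n_pos=12,
    shift_gene=None,
    shift=0.0,
    seed=0,
) -> LabeledDataset:
    """Small Gaussian dataset; optionally one gene gets a class mean shift."""
    r = np.random.default_rng(seed)
    X = r.normal(size=(n_genes, n_samples))
    y = np.zeros(n_samples, dtype=bool)
    y[:n_pos] = True
    if shift_gene is not None:
        X[shift_gene, y] += shift
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return LabeledDataset(
        pd.DataFrame(X, index=genes, columns=samples), pd.Series(y, index=samples)
    )


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture
def separable_dataset():
    """Ten informative genes with a large class shift: easy to classify."""
    r = np.random.default_rng(7)
    n_genes, n_samples, n_pos = 60, 40, 16
    X = r.normal(size=(n_genes, n_samples))
    y = np.zeros(n_samples, dtype=bool)
    y[:n_pos] = True
    X[np.ix_(range(10), np.where(y)[0])] += 2.5
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return LabeledDataset(
        pd.DataFrame(X, index=genes, columns=samples), pd.Series(y, index=samples)
    )
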