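import numpy as np
import pytest
import scipy.sparse as sp

from sccorrect.preprocess import ExpressionDataset, FeatureMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(counts, batch_id="b1", prefix="c"):
    """Wrap a dense count array into an ExpressionDataset."""
    counts = np.asarray(counts)
    return ExpressionDataset(
        values=sp.csr_matrix(counts),
        cell_ids=[f"{prefix}{i}" for i in range(counts.shape[0])],
        feature_ids=[f"g{j}" for j in range(counts.shape[1])],
        batch_id=batch_id,
    )


def make_fm(values, batch_ids=None, prefix="c"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return FeatureMatrix(
        values=values,
        feature_ids=[f"g{j}" for j in range(m)],
        cell_ids=[f"{prefix}{i}" for i in range(n)],
        batch_ids=batch_ids or ["b1"] * n,
    )
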