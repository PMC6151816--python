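import numpy as np
import pandas as pd
import pytest

from qsarval.data import Dataset, DescriptorMatrix, ResponseVector


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_design(rng):
    """25 compounds x 3 well-conditioned descriptors with a noisy response."""
    X = pd.DataFrame(
        rng.standard_normal((25, 3)),
        columns=["a", "b", "c"],
        index=[f"c{i}" for i in range(25)],
    )
    y = pd.Series(
        1.0 + 2.0 * X["a"] - 0.5 * X["b"] + 0.3 * X["c"] + rng.normal(0, 0.4, 25),
        index=X.index,
    )
    return X, y


@pytest.fixture
def noiseless_dataset(rng):
    """Exact linear data: y = 3 + 2*x1 - x2, no noise."""
    X = pd.DataFrame(
        rng.standard_normal((20, 2)),
        columns=["x1", "x2"],
        index=[f"m{i}" for i in range(20)],
    )
    y = 3.0 + 2.0 * X["x1"] - X["x2"]
    return X, y


def make_dataset(X: pd.DataFrame, y: pd.Series, split=None) -> Dataset:
    return Dataset(DescriptorMatrix(X), ResponseVector(y, "test-endpoint"), split)
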