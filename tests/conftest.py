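import numpy as np
import pytest

from petcov import RegionalEstimateTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def printed_table():
    """Tiny 4-subject x 3-ROI table with hand-checkable correlations."""
    return RegionalEstimateTable(
        subject_ids=["s1", "s2", "s3", "s4"],
        roi_labels=["roiA", "roiB", "roiC"],
        values=np.array([[1.0, 2.0, 10.0],
                         [2.0, 1.0, 9.0],
                         [3.0, 4.0, 12.0],
                         [4.0, 3.0, 11.0]]),
        parameter_name="CMRgl",
        group_label="demo",
    )


@pytest.fixture
def random_table(rng):
    """Moderately sized random table for structural checks."""
    values = rng.normal(6.0, 1.0, size=(12, 7))
    return RegionalEstimateTable(
        subject_ids=[f"s{i}" for i in range(12)],
        roi_labels=[f"r{j}" for j in range(7)],
        values=values,
        group_label="random",
    )


def random_symmetric_weights(rng, n, density=1.0, zero_diagonal=True):
    """Random nonnegative symmetric weight matrix with zero diagonal."""
    W = rng.uniform(0.1, 2.0, size=(n, n))
    mask = rng.random((n, n)) < density
    W = np.triu(W * mask, 1)
    W = W + W.T
    if not zero_diagonal:
        np.fill_diagonal(W, 1.0)
    return W
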