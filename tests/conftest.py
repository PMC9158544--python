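import numpy as np
import pytest

from symbionet import InteractionMatrix


def make_matrix(arr) -> InteractionMatrix:
    """Build an InteractionMatrix with generated labels from a 2-D array."""
    arr = np.asarray(arr, dtype=np.int64)
    n_r, n_c = arr.shape
    return InteractionMatrix(
        counts=arr,
        row_labels=tuple(f"p{i:02d}" for i in range(n_r)),
        col_labels=tuple(f"f{j:02d}" for j in range(n_c)),
    )


@pytest.fixture
def im():
    return make_matrix


@pytest.fixture
def random_network():
    """A 10x20 network with no empty species, fixed across the suite."""
    rng = np.random.default_rng(20240917)
    counts = rng.integers(0, 7, size=(10, 20))
    counts[counts < 3] = 0
    counts[:, 0] += 1  # guarantee no empty column/row
    counts[0, :] += 1
    return make_matrix(counts).drop_empty()
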