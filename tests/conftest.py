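import numpy as np
import pytest

from smlmnet.locio import LocalizationTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_roi():
    return np.array([[0.0, 1000.0], [0.0, 1000.0]])


@pytest.fixture
def small_table():
    """Ten fixed points in a 100x100 nm box."""
    coords = np.array([
        [10.0, 10.0], [15.0, 12.0], [12.0, 18.0],
        [60.0, 60.0], [64.0, 58.0], [58.0, 65.0],
        [90.0, 10.0], [5.0, 90.0], [50.0, 50.0], [30.0, 70.0],
    ])
    return LocalizationTable(coords=coords,
                             roi=np.array([[0.0, 100.0], [0.0, 100.0]]))


def brute_force_pairs(coords, r):
    """All index pairs (i<j) with Euclidean distance <= r, by exhaustive scan."""
    n = len(coords)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) <= r:
                pairs.append((i, j))
    return pairs
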