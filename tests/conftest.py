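import numpy as np
import pandas as pd
import pytest

from avatarize import FixtureSpec, TabularDataset, VariableSpec, generate_mixed


@pytest.fixture(scope="session")
def mixed_small() -> TabularDataset:
    """300-row mixed fixture: 4 continuous clustered columns + 1 categorical."""
    return generate_mixed(FixtureSpec(n=300, seed=11))


@pytest.fixture(scope="session")
def mixed_dupes() -> TabularDataset:
    """Mixed fixture with 10% exact duplicate rows (WBCD-like degeneracy)."""
    return generate_mixed(FixtureSpec(n=200, seed=13, duplicate_fraction=0.1))


@pytest.fixture()
def tiny_table() -> TabularDataset:
    """3-row table with one continuous and one categorical column."""
    frame = pd.DataFrame({"age": [30.0, 41.0, 55.0], "sex": ["M", "F", "F"]})
    schema = [
        VariableSpec("age", "continuous"),
        VariableSpec("sex", "categorical", ("M", "F")),
    ]
    return TabularDataset(schema, frame)


@pytest.fixture()
def two_points_1d() -> TabularDataset:
    """The analytic 2-record line {0, 10} used for degeneracy checks."""
    return TabularDataset(
        [VariableSpec("x", "continuous")], pd.DataFrame({"x": [0.0, 10.0]})
    )


def brute_force_knn(coords: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Independent all-pairs neighbor oracle with lower-index tie-break."""
    n = coords.shape[0]
    idx = np.empty((n, k), dtype=int)
    dst = np.empty((n, k))
    for i in range(n):
        pairs = []
        for j in range(n):
            if j == i:
                continue
            pairs.append((float(np.linalg.norm(coords[i] - coords[j])), j))
        pairs.sort()
        idx[i] = [j for _, j in pairs[:k]]
        dst[i] = [d for d, _ in pairs[:k]]
    return idx, dst
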