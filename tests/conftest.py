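import numpy as np
import pandas as pd
import pytest

from complexspace import PartTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_system_table():
    """Small two-system, two-variable part table."""
    df = pd.DataFrame(
        {
            "system_id": ["s1"] * 3 + ["s2"] * 4,
            "part_id": ["a", "b", "c", "a", "b", "c", "d"],
            "axial": [2.0, 4.0, 3.0, 10.0, 12.0, 14.0, 16.0],
            "pleural": [1.0, 1.5, 2.0, 5.0, 5.0, 6.0, 8.0],
        }
    )
    return PartTable(df)


def random_rotation(k: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-random proper rotation matrix in k dimensions."""
    a = rng.normal(size=(k, k))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
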