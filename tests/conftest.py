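import numpy as np
import pandas as pd
import pytest

from refstab import CtMatrix


@pytest.fixture
def toy_matrix() -> CtMatrix:
    """3 genes x 4 samples: B is A shifted by +5 cycles, C is noisier."""
    ct = pd.DataFrame(
        {
            "s1": [20.0, 25.0, 20.0],
            "s2": [21.0, 26.0, 22.0],
            "s3": [22.0, 27.0, 21.0],
            "s4": [23.0, 28.0, 24.0],
        },
        index=["A", "B", "C"],
    )
    return CtMatrix(
        ct, group_of={"s1": "g1", "s2": "g1", "s3": "g2", "s4": "g2"}
    )


@pytest.fixture
def make_random_matrix():
    """Factory for random Ct matrices in a realistic 15-35 cycle range."""

    def _make(rng: np.random.Generator, k: int, n: int, with_groups: bool = False):
        ct = pd.DataFrame(
            rng.uniform(15.0, 35.0, size=(k, n)),
            index=[f"g{i}" for i in range(k)],
            columns=[f"s{j}" for j in range(n)],
        )
        group_of = None
        if with_groups:
            half = n // 2
            group_of = {
                f"s{j}": ("grpA" if j < half else "grpB") for j in range(n)
            }
        return CtMatrix(ct, group_of=group_of)

    return _make
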