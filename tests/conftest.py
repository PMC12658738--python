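import numpy as np
import pandas as pd
import pytest

from ilearner.data import ObservationTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_binary_table(n=300, seed=0, q=4):
    """Small synthetic binary-outcome dataset with mild confounding."""
    rng = np.random.default_rng(seed)
    L = rng.normal(size=(n, q))
    pi = 1.0 / (1.0 + np.exp(-(0.3 + 0.6 * L[:, 0] - 0.4 * L[:, 1])))
    A = rng.binomial(1, pi)
    b = 1.0 / (1.0 + np.exp(-(-0.4 + 0.8 * L[:, 0] + 0.3 * L[:, 2])))
    Y = rng.binomial(1, b)
    df = pd.DataFrame(L, columns=[f"L{j+1}" for j in range(q)])
    df["A"], df["Y"] = A, Y
    df["_pi"], df["_b"] = pi, b
    return ObservationTable(df)


@pytest.fixture
def binary_table():
    return make_binary_table()
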