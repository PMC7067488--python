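import numpy as np
import pandas as pd
import pytest

from anchorbn import Dataset


def gaussian_dataset(seed: int, k: int = 4, n: int = 200) -> Dataset:
    """Random linear-Gaussian DAG data: upper-triangular coefficient
    matrix with ~40% dense N(0,1) entries, unit residuals."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(k, k)) * (rng.random((k, k)) < 0.4) * np.tri(k, k, -1).T
    X = np.zeros((n, k))
    for j in range(k):
        X[:, j] = X @ A[:, j] + rng.normal(size=n)
    df = pd.DataFrame(X, columns=[f"V{i}" for i in range(k)])
    return Dataset(df, {c: "continuous" for c in df}, {c: "phenotype" for c in df})


def binary_dataset(seed: int, n: int = 500) -> Dataset:
    """Three dependent binary columns for multinomial scoring tests."""
    rng = np.random.default_rng(seed)
    a = rng.binomial(1, 0.5, n)
    b = rng.binomial(1, 0.3 + 0.4 * a)
    c = rng.binomial(1, 0.3 + 0.3 * b)
    df = pd.DataFrame({"A": a, "B": b, "C": c})
    return Dataset(df, {c_: "categorical" for c_ in df},
                   {c_: "phenotype" for c_ in df},
                   levels={c_: (0, 1) for c_ in df})


@pytest.fixture
def toy_gaussian():
    return gaussian_dataset(0)


@pytest.fixture
def toy_binary():
    return binary_dataset(0)
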