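import numpy as np
import pandas as pd
import pytest

from refquant import CtMatrix


def make_matrix(values, genes=None, samples=None, condition=None, max_cycle=34.0):
    """Build a CtMatrix from a 2-D array and optional labels."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i + 1}" for i in range(n_genes)]
    samples = samples or [f"S{j + 1}" for j in range(n_samples)]
    if condition is None:
        half = n_samples // 2
        condition = ["control"] * half + ["treated"] * (n_samples - half)
    return CtMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        pd.Series(condition, index=samples, dtype=object),
        max_cycle=max_cycle,
    )


@pytest.fixture
def tiny_matrix():
    """3 genes x 6 samples, two conditions, no undetermined wells."""
    rng = np.random.default_rng(7)
    return make_matrix(24.0 + rng.normal(0, 0.5, size=(3, 6)))


@pytest.fixture
def hkg_matrix():
    """6 candidate genes x 8 one-condition samples for stability runs."""
    rng = np.random.default_rng(11)
    base = np.array([22.0, 24.0, 25.0, 23.0, 26.0, 21.0])[:, None]
    return make_matrix(
        base + rng.normal(0, 0.4, size=(6, 8)),
        condition=["control"] * 8,
    )
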