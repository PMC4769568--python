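import numpy as np
import pandas as pd
import pytest

from plasmodebench.containers import CountMatrix
from plasmodebench.synthetic import SimConfig, default_config, generate_counts


@pytest.fixture(scope="session")
def small_null_counts() -> CountMatrix:
    """Default-shaped null 4+4 matrix, 600 transcripts."""
    from plasmodebench.synthetic import generate_null_counts

    return generate_null_counts(default_config(n_transcripts=600, seed=42))


@pytest.fixture()
def toy_counts() -> CountMatrix:
    counts = pd.DataFrame(
        {
            "s1": [1000, 500, 10, 5, 3],
            "s2": [900, 450, 12, 0, 2],
            "s3": [1100, 520, 9, 4, 0],
            "s4": [950, 480, 11, 6, 1],
        },
        index=[f"t{i}" for i in range(5)],
    )
    groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
    return CountMatrix(counts, groups)


def make_counts(mat, groups=None) -> CountMatrix:
    mat = np.asarray(mat)
    n = mat.shape[1]
    cols = [f"s{j}" for j in range(n)]
    df = pd.DataFrame(mat, index=[f"t{i}" for i in range(mat.shape[0])], columns=cols)
    if groups is None:
        groups = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    return CountMatrix(df, pd.Series(list(groups), index=cols))
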