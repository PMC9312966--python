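import numpy as np
import pandas as pd
import pytest

from szdetect.features import TARGET_COLUMN


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def make_feature_table(
    n_y: int,
    n_n: int,
    n_features: int = 3,
    separation: float = 4.0,
    seed: int = 0,
    index_prefix: str | None = None,
) -> pd.DataFrame:
    """Random two-class feature table; class means differ by ``separation`` SDs."""
    r = np.random.default_rng(seed)
    x = np.vstack(
        [
            r.normal(separation, 1.0, size=(n_y, n_features)),
            r.normal(0.0, 1.0, size=(n_n, n_features)),
        ]
    )
    table = pd.DataFrame(x, columns=[f"f{i}" for i in range(n_features)])
    table[TARGET_COLUMN] = ["Y"] * n_y + ["N"] * n_n
    if index_prefix is not None:
        table.index = pd.Index([f"{index_prefix}{i}" for i in range(len(table))])
    return table
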