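import numpy as np
import pandas as pd
import pytest

from pfaser.synthetic import generate_dataset, pfas_like_spec


def random_table(n_rows: int, n_cols: int, seed: int, corr: float = 0.0) -> pd.DataFrame:
    """Random descriptor-like table; optional uniform pairwise correlation."""
    rng = np.random.default_rng(seed)
    if corr:
        cov = np.full((n_cols, n_cols), corr)
        np.fill_diagonal(cov, 1.0)
        L = np.linalg.cholesky(cov)
        X = rng.standard_normal((n_rows, n_cols)) @ L.T
    else:
        X = rng.standard_normal((n_rows, n_cols))
    return pd.DataFrame(
        X,
        index=[f"L{i:03d}" for i in range(n_rows)],
        columns=[f"desc_{j}" for j in range(n_cols)],
    )


@pytest.fixture(scope="session")
def reference_dataset():
    """One medium synthetic dataset under the default study conditions."""
    return generate_dataset(pfas_like_spec(n_ligands=200, noise_sd=0.3, seed=42))


@pytest.fixture()
def small_table():
    return random_table(40, 5, seed=7)
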