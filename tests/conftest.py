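import numpy as np
import pandas as pd
import pytest

from cgsc import SyntheticConfig, simulate_bulk, simulate_methylome, simulate_sc_cohort


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Scaled-down study conditions for fast unit tests."""
    return SyntheticConfig(
        n_cells=600, n_patients=10, n_genes=300, n_probes=1200, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_sc_cohort(small_config)


@pytest.fixture(scope="session")
def small_bulk(small_config):
    return simulate_bulk(small_config)


@pytest.fixture(scope="session")
def small_methylome(small_config):
    return simulate_methylome(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def toy_matrix(values: dict[str, list[float]], cells: list[str] | None = None) -> pd.DataFrame:
    """Genes x cells DataFrame from a dict of per-gene value lists."""
    df = pd.DataFrame(values).T
    if cells is not None:
        df.columns = cells
    else:
        df.columns = [f"c{i}" for i in range(df.shape[1])]
    return df
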