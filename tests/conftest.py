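import numpy as np
import pandas as pd
import pytest

from healthineq import PanelDataset, SyntheticConfig, generate_panel
from healthineq.panel import REQUIRED_COLUMNS


def make_panel(overrides: dict, n: int = 8, metadata: dict | None = None) -> PanelDataset:
    """Hand-built panel: fill required columns with benign defaults, then
    overwrite with the test's columns of interest."""
    base = {
        "person_id": np.arange(n),
        "city_id": np.zeros(n, dtype=int),
        "year": np.full(n, 2012),
        "urrbmi": np.zeros(n, dtype=int),
        "lnpcincome": np.linspace(7.0, 10.0, n),
        "healthy": np.ones(n, dtype=int),
        "outpatient": np.zeros(n, dtype=int),
        "hospital": np.zeros(n, dtype=int),
        "lnoutself": np.full(n, np.nan),
        "lnhosself": np.full(n, np.nan),
        "age": np.full(n, 40),
        "male": np.zeros(n, dtype=int),
        "married": np.ones(n, dtype=int),
        "hhnum": np.full(n, 3),
        "rural": np.ones(n, dtype=int),
        "priedu": np.zeros(n, dtype=int),
        "secedu": np.zeros(n, dtype=int),
        "highedu": np.zeros(n, dtype=int),
        "superhigh": np.zeros(n, dtype=int),
        "pension": np.zeros(n, dtype=int),
        "sanitary": np.ones(n, dtype=int),
        "east": np.zeros(n, dtype=int),
    }
    base.update(overrides)
    base["age2"] = np.asarray(base["age"]) ** 2
    df = pd.DataFrame({c: base[c] for c in REQUIRED_COLUMNS})
    return PanelDataset(df, metadata=metadata or {})


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_individuals=2000, n_cities=20, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_config) -> PanelDataset:
    return generate_panel(small_config)


@pytest.fixture(scope="session")
def big_panel() -> PanelDataset:
    """Default-scale panel (20,000 individuals, 60 cities, 3 waves)."""
    return generate_panel(SyntheticConfig(seed=1))
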