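import numpy as np
import pandas as pd
import pytest

from wingallometry.climate import CovariateTable
from wingallometry.model import SamplerConfig, fit
from wingallometry.simulate import SimulationConfig, simulate_dataset


def covariate_table_from_dict(g_dict, columns):
    """Build a CovariateTable directly from {(species, year): vector}."""
    idx = pd.MultiIndex.from_tuples(g_dict.keys(), names=["species", "year"])
    df = pd.DataFrame([g_dict[k] for k in g_dict], index=idx,
                      columns=list(columns))
    return CovariateTable(table=df, column_spec=list(columns))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic dataset shared by structural tests."""
    cfg = SimulationConfig(n_species=3, year_start=2004, year_end=2009,
                           n_per_species_year=20, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_draws(tiny_dataset):
    """A short (but real) posterior fit shared by summary/diagnostic tests."""
    cfg = tiny_dataset.config
    return fit(
        tiny_dataset.model_data(), tiny_dataset.G, cfg.model_spec(),
        SamplerConfig(n_chains=2, n_iterations=300, n_warmup=150, seed=5),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
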