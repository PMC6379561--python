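import dataclasses

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from medipdmr.config import DEConfig, PathologyConfig, SimulationConfig
from medipdmr.simulate import sample_names

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_sim_config() -> SimulationConfig:
    """A 100 kb single-chromosome experiment, fast enough for unit tests."""
    return SimulationConfig(
        seed=11,
        chrom_length_bp=100_000,
        n_planted_dmrs=5,
        de_config=DEConfig(n_per_class={"mRNA": 150, "lncRNA": 90, "sncRNA": 60}),
        pathology_config=PathologyConfig(),
    )


@pytest.fixture
def groups_3v3(small_sim_config) -> pd.Series:
    return sample_names(small_sim_config)[1]


@pytest.fixture
def null_sim_config(small_sim_config) -> SimulationConfig:
    return dataclasses.replace(small_sim_config, n_planted_dmrs=0, seed=12)
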