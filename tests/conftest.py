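import numpy as np
import pandas as pd
import pytest

from rockpool.registry import MCMCSettings
from rockpool.simulate import SyntheticConfig, generate_phenotypes


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study: 4 pools, 5 clones/pool, reduced size."""
    cfg = SyntheticConfig(n_pools=4, clones_per_pool=5)
    return generate_phenotypes(cfg, seed=123)


@pytest.fixture(scope="session")
def paper_scale_study():
    """Default-condition study: 10 pools x 13 clones, 2-3 reps/clone/temp."""
    return generate_phenotypes(SyntheticConfig(), seed=2024)


@pytest.fixture
def quick_settings():
    return MCMCSettings(2000, 800, thin=1, n_chains=2, seed=99)


@pytest.fixture
def intercept_frame():
    """Simple one-group data for intercept-only models."""
    rng = np.random.default_rng(42)
    y = rng.normal(2.0, 1.0, 50)
    return pd.DataFrame({
        "response": y, "clone": "c1", "pool": "p1",
        "year": 2018, "dev_temp": 20,
    })
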