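import numpy as np
import pytest
from hypothesis import settings

import geoadditive as ga

settings.register_profile("det", derandomize=True)
settings.load_profile("det")


@pytest.fixture(scope="session")
def graph8():
    return ga.make_region_graph("bdhs2018")


@pytest.fixture(scope="session")
def graph7():
    return ga.make_region_graph("bdhs2014")


@pytest.fixture(scope="session")
def medium_sim():
    """One medium synthetic survey with full ground truth, shared read-only."""
    cfg = ga.GeneratorConfig(
        n_records=2000,
        seed=42,
        true_linear_effects=ga.default_true_linear_effects(),
        true_smooth_functions=ga.default_true_smooth_functions(),
        structured_truth_delta=0.15,
    )
    return ga.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def medium_data(medium_sim):
    return ga.ModelData(medium_sim.data, graph=medium_sim.graph)


@pytest.fixture(scope="session")
def small_m1_fit(medium_sim):
    """A quick M1 fit on a subset, reused by summary-level tests."""
    df = medium_sim.data.head(800)
    data = ga.ModelData(df, graph=medium_sim.graph)
    config = ga.MCMCConfig(n_iter=400, burn_in=100, thin=2, seed=11)
    return ga.run_mcmc(data, ga.ModelSpec("M1"), config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
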