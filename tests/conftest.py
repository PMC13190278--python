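import numpy as np
import pytest

import behavar as bv
from behavar.inference import McmcConfig


@pytest.fixture(scope="session")
def paper_sim():
    """One paper-scale synthetic dataset (217 individuals, 12 pools)."""
    return bv.simulate_dataset(bv.default_params("paper_like", seed=1))


@pytest.fixture(scope="session")
def paper_prepared(paper_sim):
    return bv.prepare(paper_sim.records)


def small_params(seed: int = 0, scenario: str = "paper_like") -> bv.SimulationParams:
    """Reduced study: 40 naive + 16 exposed individuals in 2 + 4 pools."""
    p = bv.default_params(scenario, seed=seed)
    p.n_naive, p.n_exposed = 40, 16
    p.n_pools_naive, p.n_pools_exposed = 2, 4
    p.missingness = 0.0
    return p


@pytest.fixture(scope="session")
def small_sim():
    return bv.simulate_dataset(small_params(seed=3))


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A quick full-model fit shared by derived/inference tests."""
    prepared = bv.prepare(small_sim.records)
    config = McmcConfig(n_chains=2, n_iterations=500, n_burnin=200, thin=3, seed=3)
    return bv.run_mcmc(prepared, config=config)
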