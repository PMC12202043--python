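"""Shared fixtures: session-scoped model fits reused across test modules."""

import numpy as np
import pytest

from urbanvar import hetvar, partition, synthetic


@pytest.fixture(scope="session")
def gauss_spec() -> synthetic.VarianceSpec:
    """Full-featured Gaussian two-habitat design with known truth."""
    return synthetic.VarianceSpec(
        family="gaussian",
        intercept={"forest": 10.0, "urban": 10.5},
        v_individual={"forest": 1.0, "urban": 2.0},
        v_residual={"forest": 1.0, "urban": 1.0},
        v_year=0.1,
        v_observer=0.05,
        beta_sex=0.4,
        beta_age=0.2,
        beta_day=0.01,
        beta_hour=0.03,
        beta_hour2=-0.005,
        beta_assay_rank=-0.1,
        beta_protocol=0.3,
        n_individuals=250,
        repeats_probs={1: 0.55, 2: 0.30, 3: 0.15},
    )


@pytest.fixture(scope="session")
def gauss_table(gauss_spec):
    return synthetic.simulate_observations(gauss_spec, seed=11)


@pytest.fixture(scope="session")
def gauss_draws(gauss_table):
    config = hetvar.ModelConfig(
        family="gaussian",
        variance_grouping="by_habitat",
        mcmc=hetvar.MCMCOptions(n_iter=3600, burn_in=1200, thin=2, seed=5),
    )
    return hetvar.fit(gauss_table, config)


@pytest.fixture(scope="session")
def gauss_decomposition(gauss_draws, gauss_table):
    return partition.decompose(gauss_draws, gauss_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
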