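import warnings

# arviz emits a refactor FutureWarning at import time; silence it before any
# fit triggers the lazy import.
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz  # noqa: F401

import numpy as np
import pytest

import dispersaltrials as dt


@pytest.fixture
def growth_prior():
    """Informative Normal prior on r used across MCMC tests."""
    return dt.GrowthPrior(m=4.0, sigma=0.5)


@pytest.fixture
def prior_spec(growth_prior):
    return dt.PriorSpec(growth=growth_prior)


@pytest.fixture
def small_sim_data():
    """Ten simulated trials at moderate source sizes with known truth."""
    cfg = dt.SimConfig(
        n_trials=10,
        source_sizes=300,
        q_true=0.37,
        mu_true=float(np.log(0.29 / 0.71)),
        sigma_p_true=1.8,
        r_true=4.0,
        seed=11,
    )
    return dt.simulate_trials(cfg)
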