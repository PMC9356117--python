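import numpy as np
import pytest

from histborrow.simstudy import GenParams, ScenarioSpec, simulate_trial


@pytest.fixture(scope="session")
def toy_pair():
    """Small homogeneous trial pair with a true treatment effect of 0.36."""
    spec = ScenarioSpec.named("No", beta2=0.36, n_per_arm=25)
    return simulate_trial(spec, seed=42)


@pytest.fixture(scope="session")
def toy_pair_null():
    """Small homogeneous trial pair with no treatment effect."""
    spec = ScenarioSpec.named("No", beta2=0.0, n_per_arm=25)
    return simulate_trial(spec, seed=42)


@pytest.fixture(scope="session")
def fast():
    """Reduced sampler settings for unit tests."""
    return dict(chains=2, iterations=600, burn_in=300)


@pytest.fixture(scope="session")
def fast_mpp(fast):
    """Reduced sampler + grid settings for MPP unit tests."""
    return dict(
        **fast,
        grid_step=0.1,
        grid_iterations=50,
        grid_burn_in=20,
        grid_prior_draws=300,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
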