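import pytest
from hypothesis import HealthCheck, settings

import pedisrisk as pr

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort() -> pr.Cohort:
    """A 400-patient synthetic cohort at the default (published) conditions."""
    return pr.generate_cohort(pr.GeneratorConfig(n=400, seed=1))


@pytest.fixture(scope="session")
def light_chains() -> pr.ChainConfig:
    """Short two-chain configuration for tests that only need a usable posterior."""
    return pr.ChainConfig(n_chains=2, n_steps=2500, burn_in=500, seed=5)


@pytest.fixture(scope="session")
def small_fit(small_cohort, light_chains) -> pr.PosteriorDraws:
    return pr.fit(None, small_cohort, light_chains)
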