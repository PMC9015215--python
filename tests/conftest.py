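import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import coopsem as cs

settings.register_profile(
    "ci", derandomize=True, max_examples=40, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def m6_spec():
    return cs.build_model_spec("M6")


@pytest.fixture(scope="session")
def small_dataset():
    """30 territories over 4 years under the fully sex-invariant model."""
    return cs.generate_dataset(cs.GeneratorConfig(n_groups=30, years=4, seed=11))


@pytest.fixture(scope="session")
def small_fit(m6_spec, small_dataset):
    """A short but multi-chain fit reused by several diagnostics tests."""
    mcmc = cs.McmcConfig(n_chains=2, n_iterations=500, n_burnin=250, thin=2, seed=21)
    return cs.fit(m6_spec, small_dataset, mcmc)


@pytest.fixture(scope="session")
def tiny_dataset():
    return cs.generate_dataset(cs.GeneratorConfig(n_groups=12, years=4, seed=5))
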