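import pytest
from hypothesis import HealthCheck, settings

import psfsim as ps

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noise_free_plots():
    """Experiment table at the noise-free limit of the default config."""
    return ps.generate_experiment(ps.GeneratorConfig(dispersion=0.0))


@pytest.fixture(scope="session")
def noisy_plots():
    return ps.generate_experiment(ps.GeneratorConfig(rng_seed=42))


@pytest.fixture(scope="session")
def noise_free_rates(noise_free_plots):
    return ps.derive_rate_table(noise_free_plots)


@pytest.fixture(scope="session")
def noise_free_caps(noise_free_plots):
    return ps.derive_capacities(noise_free_plots)


@pytest.fixture(scope="session")
def noise_free_survey():
    return ps.generate_survey(dispersion=0.0, site_sd=0.0)


@pytest.fixture(scope="session")
def noisy_survey():
    return ps.generate_survey(rng_seed=7)
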