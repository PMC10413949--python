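import pytest
from hypothesis import HealthCheck, settings

from gutflux.synthetic import ScenarioSpec, make_kinetics_dataset

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noiseless_spec() -> ScenarioSpec:
    return ScenarioSpec(noise_cv=0.0, ffa_noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def kinetics_low(noiseless_spec):
    """Noiseless low-enzyme digestion-phase dataset (truth attached)."""
    return make_kinetics_dataset(noiseless_spec, "low")


@pytest.fixture(scope="session")
def kinetics_high(noiseless_spec):
    return make_kinetics_dataset(noiseless_spec, "high")
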