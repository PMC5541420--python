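import pytest

from hrgap.synth import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """A study with the default shape: 12 urban + 8 rural facilities."""
    return generate_study(seed=123)


@pytest.fixture(scope="session")
def big_study():
    """200 facilities -> 200 draws per age group, for parameter-recovery checks."""
    return generate_study(GeneratorConfig(n_urban=120, n_rural=80), seed=7)
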