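import pytest
from hypothesis import settings

from swapset import (
    RegistryConfig,
    RunSecrets,
    generate_registry,
    inject_pathologies,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    """A small clean synthetic registry: (tables, dictionary)."""
    config = RegistryConfig(n_patients=400, seed=11)
    return generate_registry(config)


@pytest.fixture(scope="session")
def messy_registry():
    """The same registry with planted pathologies (bad dates, short ICDs)."""
    config = RegistryConfig(n_patients=400, seed=11)
    tables, dictionary = generate_registry(config)
    return inject_pathologies(tables, config), dictionary


@pytest.fixture()
def test_secrets():
    return RunSecrets.for_testing(seed=123)
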