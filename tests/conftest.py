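import pytest

from nachr_pf import (
    load_packaged_observations,
    load_packaged_predictions,
    load_packaged_subunits,
    registry_with_mutants,
)


@pytest.fixture(scope="session")
def registry():
    return load_packaged_subunits()


@pytest.fixture(scope="session")
def registry_mut():
    return registry_with_mutants()


@pytest.fixture(scope="session")
def observations():
    return load_packaged_observations()


@pytest.fixture(scope="session")
def predictions():
    return load_packaged_predictions()
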