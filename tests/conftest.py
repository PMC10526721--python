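import pytest

from connectomatrix import (
    build_dti_fixture,
    build_pre_dti_fixture,
    default_registry,
)
from connectomatrix.fixtures import build_fixture_db
from connectomatrix.matrix import Era


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def pre_dti(registry):
    return build_pre_dti_fixture(registry)


@pytest.fixture(scope="session")
def dti(registry):
    return build_dti_fixture(registry)


@pytest.fixture(scope="session")
def fixture_db(registry):
    db, report = build_fixture_db(Era.PRE_DTI, registry)
    assert report.ok, report.quarantined
    return db
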