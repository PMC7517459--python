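import pytest

from kkpeusner import make_reference_profiles, nephrophan_fixture


@pytest.fixture(scope="session")
def system():
    """Nephrophan membrane / glucose / aqueous-ethanol reference system."""
    return nephrophan_fixture()


@pytest.fixture(scope="session")
def membrane(system):
    return system.membrane


@pytest.fixture(scope="session")
def env(system):
    return system.env


@pytest.fixture(scope="session")
def baths(system):
    return system.baths


@pytest.fixture(scope="session")
def profiles():
    """(A, B) concentration-polarization profiles of the reference system."""
    return make_reference_profiles()
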