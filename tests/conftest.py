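import pytest

from pfaslevels.core import ToleranceProfile
from pfaslevels.simulate import worked_example_fixture, worked_example_profile


@pytest.fixture
def profile() -> ToleranceProfile:
    return ToleranceProfile()


@pytest.fixture(scope="session")
def worked_examples():
    """Canned fixture of the worked-example features/library."""
    return worked_example_fixture()


@pytest.fixture(scope="session")
def worked_profile() -> ToleranceProfile:
    return worked_example_profile()
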