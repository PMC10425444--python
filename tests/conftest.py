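import pytest

from tsameta import Outcome, load_lvt_fixture


@pytest.fixture(scope="session")
def lvt():
    """The packaged LV-thrombus evidence base, keyed by outcome."""
    return load_lvt_fixture()


@pytest.fixture(scope="session")
def resolution(lvt):
    return lvt[Outcome.THROMBUS_RESOLUTION]


@pytest.fixture(scope="session")
def any_bleeding(lvt):
    return lvt[Outcome.ANY_BLEEDING]
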