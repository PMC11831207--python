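import pytest

from drivebalance import LifeCycle, make_strategy


@pytest.fixture(scope="session")
def pdne():
    """Idealized single-locus protected dominant-negative editor."""
    return make_strategy("pdne1")


@pytest.fixture(scope="session")
def sit():
    return make_strategy("sit")


@pytest.fixture(scope="session")
def lc6():
    return LifeCycle(Rm=6)
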