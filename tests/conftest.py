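import pytest

from helpers import make_instruments, simulate_instruments


@pytest.fixture
def instrument_factory():
    return make_instruments


@pytest.fixture
def sim_factory():
    return simulate_instruments


@pytest.fixture
def toy_triple():
    """Equal exposure effects, outcome effects 0.4/0.5/0.6, sigma 0.1.

    Closed form: IVW slope 0.5, fixed-effect SE 0.1/sqrt(3), Q = 2.
    """
    return make_instruments([1.0, 1.0, 1.0], [0.4, 0.5, 0.6], 0.1)
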