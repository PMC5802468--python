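import numpy as np
import pytest

from pleiopace import build_neuron, build_san, integrate_cell


@pytest.fixture(scope="session")
def neuron():
    return build_neuron()


@pytest.fixture(scope="session")
def san_mouse():
    return build_san("mouse")


@pytest.fixture(scope="session")
def san_rabbit():
    return build_san("rabbit")


@pytest.fixture(scope="session")
def san_long_runs(san_mouse, san_rabbit):
    """20 s unstimulated integrations of both SAN controls, with currents.

    Shared by the model-invariant tests and the acceptance checks on
    control pacemaking rate and funny-current amplitude.
    """
    out = {}
    for name, model in (("mouse", san_mouse), ("rabbit", san_rabbit)):
        out[name] = integrate_cell(model, None, 20000.0, dt_record=0.5,
                                   record_currents=True)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
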