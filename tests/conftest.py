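import numpy as np
import pytest

from pocketscope import optics, synth


@pytest.fixture(scope="session")
def stock_train():
    """The 1 mm ball / 0.8 mm aperture / EFL-3.36 phone-camera train."""
    return optics.build_iphone2g_microscope()


@pytest.fixture(scope="session")
def stock_metrics(stock_train):
    """System metrics of the stock train (best focus located once)."""
    return optics.system_metrics(stock_train)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def grating_texture():
    return synth.make_texture(seed=7)


@pytest.fixture(scope="session")
def curvature_stack(grating_texture):
    """Two-plane field-curvature stack: in-focus centre and +2 µm offset."""
    return synth.apply_aberrations(grating_texture, synth.AberrationSpec())
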