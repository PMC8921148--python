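import numpy as np
import pytest

from relspect.phantom import PhantomParams, make_phantom_rois


@pytest.fixture(scope="session")
def rois_default():
    """Phantom ROI set on the full 48x56x44 grid at 3 mm."""
    return make_phantom_rois((48, 56, 44), 3.0)


@pytest.fixture(scope="session")
def rois_coarse():
    """Phantom ROI set on the 24x28x22 study grid at 6 mm."""
    return make_phantom_rois((24, 28, 22), 6.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
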