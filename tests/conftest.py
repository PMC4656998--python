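import numpy as np
import pytest

import maizeflow as mf


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def square120():
    """The worked-example field: equivalent square of the I = 30 m field."""
    return mf.FieldGeometry.rectangle(120.0, 120.0)


@pytest.fixture
def rect_100x150():
    return mf.FieldGeometry.rectangle(150.0, 100.0)


@pytest.fixture
def calibrated_model():
    """Model calibrated so the 3 m perimeter mean is 0.3% on a = 120 m."""
    return mf.calibrate(120.0, 3.0, 0.3)
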