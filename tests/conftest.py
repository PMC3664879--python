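import numpy as np
import pytest

from sampledshapes import RFShapeSpec

CIRCLE = RFShapeSpec(r0=2.7, amplitude=0.0, frequency=0)
RF4 = RFShapeSpec(r0=2.7, amplitude=0.18, frequency=4)
RF8 = RFShapeSpec(r0=2.7, amplitude=0.1, frequency=8)


@pytest.fixture
def circle():
    return CIRCLE


@pytest.fixture
def rf4():
    return RF4


@pytest.fixture
def rf8():
    return RF8


@pytest.fixture
def shapes():
    return {"circle": CIRCLE, "rf4": RF4, "rf8": RF8}


@pytest.fixture
def rng():
    return np.random.default_rng(20130528)
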