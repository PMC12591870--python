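import numpy as np
import pytest

from rotoloc.geometry import Box, DecisionConfig, ObjectClass


@pytest.fixture
def cfg():
    return DecisionConfig()


def make_slot(x=200.0, y=150.0, length=100.0, height=30.0, conf=1.0):
    return Box(x, y, length, height, class_id=ObjectClass.SLOT, confidence=conf)


def make_tumor(x=190.0, y=140.0, length=60.0, height=40.0, conf=1.0):
    return Box(x, y, length, height, class_id=ObjectClass.TUMOR, confidence=conf)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
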