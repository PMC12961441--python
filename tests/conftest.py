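import numpy as np
import pytest

from ptv2fr import LabeledCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cloud(rng):
    """Small random labeled cloud for plumbing tests."""
    n = 64
    return LabeledCloud(
        points=rng.standard_normal((n, 3)) * 0.1,
        colors=rng.integers(0, 256, size=(n, 3)),
        labels=rng.integers(0, 3, size=n),
        pot_id="pot_test",
    )
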