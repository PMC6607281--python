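import numpy as np
import pytest

import stirnet as sn


@pytest.fixture(scope="session")
def default_phantom():
    """Reduced-size phantom at the clinical frame interval (45 s / 119 frames)."""
    spec = sn.default_phantom_spec(48, 48, 119, seed=11)
    vol, gt = sn.generate_phantom(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def quick_phantom():
    """Tiny, fast phantom (dt = 1 s) for degradation and network tests."""
    spec = sn.default_phantom_spec(32, 32, 24, dt=1.0, seed=5)
    vol, gt = sn.generate_phantom(spec)
    return spec, vol, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def inwindow_volume(rng):
    """A random volume whose values already sit inside the [0, 255] display
    window (so clipped normalization is lossless)."""
    data = rng.uniform(10.0, 240.0, size=(16, 16, 10)).astype(np.float32)
    return sn.CTPVolume(data=data, dt=1.0)
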