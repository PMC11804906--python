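import numpy as np
import pytest

import escrtkit as ek

# Band geometry used to read out the spike signal of synthetic edge scenes:
# profile at the spike-centre offset, averaged across half the spike length.
BAND_OFFSET_A = 60.0
BAND_HALFWIDTH_A = 25.0
PERIOD_RANGE_A = (15.0, 60.0)


@pytest.fixture(scope="session")
def standard_scene():
    """The standard synthetic edge scene: 1024^2, 2.8 A/px, 30-A repeat, SNR 1."""
    return ek.make_edge_scene(ek.SceneSpec())


@pytest.fixture(scope="session")
def standard_subtraction(standard_scene):
    mic, truth = standard_scene
    return ek.subtract_rolling_average(mic, truth.path, repeat_A=30.0,
                                       window_len=3, box_size_A=240.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
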