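import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

from ornpulse import synthetic
from ornpulse.imaging_io import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_trace():
    """Noiseless, eventless trace: constant at the baseline level."""
    params = synthetic.CalciumSimParams(
        event_rate=0.0, noise_sigma=0.0, drift_slope=0.0, duration=10.0, seed=0
    )
    trace, gt = synthetic.simulate_calcium_trace(params)
    return trace, gt


@pytest.fixture
def random_stack(rng):
    return ImageStack(rng.uniform(0, 255, size=(3, 16, 16)), frame_interval=0.2)
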