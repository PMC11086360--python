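import numpy as np
import pytest

from grfest.body import build_model, neutral_pose
from grfest.synth import NoiseModel, synthesize


@pytest.fixture(scope="session")
def model():
    return build_model(1.69, 63.3)


@pytest.fixture(scope="session")
def standing_state(model):
    return neutral_pose(model)


@pytest.fixture(scope="session")
def hop_trial():
    """Noisy single-leg-hop fixture shared by the slower tests."""
    return synthesize("single-leg-hop", seed=3)


@pytest.fixture(scope="session")
def hop_trial_clean():
    """Noise-free single-leg-hop fixture (inverse-crime reference)."""
    return synthesize("single-leg-hop", seed=3, noise=NoiseModel(0.0, 0.0, 0.0, 0))


@pytest.fixture(scope="session")
def calib_trial():
    return synthesize("calibration-pose", seed=5, duration=1.0)
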