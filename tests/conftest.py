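import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from birdgaze.camera import CameraGrid
from birdgaze.synth import make_lab_scene, make_pursuit_trial


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def grid1():
    return CameraGrid(resolution=1.0)


@pytest.fixture(scope="session")
def box_scene():
    return make_lab_scene("box")


@pytest.fixture(scope="session")
def obstacle_scene():
    return make_lab_scene("obstacle")


@pytest.fixture(scope="session")
def short_trial():
    """Small noiseless-ish pursuit trial shared across tests (0.3 s flight)."""
    return make_pursuit_trial(seed=11, duration=0.3)
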