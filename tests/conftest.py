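import numpy as np
import pytest

from pedweight import synthetic_growth_chart, default_zone_table
from pedweight.pose_features import KEYPOINT_NAMES, Keypoint, PoseFrame


@pytest.fixture(scope="session")
def chart():
    return synthetic_growth_chart()


@pytest.fixture(scope="session")
def zones():
    return default_zone_table()


def make_frame(coords, subject_id="s0", w=640, h=480, conf=1.0):
    """PoseFrame from a (17, 2) array in canonical keypoint order."""
    kps = {
        name: Keypoint(name, float(x), float(y), conf)
        for name, (x, y) in zip(KEYPOINT_NAMES, np.asarray(coords))
    }
    return PoseFrame(subject_id, kps, w, h)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
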