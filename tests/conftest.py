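import numpy as np
import pytest

import finlogger as fl


@pytest.fixture(scope="session")
def default_video():
    """One tracked default swim video shared across kinematics tests."""
    spec = fl.SwimmerSpec()
    frames, truth = fl.generate_swim_video(spec, duration=3.0, fps=75.0, seed=11)
    area_range, ratio_range = fl.kinematics.default_selection_ranges(
        truth["expected_area_px2"])
    track = fl.track_video(frames, area_range=area_range,
                           ratio_range=ratio_range)
    return spec, frames, truth, track


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
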