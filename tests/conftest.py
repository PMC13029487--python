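import numpy as np
import pytest

from gaitfusion import GaitParams, SensorLayout, simulate_activity
from gaitfusion.preprocessing import segment_windows


@pytest.fixture(scope="session")
def layout():
    return SensorLayout()


@pytest.fixture(scope="session")
def walking_recording():
    return simulate_activity(GaitParams.for_activity("walking"), 60, seed=7)


@pytest.fixture(scope="session")
def walking_windows(walking_recording):
    return segment_windows(walking_recording)


@pytest.fixture(scope="session")
def running_recording():
    return simulate_activity(GaitParams.for_activity("running"), 60, seed=7)
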