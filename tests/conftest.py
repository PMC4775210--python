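import numpy as np
import pytest

from eatmap import (AcquisitionConfig, CalibrationCurve, GroundTruth,
                    HillParams, simulate_recording)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def calib():
    return CalibrationCurve()


@pytest.fixture(scope="session")
def hill():
    return HillParams()


@pytest.fixture(scope="session")
def default_truth():
    return GroundTruth(seed=12345)


@pytest.fixture(scope="session")
def small_recording(default_truth, acq, calib):
    """An 8000-cycle (2 s) simulated measurement with default truth."""
    rec, transits = simulate_recording(default_truth, acq, n_cycles=8000,
                                       calib=calib)
    return rec, transits


def make_square_dip_trace(n=4000, level=100, dip_level=20,
                          dips=((1000, 1040),)):
    """Noiseless trace with rectangular fluorescence dips."""
    trace = np.full(n, level, dtype=np.int64)
    for s, e in dips:
        trace[s:e] = dip_level
    return trace
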