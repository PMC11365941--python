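import numpy as np
import pytest

from spinecomp.layout import SpineLayout
from spinecomp.rdmodel import REFERENCE_PARAMS, simulate
from spinecomp.fitting import TargetTrajectory

SNAPSHOT_TIMES = np.arange(2.0, 41.0, 2.0)


@pytest.fixture(scope="session")
def three_layout():
    return SpineLayout(np.array([0.0, 1.6, 3.2]), np.ones(3, bool),
                       paradigm="three")


@pytest.fixture(scope="session")
def single_layout():
    return SpineLayout(np.array([0.0]), np.array([True]), paradigm="single")


@pytest.fixture(scope="session")
def snapshot_times():
    return SNAPSHOT_TIMES


@pytest.fixture(scope="session")
def three_truth(three_layout):
    """Noiseless reference simulation of the three-spine layout (dt = 0.1,
    matching the fitting default so model/target comparisons are exact)."""
    return simulate(three_layout, REFERENCE_PARAMS, SNAPSHOT_TIMES, dt=0.1)


@pytest.fixture(scope="session")
def three_target(three_truth):
    return TargetTrajectory(SNAPSHOT_TIMES, three_truth.mean_stim_trajectory())
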