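import numpy as np
import pytest

from beeodom import flat_course_8m, long_course_100m
from beeodom.simulate import simulate


@pytest.fixture(scope="session")
def short_course_runs():
    """The 8 m flat course under tail / no / head wind, with trajectories."""
    cfgs = [flat_course_8m(k) for k in (1.0, 0.0, -1.0)]
    return simulate(cfgs, record=True, log_every=1)


@pytest.fixture(scope="session")
def long_flat_runs():
    """The 100 m flat course under tail / no / head wind, with trajectories."""
    cfgs = [long_course_100m(k) for k in (1.0, 0.0, -1.0)]
    return simulate(cfgs, record=True, log_every=10)


def cruise_window(traj, x_lo=2.0, x_hi=None):
    """Rows of a trajectory inside the cruise section of its course."""
    x_hi = x_hi if x_hi is not None else traj["x"].max() - 4.5
    return traj[(traj["x"] > x_lo) & (traj["x"] < x_hi)]
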