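import numpy as np
import pytest

from mitoclock import (
    default_sensors,
    default_wt,
    simulate_trajectory,
)
from mitoclock.simulate import simulate_population, trajectory_trace_frame


@pytest.fixture(scope="session")
def wt_trajectory():
    """One noiseless wild-type cell through a full mitotic entry/exit."""
    return simulate_trajectory(default_wt(), default_sensors(), duration=160.0)


@pytest.fixture(scope="session")
def wt_trace_frame(wt_trajectory):
    """Noiseless trace table of the wild-type cell at 5-min sampling."""
    return trajectory_trace_frame(wt_trajectory, dt_img=5.0)


@pytest.fixture(scope="session")
def small_wt_cohort():
    """A 25-cell wild-type cohort with default variability and noise."""
    return simulate_population(
        default_wt(), default_sensors(), n_cells=25, seed=11, duration=160.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
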