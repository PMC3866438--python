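import numpy as np
import pytest

from boundarycell import (
    RateMap,
    SpikeTrain,
    Trajectory,
    make_standard_environment,
)


@pytest.fixture(scope="session")
def walled_circle():
    return make_standard_environment("walled_circle")


@pytest.fixture(scope="session")
def walled_square():
    return make_standard_environment("walled_square")


def make_map(rate: np.ndarray, bin_size: float = 3.0, dwell_s: float = 1.0) -> RateMap:
    """Construct a RateMap directly from a rate grid (NaN = unvisited), with
    the grid symmetric about the origin (a bin corner at the centre)."""
    rate = np.asarray(rate, dtype=float)
    nx, ny = rate.shape
    x_edges = bin_size * (np.arange(nx + 1) - nx / 2)
    y_edges = bin_size * (np.arange(ny + 1) - ny / 2)
    visited = ~np.isnan(rate)
    dwell = np.where(visited, dwell_s, 0.0)
    counts = np.where(visited, rate * dwell_s, 0.0)
    return RateMap(x_edges, y_edges, dwell, counts, rate, visited, True, bin_size)


def straight_trajectory(duration: float, speed: float, dt: float = 0.02) -> Trajectory:
    """Constant-speed eastward path starting at the origin."""
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    return Trajectory(t, speed * t, np.zeros(n), np.zeros(n), dt)


def spikes(times, duration=None) -> SpikeTrain:
    times = np.asarray(times, dtype=float)
    if duration is None:
        duration = float(times[-1]) + 1.0 if len(times) else 1.0
    return SpikeTrain(times, duration)
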