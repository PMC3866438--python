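"""Locational firing-rate maps and directional polar tuning curves.

Rate maps use square bins (default 3 x 3 cm) with the grid aligned so a bin
corner sits at the environment centre; rate per bin is spike count over dwell
time.  Smoothing is a 5 x 5 boxcar applied to counts and dwell separately
before dividing, with the kernel renormalised over visited bins so rates are
not diluted at the map border (where boundary-cell fields live).  Polar plots
use 60 bins of 6 degrees with a circular 5-bin boxcar.

Spikes are assigned to the temporally nearest tracked position (at most 10 ms
error at 50 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .synth import SpikeTrain, Trajectory

__all__ = [
    "RateMap",
    "PolarMap",
    "filter_positions",
    "compute_rate_map",
    "compute_polar_map",
    "windowed_maps",
    "SPEED_CAP_CM_S",
]

#: tracking speed cap, cm/s; faster samples are artefacts of head movement
SPEED_CAP_CM_S = 200.0

N_DIR_BINS = 60  # 6 degree bins


@dataclass
class RateMap:
    """Binned locational firing-rate estimate.

    ``counts`` and ``dwell`` are always the raw (unsmoothed) per-bin spike
    counts and occupancy seconds, so their sums conserve the filtered spike
    count and trial duration; ``rate`` is smoothed when ``smoothed`` is True.
    Unvisited bins carry NaN rate.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    dwell: np.ndarray
    counts: np.ndarray
    rate: np.ndarray
    visited: np.ndarray
    smoothed: bool
    bin_size: float

    @property
    def peak_rate(self) -> float:
        """Highest rate over visited bins, Hz."""
        if not self.visited.any():
            return 0.0
        return float(np.nanmax(self.rate[self.visited]))

    def bin_centres(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            0.5 * (self.x_edges[:-1] + self.x_edges[1:]),
            0.5 * (self.y_edges[:-1] + self.y_edges[1:]),
        )

    def mean_rate(self) -> float:
        """Dwell-weighted mean rate over visited bins (equals global mean rate
        for unsmoothed maps)."""
        d = self.dwell[self.visited]
        raw = np.where(d > 0, self.counts[self.visited] / np.where(d > 0, d, 1), 0.0)
        return float((d * raw).sum() / d.sum()) if d.sum() > 0 else 0.0


@dataclass
class PolarMap:
    """Binned directional firing-rate estimate over 60 bins of 6 degrees."""

    edges: np.ndarray
    dwell: np.ndarray
    counts: np.ndarray
    rate: np.ndarray
    visited: np.ndarray
    smoothed: bool

    @property
    def peak_rate(self) -> float:
        if not self.visited.any():
            return 0.0
        return float(np.nanmax(self.rate[self.visited]))

    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def filter_positions(trajectory: Trajectory, speed_cap: float = SPEED_CAP_CM_S) -> Trajectory:
    """Drop samples whose instantaneous (centred-difference) speed exceeds
    the cap; such jumps are tracking artefacts, not locomotion."""
    if len(trajectory) < 2:
        return trajectory
    keep = trajectory.speed() <= speed_cap
    return Trajectory(
        trajectory.t[keep], trajectory.x[keep], trajectory.y[keep], trajectory.hd[keep], trajectory.dt
    )


def _grid_edges(values: np.ndarray, bin_size: float, extent: tuple[float, float] | None) -> np.ndarray:
    """1-D bin edges at integer multiples of bin_size (a bin corner at the
    origin), covering the data or the requested extent."""
    if extent is None:
        lo, hi = float(values.min()), float(values.max())
    else:
        lo, hi = extent
    i0 = int(np.floor(lo / bin_size))
    i1 = int(np.ceil(hi / bin_size))
    if i1 == i0:
        i1 += 1
    return bin_size * np.arange(i0, i1 + 1)


def _assign_spikes(trajectory: Trajectory, spikes: SpikeTrain) -> np.ndarray:
    """Index of the temporally nearest trajectory sample for every spike."""
    idx = np.searchsorted(trajectory.t, spikes.times)
    idx = np.clip(idx, 1, len(trajectory) - 1)
    left = np.abs(spikes.times - trajectory.t[idx - 1]) <= np.abs(trajectory.t[idx] - spikes.times)
    return np.where(left, idx - 1, idx)


def _boxcar_visited(arr: np.ndarray, visited: np.ndarray, size: int = 5) -> np.ndarray:
    """Boxcar sum over visited bins only (masked convolution)."""
    return uniform_filter(np.where(visited, arr, 0.0), size=size, mode="constant") * size**2


def compute_rate_map(
    trajectory: Trajectory,
    spikes: SpikeTrain,
    bin_size: float = 3.0,
    smooth: bool = True,
    smooth_mode: str = "counts_dwell",
    extent: tuple[float, float, float, float] | None = None,
) -> RateMap:
    """Locational firing-rate map.

    With ``smooth`` the 5 x 5 boxcar is applied to counts and dwell separately
    over visited bins and the smoothed fields divided (``smooth_mode=
    'counts_dwell'``, the default, numerically stable at low occupancy), or
    directly to the raw rate (``smooth_mode='rate'``).  ``extent`` fixes the
    grid to (xmin, xmax, ymin, ymax) so maps from different time windows
    share bins.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    if smooth_mode not in ("counts_dwell", "rate"):
        raise ValueError(f"unknown smooth_mode {smooth_mode!r}")
    x_ext = None if extent is None else (extent[0], extent[1])
    y_ext = None if extent is None else (extent[2], extent[3])
    x_edges = _grid_edges(trajectory.x, bin_size, x_ext)
    y_edges = _grid_edges(trajectory.y, bin_size, y_ext)

    dwell = (
        np.histogram2d(trajectory.x, trajectory.y, bins=(x_edges, y_edges))[0] * trajectory.dt
    )
    sidx = _assign_spikes(trajectory, spikes) if len(spikes) else np.empty(0, dtype=int)
    counts = np.histogram2d(
        trajectory.x[sidx], trajectory.y[sidx], bins=(x_edges, y_edges)
    )[0]
    visited = dwell > 0

    raw = np.full(dwell.shape, np.nan)
    raw[visited] = counts[visited] / dwell[visited]
    if smooth:
        if smooth_mode == "counts_dwell":
            sc = _boxcar_visited(counts, visited)
            sd = _boxcar_visited(dwell, visited)
            rate = np.full(dwell.shape, np.nan)
            ok = visited & (sd > 0)
            rate[ok] = sc[ok] / sd[ok]
        else:
            num = _boxcar_visited(np.where(visited, raw, 0.0), visited)
            den = _boxcar_visited(visited.astype(float), visited)
            rate = np.full(dwell.shape, np.nan)
            ok = visited & (den > 0)
            rate[ok] = num[ok] / den[ok]
    else:
        rate = raw
    return RateMap(x_edges, y_edges, dwell, counts, rate, visited, smooth, bin_size)


def compute_polar_map(
    trajectory: Trajectory, spikes: SpikeTrain, smooth: bool = True, n_bins: int = N_DIR_BINS
) -> PolarMap:
    """Directional firing-rate tuning curve over ``n_bins`` bins tiling the
    circle, smoothed by a circular 5-bin boxcar (each bin plus its two
    neighbours on both sides)."""
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    edges = np.linspace(0.0, 2.0 * np.pi, n_bins + 1)
    hd = np.mod(trajectory.hd, 2.0 * np.pi)
    dwell = np.histogram(hd, bins=edges)[0] * trajectory.dt
    sidx = _assign_spikes(trajectory, spikes) if len(spikes) else np.empty(0, dtype=int)
    counts = np.histogram(hd[sidx], bins=edges)[0].astype(float)
    visited = dwell > 0

    raw = np.full(n_bins, np.nan)
    raw[visited] = counts[visited] / dwell[visited]
    if smooth:
        kernel = np.ones(5)
        vc = np.where(visited, counts, 0.0)
        vd = np.where(visited, dwell, 0.0)
        sc = np.convolve(np.r_[vc[-2:], vc, vc[:2]], kernel, mode="valid")
        sd = np.convolve(np.r_[vd[-2:], vd, vd[:2]], kernel, mode="valid")
        rate = np.full(n_bins, np.nan)
        ok = visited & (sd > 0)
        rate[ok] = sc[ok] / sd[ok]
    else:
        rate = raw
    return PolarMap(edges, dwell, counts, rate, visited, smooth)


def windowed_maps(
    trajectory: Trajectory,
    spikes: SpikeTrain,
    t0: float,
    t1: float,
    **kwargs,
) -> RateMap:
    """Rate map restricted to trajectory samples and spikes in [t0, t1).

    Pass ``extent`` via kwargs to keep the bin grid identical across windows
    (otherwise each window's grid covers just its own positions).
    """
    if not t0 < t1:
        raise ValueError("need t0 < t1")
    sub_traj = trajectory.slice_time(t0, t1)
    if len(sub_traj) == 0:
        raise ValueError(f"no trajectory samples in window [{t0}, {t1})")
    sub_spikes = spikes.slice_time(t0, t1)
    return compute_rate_map(sub_traj, sub_spikes, **kwargs)
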