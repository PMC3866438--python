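"""Temporal firing statistics: global mean rate and theta modulation.

Theta modulation is scored from the power spectrum of the spike-train 500 ms
autocorrelogram, using only spikes emitted during runs (speed above 5 cm/s
sustained for at least 0.5 s).  The autocorrelogram is binned at 4 ms, so its
spectrum spans exactly 0-125 Hz; the score is the mean power in a 2 Hz band
centred on the spectral peak within 6-12 Hz, divided by the mean power over
the whole 0-125 Hz spectrum.  The theta peak frequency is found per cell, not
fixed in advance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import SpikeTrain, Trajectory

__all__ = [
    "ThetaScore",
    "global_mean_rate",
    "extract_runs",
    "spikes_in_intervals",
    "spike_autocorrelogram",
    "theta_modulation_score",
    "ACG_WINDOW_S",
    "ACG_BIN_S",
]

ACG_WINDOW_S = 0.5
ACG_BIN_S = 0.004  # 4 ms -> Nyquist 125 Hz
RUN_SPEED_CM_S = 5.0
RUN_MIN_S = 0.5
THETA_BAND_HZ = (6.0, 12.0)


@dataclass(frozen=True)
class ThetaScore:
    peak_freq: float  # Hz, within 6-12
    band_power: float  # mean power in the 2 Hz band around the peak
    total_power: float  # mean power over 0-125 Hz
    score: float  # band / total


def global_mean_rate(spikes: SpikeTrain, duration: float | None = None) -> float:
    """Number of spikes divided by the trial length in seconds."""
    duration = spikes.duration if duration is None else duration
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return len(spikes) / duration


def extract_runs(
    trajectory: Trajectory,
    speed_threshold: float = RUN_SPEED_CM_S,
    min_duration: float = RUN_MIN_S,
) -> list[tuple[float, float]]:
    """Maximal time intervals where speed exceeds the threshold, kept only if
    at least ``min_duration`` long."""
    if len(trajectory) < 2:
        return []
    fast = trajectory.speed() > speed_threshold
    edges = np.diff(fast.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if fast[0]:
        starts.insert(0, 0)
    if fast[-1]:
        ends.append(len(fast))
    runs = []
    for a, b in zip(starts, ends):
        t0 = trajectory.t[a]
        t1 = trajectory.t[b - 1] + trajectory.dt
        if t1 - t0 >= min_duration:
            runs.append((float(t0), float(t1)))
    return runs


def spikes_in_intervals(spikes: SpikeTrain, intervals: list[tuple[float, float]]) -> SpikeTrain:
    """Spikes falling inside any of the (half-open) time intervals."""
    if not intervals or len(spikes) == 0:
        return SpikeTrain(np.empty(0), spikes.duration)
    keep = np.zeros(len(spikes), dtype=bool)
    for t0, t1 in intervals:
        keep |= (spikes.times >= t0) & (spikes.times < t1)
    return SpikeTrain(spikes.times[keep], spikes.duration)


def spike_autocorrelogram(
    spikes: SpikeTrain,
    window: float = ACG_WINDOW_S,
    bin_size: float = ACG_BIN_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of ordered spike-time differences in (0, window].

    Returns (lag bin edges, counts).  The zero-lag bin is excluded: pairs at
    exactly zero lag (duplicate timestamps) are not counted.  Raises for
    fewer than two spikes.
    """
    t = spikes.times
    if len(t) < 2:
        raise ValueError("autocorrelogram needs at least two spikes")
    edges = np.arange(0.0, window + bin_size / 2, bin_size)
    counts = np.zeros(len(edges) - 1)
    # sliding window over the sorted train: all ordered pairs within `window`
    hi = np.searchsorted(t, t + window, side="right")
    for i in range(len(t)):
        d = t[i + 1 : hi[i]] - t[i]
        d = d[d > 0]
        if len(d):
            counts += np.histogram(d, bins=edges)[0]
    return edges, counts


def theta_modulation_score(
    acg_counts: np.ndarray,
    bin_size: float = ACG_BIN_S,
    theta_band: tuple[float, float] = THETA_BAND_HZ,
    half_band: float = 1.0,
    pad_to_s: float = 2.0,
) -> ThetaScore:
    """Theta modulation from an autocorrelogram.

    The mean-subtracted autocorrelogram is zero-padded to at least
    ``pad_to_s`` seconds (frequency resolution <= 0.5 Hz), transformed, and
    the magnitude-squared spectrum inspected: the peak within the theta band
    defines the cell's theta frequency, and the score is the mean power in
    the 2 Hz band centred there over the mean power across 0-125 Hz.  No
    taper is applied by default.
    """
    acg = np.asarray(acg_counts, dtype=float)
    if acg.sum() == 0:
        raise ValueError("autocorrelogram is empty")
    x = acg - acg.mean()
    n = max(int(np.ceil(pad_to_s / bin_size)), len(x))
    n = int(2 ** np.ceil(np.log2(n)))
    power = np.abs(np.fft.rfft(x, n)) ** 2
    freqs = np.fft.rfftfreq(n, d=bin_size)
    nyquist = 0.5 / bin_size
    total_mask = freqs <= nyquist
    total_power = float(power[total_mask].mean())
    if total_power == 0:
        raise ValueError("zero total spectral power")
    band_mask = (freqs >= theta_band[0]) & (freqs <= theta_band[1])
    peak_freq = float(freqs[band_mask][np.argmax(power[band_mask])])
    around = (freqs >= peak_freq - half_band) & (freqs <= peak_freq + half_band)
    band_power = float(power[around].mean())
    return ThetaScore(peak_freq, band_power, total_power, band_power / total_power)
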