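"""Basic rendering of rate maps and polar plots.

Rate maps use five discrete colour bands of 20% of the peak rate each, dark
blue (0-20%) to red (80-100%), matching the conventional false-colour style
of boundary-cell figures.
"""

from __future__ import annotations

import numpy as np

BAND_COLOURS = ["#00008b", "#1e90ff", "#00c957", "#ffd700", "#d22b2b"]


def plot_rate_map(rate_map, ax=None, title: str | None = None):
    """Draw a rate map with five 20%-of-peak colour bands; unvisited bins are
    white.  Returns the matplotlib axes."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    if ax is None:
        _, ax = plt.subplots()
    peak = rate_map.peak_rate
    cmap = ListedColormap(BAND_COLOURS)
    cmap.set_bad("white")
    bounds = np.linspace(0.0, max(peak, 1e-12), 6)
    norm = BoundaryNorm(bounds, cmap.N)
    img = np.where(rate_map.visited, rate_map.rate, np.nan)
    ax.pcolormesh(rate_map.x_edges, rate_map.y_edges, img.T, cmap=cmap, norm=norm)
    ax.set_aspect("equal")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    ax.set_title(title or f"peak {peak:.1f} Hz")
    return ax


def plot_polar_map(polar_map, ax=None, title: str | None = None):
    """Draw a directional tuning curve on polar axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centres = polar_map.bin_centres()
    r = np.where(polar_map.visited, polar_map.rate, 0.0)
    ax.plot(np.r_[centres, centres[0]], np.r_[r, r[0]])
    ax.set_title(title or f"peak {polar_map.peak_rate:.1f} Hz")
    return ax
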