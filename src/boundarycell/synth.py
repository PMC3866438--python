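"""Generative models: foraging trajectories and synthetic spike trains.

Three firing-rate models are provided, matching the cell types the analysis
is designed around:

* **Boundary vector cell (BVC)** — fires when an environmental boundary lies
  at a preferred distance and allocentric direction from the animal,
  independent of heading.  The rate at a position integrates, over allocentric
  directions, a Gaussian in the distance to the nearest boundary along each
  direction times a wrapped Gaussian in direction.  The radial tuning width
  grows linearly with preferred distance.
* **Head-direction (HD) cell** — von-Mises-shaped tuning to allocentric
  heading, independent of location.
* **Boundary-off cell** — fires everywhere except where a matched BVC would
  fire (an inverse BVC).

Spike trains are inhomogeneous Poisson, generated by thinning against the
piecewise-constant rate along a trajectory, optionally multiplied by a theta
(6-12 Hz) modulation factor.  All stochastic operations take explicit integer
seeds.
"""

from __future__ import annotations

import math
import weakref
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.interpolate import RegularGridInterpolator
from shapely.geometry import Point
from shapely.ops import nearest_points

from .environment import Environment, OutsideFloorError, ray_segment_distances

__all__ = [
    "BVCParams",
    "HDParams",
    "BoundaryOffParams",
    "Trajectory",
    "SpikeTrain",
    "simulate_trajectory",
    "bvc_rate",
    "bvc_rate_field",
    "hd_rate",
    "boundary_off_rate",
    "boundary_off_rate_field",
    "hd_rate_fn",
    "generate_spikes",
    "SpatialRateField",
]

SAMPLE_RATE_HZ = 50.0
DT = 1.0 / SAMPLE_RATE_HZ

#: rays used to integrate the boundary response around the circle (1 deg steps)
N_RAYS = 360

#: grid step (cm) for rate-surface precomputation and peak normalisation
FIELD_GRID_STEP = 3.0


@dataclass(frozen=True)
class BVCParams:
    """Boundary-vector-cell tuning parameters.

    d_pref : preferred boundary distance, cm.
    phi_pref : preferred allocentric direction, radians CCW from east.
    sigma0 : radial tuning width at zero preferred distance, cm.
    beta : distance-broadening constant, cm (sigma_rad = sigma0*(d_pref/beta+1)).
    sigma_ang : angular tuning width, radians.
    a_max : peak firing rate over the environment, Hz.
    """

    d_pref: float
    phi_pref: float
    sigma0: float = 12.0
    beta: float = 180.0
    sigma_ang: float = 0.2
    a_max: float = 10.0

    def __post_init__(self) -> None:
        if self.d_pref < 0:
            raise ValueError("d_pref must be >= 0")
        if min(self.sigma0, self.beta, self.sigma_ang, self.a_max) <= 0:
            raise ValueError("sigma0, beta, sigma_ang, a_max must be > 0")

    @property
    def sigma_rad(self) -> float:
        return self.sigma0 * (self.d_pref / self.beta + 1.0)


@dataclass(frozen=True)
class HDParams:
    """Head-direction-cell tuning: preferred heading mu, concentration kappa,
    peak rate a_max (Hz)."""

    mu: float
    kappa: float = 8.0
    a_max: float = 30.0

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.a_max <= 0:
            raise ValueError("kappa and a_max must be > 0")


@dataclass(frozen=True)
class BoundaryOffParams:
    """Inverse-BVC parameters: uniform ``baseline`` rate (Hz) suppressed by a
    matched BVC's normalised field; ``suppression`` in [0, 1]."""

    baseline: float
    suppression: float
    bvc: BVCParams

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be > 0")
        if not 0.0 <= self.suppression <= 1.0:
            raise ValueError("suppression must be in [0, 1]")


@dataclass
class Trajectory:
    """Time-stamped 2-D head positions and head direction, 50 Hz nominal."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    hd: np.ndarray
    dt: float = DT

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.hd = np.asarray(self.hd, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.hd)):
            raise ValueError("t, x, y, hd must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0] + self.dt) if len(self) else 0.0

    def speed(self) -> np.ndarray:
        """Instantaneous speed (cm/s) by centred differences; one-sided at
        the ends."""
        if len(self) < 2:
            return np.zeros(len(self))
        vx = np.gradient(self.x, self.t)
        vy = np.gradient(self.y, self.t)
        return np.hypot(vx, vy)

    def slice_time(self, t0: float, t1: float) -> "Trajectory":
        m = (self.t >= t0) & (self.t < t1)
        return Trajectory(self.t[m], self.x[m], self.y[m], self.hd[m], self.dt)


@dataclass
class SpikeTrain:
    """Sorted spike times (s) within [0, duration]."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) and (
            np.any(np.diff(self.times) < 0)
            or self.times[0] < 0
            or self.times[-1] > self.duration + 1e-9
        ):
            raise ValueError("spike times must be sorted and within [0, duration]")

    def __len__(self) -> int:
        return len(self.times)

    def slice_time(self, t0: float, t1: float) -> "SpikeTrain":
        m = (self.times >= t0) & (self.times < t1)
        return SpikeTrain(self.times[m], self.duration)


# ---------------------------------------------------------------------- #
# rate models


def _ray_angles(n_rays: int = N_RAYS) -> np.ndarray:
    return (np.arange(n_rays) + 0.5) * (2.0 * np.pi / n_rays)


def wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a), 2.0 * np.pi)


def bvc_response(params: BVCParams, env: Environment, positions, n_rays: int = N_RAYS) -> np.ndarray:
    """Unnormalised BVC boundary response at each position.

    Integrates, over ``n_rays`` allocentric directions, the product of a
    Gaussian in (boundary distance - d_pref) and a wrapped Gaussian in
    (direction - phi_pref).  Heading-independent by construction.  Rays that
    hit no boundary contribute zero.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    thetas = _ray_angles(n_rays)
    p0, p1 = env.segment_arrays
    dist = ray_segment_distances(positions, thetas, p0, p1, chunk=64)
    g_ang = np.exp(-(wrap_angle(thetas - params.phi_pref) ** 2) / (2.0 * params.sigma_ang**2))
    with np.errstate(invalid="ignore"):
        g_rad = np.exp(-((dist - params.d_pref) ** 2) / (2.0 * params.sigma_rad**2))
    g_rad[~np.isfinite(dist)] = 0.0
    return (g_rad * g_ang[None, :]).mean(axis=1)


class SpatialRateField:
    """A firing-rate surface precomputed on a regular grid over the floor.

    Provides fast bilinear interpolation for spike generation along long
    trajectories, plus the surface maximum used for peak normalisation.
    Points outside the free floor carry rate zero.
    """

    def __init__(self, env: Environment, response_at, grid_step: float = FIELD_GRID_STEP):
        xmin, ymin, xmax, ymax = env.floor.bounds
        xs = np.arange(xmin - grid_step, xmax + 2 * grid_step, grid_step)
        ys = np.arange(ymin - grid_step, ymax + 2 * grid_step, grid_step)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        inside = env.contains(gx.ravel(), gy.ravel())
        vals = np.zeros(gx.size)
        pts = np.c_[gx.ravel()[inside], gy.ravel()[inside]]
        if len(pts):
            vals[inside] = response_at(pts)
        self.values = vals.reshape(gx.shape)
        self.max = float(self.values.max())
        self.xs, self.ys = xs, ys
        self._interp = RegularGridInterpolator(
            (xs, ys), self.values, bounds_error=False, fill_value=0.0
        )

    def __call__(self, x, y) -> np.ndarray:
        return self._interp(np.c_[np.atleast_1d(x), np.atleast_1d(y)])

    def as_rate_fn(self):
        """Adapter with the ``rate_fn(trajectory) -> rates`` signature used by
        :func:`generate_spikes`."""
        return lambda traj: self(traj.x, traj.y)


# normalisation maxima cached per environment (identity) and parameter set
_norm_cache: "weakref.WeakKeyDictionary[Environment, dict]" = weakref.WeakKeyDictionary()


def _bvc_norm_max(params: BVCParams, env: Environment, grid_step: float = FIELD_GRID_STEP) -> float:
    per_env = _norm_cache.setdefault(env, {})
    key = (params, grid_step)
    if key not in per_env:
        per_env[key] = SpatialRateField(
            env, lambda pts: bvc_response(params, env, pts), grid_step
        )
    return per_env[key].max


def bvc_rate(params: BVCParams, env: Environment, position) -> float | np.ndarray:
    """BVC firing rate (Hz) at one or more positions inside the floor.

    Normalised so the maximum over the environment equals ``a_max`` (the
    maximum is located on a ``FIELD_GRID_STEP`` grid and cached per
    environment).  Raises :class:`OutsideFloorError` for invalid positions.
    """
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    ok = env.contains(pos[:, 0], pos[:, 1])
    if not np.all(ok):
        bad = pos[~np.atleast_1d(ok)][0]
        raise OutsideFloorError(f"position {tuple(bad)} is not inside the floor")
    resp = bvc_response(params, env, pos)
    rate = params.a_max * resp / _bvc_norm_max(params, env)
    return float(rate[0]) if np.ndim(position) == 1 else rate


def bvc_rate_field(params: BVCParams, env: Environment, grid_step: float = FIELD_GRID_STEP) -> SpatialRateField:
    """Precomputed, a_max-normalised BVC rate surface for ``env``."""
    per_env = _norm_cache.setdefault(env, {})
    key = (params, grid_step)
    if key not in per_env:
        per_env[key] = SpatialRateField(
            env, lambda pts: bvc_response(params, env, pts), grid_step
        )
    raw = per_env[key]
    out = SpatialRateField.__new__(SpatialRateField)
    out.values = params.a_max * raw.values / raw.max
    out.max = params.a_max
    out.xs, out.ys = raw.xs, raw.ys
    out._interp = RegularGridInterpolator(
        (raw.xs, raw.ys), out.values, bounds_error=False, fill_value=0.0
    )
    return out


def hd_rate(params: HDParams, hd) -> float | np.ndarray:
    """Head-direction tuning: circular-Gaussian (von-Mises-shaped) rate with
    maximum ``a_max`` at ``mu``, independent of location."""
    r = params.a_max * np.exp(params.kappa * (np.cos(np.asarray(hd) - params.mu) - 1.0))
    return float(r) if np.ndim(hd) == 0 else r


def hd_rate_fn(params: HDParams):
    """``rate_fn(trajectory)`` adapter for an HD cell."""
    return lambda traj: hd_rate(params, traj.hd)


def boundary_off_rate(params: BoundaryOffParams, env: Environment, position) -> float | np.ndarray:
    """Boundary-off rate: ``baseline * (1 - suppression * bvc_rate/a_max)``,
    floored at zero."""
    norm = np.asarray(bvc_rate(params.bvc, env, position)) / params.bvc.a_max
    r = np.maximum(params.baseline * (1.0 - params.suppression * norm), 0.0)
    return float(r) if np.ndim(position) == 1 else r


def boundary_off_rate_field(
    params: BoundaryOffParams, env: Environment, grid_step: float = FIELD_GRID_STEP
) -> SpatialRateField:
    """Precomputed boundary-off rate surface (baseline minus the matched BVC
    field)."""
    bf = bvc_rate_field(params.bvc, env, grid_step)
    out = SpatialRateField.__new__(SpatialRateField)
    vals = np.maximum(params.baseline * (1.0 - params.suppression * bf.values / params.bvc.a_max), 0.0)
    # outside-floor grid nodes keep rate 0 so interpolated rates vanish off-floor
    gx, gy = np.meshgrid(bf.xs, bf.ys, indexing="ij")
    vals[~env.contains(gx.ravel(), gy.ravel()).reshape(vals.shape)] = 0.0
    out.values = vals
    out.max = float(vals.max())
    out.xs, out.ys = bf.xs, bf.ys
    out._interp = RegularGridInterpolator((bf.xs, bf.ys), vals, bounds_error=False, fill_value=0.0)
    return out


# ---------------------------------------------------------------------- #
# trajectory simulation


def simulate_trajectory(
    env: Environment,
    duration: float = 1620.0,
    seed: int = 0,
    speed_mean: float = 25.0,
    wall_clearance: float = 5.0,
    barrier_clearance: float = 2.0,
    turn_sd: float = 2.2,
    speed_sd: float = 12.0,
    speed_tau: float = 1.5,
    hd_jitter: float = 0.2,
) -> Trajectory:
    """Simulate a random-foraging path confined to the floor.

    Heading follows a bounded-increment random walk (``turn_sd`` rad/sqrt(s));
    speed follows a positive, autocorrelated Ornstein-Uhlenbeck process with
    mean ``speed_mean`` (cm/s) and relaxation time ``speed_tau`` (s).  The
    path is confined to the floor eroded by ``wall_clearance`` (the tracked
    head position stays clear of walls); around an inserted barrier a smaller
    ``barrier_clearance`` applies, since the head closely approaches and
    overhangs the thin barrier.  At a boundary the heading is reflected about
    the local boundary normal with added noise.  Head direction is the
    movement heading plus independent jitter.  Deterministic given ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    region = env.floor.buffer(-wall_clearance)
    if env.barrier is not None:
        region = region.difference(env.barrier.footprint().buffer(barrier_clearance))
    if region.is_empty:
        raise ValueError(f"wall_clearance {wall_clearance} cm leaves no free floor")
    shapely.prepare(region)
    boundary = region.boundary

    rng = np.random.default_rng(seed)
    n = int(round(duration * SAMPLE_RATE_HZ))
    xi_s = rng.standard_normal(n)
    xi_h = rng.standard_normal(n)
    xi_hd = rng.standard_normal(n)

    start = region.representative_point()
    px, py = start.x, start.y
    h = rng.uniform(0.0, 2.0 * np.pi)
    s = speed_mean

    x = np.empty(n)
    y = np.empty(n)
    heading = np.empty(n)
    sqdt = math.sqrt(DT)
    for i in range(n):
        s += (speed_mean - s) * (DT / speed_tau) + speed_sd * sqdt * xi_s[i]
        s = min(max(s, 0.0), 100.0)
        h += turn_sd * sqdt * xi_h[i]
        nx = px + s * DT * math.cos(h)
        ny = py + s * DT * math.sin(h)
        if not shapely.contains_xy(region, nx, ny):
            q = nearest_points(boundary, Point(px, py))[0]
            nvx, nvy = px - q.x, py - q.y
            nn = math.hypot(nvx, nvy)
            if nn > 1e-9:
                nvx, nvy = nvx / nn, nvy / nn
                dx, dy = math.cos(h), math.sin(h)
                dot = dx * nvx + dy * nvy
                if dot < 0:
                    dx, dy = dx - 2 * dot * nvx, dy - 2 * dot * nvy
                h = math.atan2(dy, dx) + 0.3 * xi_h[i]
            else:
                h += math.pi
            nx = px + s * DT * math.cos(h)
            ny = py + s * DT * math.sin(h)
            if not shapely.contains_xy(region, nx, ny):
                nx, ny = px, py
        px, py = nx, ny
        x[i] = px
        y[i] = py
        heading[i] = h
    hd = wrap_angle(heading + hd_jitter * xi_hd)
    t = np.arange(n) * DT
    return Trajectory(t, x, y, hd)


# ---------------------------------------------------------------------- #
# spike generation


def generate_spikes(
    rate_fn,
    trajectory: Trajectory,
    seed: int = 0,
    theta: dict | None = None,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spike train by thinning.

    ``rate_fn(trajectory)`` must return the non-negative rate (Hz) at every
    trajectory sample; the rate is treated as piecewise-constant over each
    20 ms sample interval.  If ``theta={'f0': Hz, 'depth': 0-1}`` is given the
    rate is multiplied by ``1 + depth*cos(2*pi*f0*t)`` at the candidate spike
    time.  Deterministic given ``seed``.
    """
    rates = np.asarray(rate_fn(trajectory), dtype=float)
    if rates.shape != trajectory.t.shape:
        raise ValueError("rate_fn must return one rate per trajectory sample")
    if np.any(rates < 0):
        raise ValueError("rate_fn returned negative rates")
    depth = 0.0
    f0 = 0.0
    if theta is not None:
        f0 = float(theta["f0"])
        depth = float(theta["depth"])
        if not 0.0 <= depth <= 1.0:
            raise ValueError("theta depth must be in [0, 1]")
    duration = trajectory.duration
    rmax = rates.max(initial=0.0) * (1.0 + depth)
    if rmax == 0.0 or duration <= 0:
        return SpikeTrain(np.empty(0), duration)
    rng = np.random.default_rng(seed)
    n_cand = rng.poisson(rmax * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    idx = np.clip(np.searchsorted(trajectory.t - trajectory.t[0], cand, side="right") - 1, 0, len(trajectory) - 1)
    lam = rates[idx]
    if depth > 0.0:
        lam = lam * (1.0 + depth * np.cos(2.0 * np.pi * f0 * cand))
    keep = rng.uniform(0.0, 1.0, n_cand) < lam / rmax
    return SpikeTrain(cand[keep], duration)
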