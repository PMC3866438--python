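"""Rate maps, polar tuning curves, speed filtering and windowed maps."""

import math

import numpy as np
import pytest

from boundarycell import (
    BVCParams,
    SpikeTrain,
    Trajectory,
    bvc_rate_field,
    compute_polar_map,
    compute_rate_map,
    filter_positions,
    generate_spikes,
    make_standard_environment,
    simulate_trajectory,
    windowed_maps,
)
from conftest import spikes, straight_trajectory


@pytest.fixture(scope="module")
def foraging():
    env = make_standard_environment("walled_square")
    traj = simulate_trajectory(env, duration=120.0, seed=9)
    rng = np.random.default_rng(1)
    times = np.sort(rng.uniform(0, traj.duration, 600))
    return traj, SpikeTrain(times, traj.duration)


class TestFilterPositions:
    def test_slow_trace_unchanged(self):
        traj = straight_trajectory(10.0, speed=30.0)
        out = filter_positions(traj)
        assert len(out) == len(traj)

    def test_jump_artefact_samples_removed(self):
        # a one-sample tracking glitch produces a >200 cm/s centred-difference
        # speed at the sample preceding it (30 + 8/0.04 cm/s forward) while
        # the following one swings to -170 cm/s; exactly the former is dropped
        traj = straight_trajectory(10.0, speed=30.0)
        x = traj.x.copy()
        x[250] += 8.0
        jump = Trajectory(traj.t, x, traj.y, traj.hd)
        out = filter_positions(jump)
        removed = set(traj.t) - set(out.t)
        assert removed == {traj.t[249]}

    def test_mixed_trace_matches_per_sample_oracle(self):
        rng = np.random.default_rng(2)
        n = 500
        t = np.arange(n) * 0.02
        x = np.cumsum(rng.normal(0, 0.5, n))
        y = np.cumsum(rng.normal(0, 0.5, n))
        x[rng.integers(0, n, 10)] += rng.uniform(5, 20, 10)
        traj = Trajectory(t, x, y, np.zeros(n))
        vx, vy = np.gradient(x, t), np.gradient(y, t)
        expected = np.hypot(vx, vy) <= 200.0
        assert len(filter_positions(traj)) == expected.sum()


class TestRateMap:
    def test_zero_spikes_gives_zero_rates(self, foraging):
        traj, _ = foraging
        m = compute_rate_map(traj, SpikeTrain(np.empty(0), traj.duration))
        assert m.peak_rate == 0.0
        assert np.all(m.rate[m.visited] == 0.0)

    def test_conservation_of_dwell_and_counts(self, foraging):
        traj, sp = foraging
        m = compute_rate_map(traj, sp)
        assert m.dwell.sum() == pytest.approx(len(traj) * traj.dt)
        assert m.counts.sum() == len(sp)

    def test_spikes_at_every_sample_give_flat_map(self, foraging):
        # one spike per position sample => raw and smoothed rate = 1/dt
        traj, _ = foraging
        sp = SpikeTrain(traj.t + 1e-4, traj.duration)
        for smooth in (False, True):
            m = compute_rate_map(traj, sp, smooth=smooth)
            assert np.allclose(m.rate[m.visited], 1.0 / traj.dt)

    def test_smoothing_matches_direct_convolution_oracle(self, foraging):
        traj, sp = foraging
        m = compute_rate_map(traj, sp, smooth=True)
        raw = compute_rate_map(traj, sp, smooth=False)
        nx, ny = raw.counts.shape
        for i, j in [(0, 0), (3, 4), (nx // 2, ny // 2), (nx - 1, ny - 1)]:
            if not raw.visited[i, j]:
                continue
            c = d = 0.0
            for di in range(-2, 3):
                for dj in range(-2, 3):
                    a, b = i + di, j + dj
                    if 0 <= a < nx and 0 <= b < ny and raw.visited[a, b]:
                        c += raw.counts[a, b]
                        d += raw.dwell[a, b]
            assert m.rate[i, j] == pytest.approx(c / d)

    def test_superposing_identical_train_doubles_unsmoothed_rates(self, foraging):
        traj, sp = foraging
        m1 = compute_rate_map(traj, sp, smooth=False)
        doubled = SpikeTrain(np.sort(np.r_[sp.times, sp.times]), sp.duration)
        m2 = compute_rate_map(traj, doubled, smooth=False)
        assert np.allclose(m2.rate[m2.visited], 2 * m1.rate[m1.visited])

    def test_empty_trajectory_rejected(self):
        empty = Trajectory(np.empty(0), np.empty(0), np.empty(0), np.empty(0))
        with pytest.raises(ValueError):
            compute_rate_map(empty, SpikeTrain(np.empty(0), 0.0))


class TestPolarMap:
    def test_spikes_in_one_bin_smooth_to_five(self):
        # heading fixed in directional bin k: smoothed rate nonzero exactly
        # in bins k-2..k+2
        n = 1000
        t = np.arange(n) * 0.02
        hd_all = np.linspace(0, 2 * math.pi, n, endpoint=False)  # visit all bins
        traj = Trajectory(t, np.zeros(n), np.zeros(n), hd_all)
        k = 17
        centre = (k + 0.5) * 2 * math.pi / 60
        in_bin = np.abs(hd_all - centre) < (math.pi / 60) * 0.9
        sp = SpikeTrain(t[in_bin] + 1e-4, t[-1] + 0.02)
        m = compute_polar_map(traj, sp)
        nonzero = set(np.nonzero(m.rate > 0)[0])
        assert nonzero == {(k + d) % 60 for d in range(-2, 3)}

    def test_rotation_equivariance(self, foraging):
        traj, sp = foraging
        m1 = compute_polar_map(traj, sp)
        rot = Trajectory(traj.t, traj.x, traj.y, traj.hd + math.pi / 3)
        m2 = compute_polar_map(rot, sp)
        assert np.allclose(np.roll(m1.rate, 10), m2.rate, equal_nan=True)

    def test_conservation(self, foraging):
        traj, sp = foraging
        m = compute_polar_map(traj, sp)
        assert m.counts.sum() == len(sp)
        assert m.dwell.sum() == pytest.approx(len(traj) * traj.dt)

    def test_heading_invariant_cell_is_weakly_tuned(self):
        # a BVC's firing does not depend on heading: directional max/min < 2
        # over a long trial
        env = make_standard_environment("walled_circle")
        params = BVCParams(d_pref=8.0, phi_pref=-math.pi / 2)
        traj = simulate_trajectory(env, duration=1620.0, seed=12)
        sp = generate_spikes(bvc_rate_field(params, env).as_rate_fn(), traj, seed=13)
        m = compute_polar_map(filter_positions(traj), sp)
        rates = m.rate[m.visited]
        assert rates.max() / rates.min() < 2.0


class TestWindowedMaps:
    def test_full_window_identical_to_plain_map(self, foraging):
        traj, sp = foraging
        full = compute_rate_map(traj, sp)
        win = windowed_maps(traj, sp, 0.0, traj.duration + 1.0)
        assert np.allclose(win.rate, full.rate, equal_nan=True)

    def test_disjoint_windows_partition_dwell(self, foraging):
        traj, sp = foraging
        ext = (traj.x.min(), traj.x.max(), traj.y.min(), traj.y.max())
        half = traj.duration / 2
        a = windowed_maps(traj, sp, 0.0, half, extent=ext)
        b = windowed_maps(traj, sp, half, traj.duration + 1.0, extent=ext)
        assert a.dwell.sum() + b.dwell.sum() == pytest.approx(len(traj) * traj.dt)
        assert a.counts.sum() + b.counts.sum() == len(sp)

    def test_empty_window_rejected(self, foraging):
        traj, sp = foraging
        with pytest.raises(ValueError):
            windowed_maps(traj, sp, 1e6, 1e6 + 1.0)

    def test_first_minute_in_apart_shows_duplicate_field(self):
        # a BVC tuned along the long axis of the three-platform array fires
        # at the newly created gap drop within the very first minute
        env = make_standard_environment("apart")
        params = BVCParams(d_pref=8.0, phi_pref=0.0)  # east-tuned
        traj = simulate_trajectory(env, duration=300.0, seed=21)
        sp = generate_spikes(bvc_rate_field(params, env).as_rate_fn(), traj, seed=22)
        win = windowed_maps(
            filter_positions(traj), sp, 0.0, 60.0, extent=(-85, 85, -25, 25)
        )
        # duplicate-field region: just west of the middle platform's east
        # drop edge at x = 25 (the rat starts on the middle platform)
        cx, cy = win.bin_centres()
        cols = (cx >= 25 - 2 * params.d_pref) & (cx <= 25)
        region = win.rate[cols, :]
        ok = ~np.isnan(region)
        assert ok.any()
        assert np.nanmax(region) > 0.4 * win.peak_rate
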