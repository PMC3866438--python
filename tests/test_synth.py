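"""Generative models: BVC/HD/boundary-off rates, trajectories, spike trains."""

import math

import numpy as np
import pytest
from scipy.special import i0

from boundarycell import (
    BoundaryOffParams,
    BVCParams,
    HDParams,
    boundary_off_rate,
    boundary_off_rate_field,
    bvc_rate,
    bvc_rate_field,
    generate_spikes,
    hd_rate,
    insert_barrier,
    simulate_trajectory,
)
from boundarycell.environment import OutsideFloorError

SOUTH = -math.pi / 2


@pytest.fixture(scope="module")
def south_bvc():
    return BVCParams(d_pref=8.0, phi_pref=SOUTH)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(d_pref=-1.0, phi_pref=0.0), dict(d_pref=5.0, phi_pref=0.0, sigma0=0.0),
         dict(d_pref=5.0, phi_pref=0.0, a_max=-2.0)],
    )
    def test_bvc_validation(self, kwargs):
        with pytest.raises(ValueError):
            BVCParams(**kwargs)

    def test_radial_width_broadens_with_distance(self):
        near = BVCParams(d_pref=5.0, phi_pref=0.0)
        far = BVCParams(d_pref=60.0, phi_pref=0.0)
        assert far.sigma_rad > near.sigma_rad

    def test_boundary_off_validation(self):
        bvc = BVCParams(8.0, 0.0)
        with pytest.raises(ValueError):
            BoundaryOffParams(baseline=5.0, suppression=1.5, bvc=bvc)


class TestBVCRate:
    def test_deterministic_and_heading_independent(self, south_bvc, walled_circle):
        # the rate is a function of position only: repeated evaluation at the
        # same position is identical regardless of any notion of heading
        r1 = bvc_rate(south_bvc, walled_circle, (10.0, -30.0))
        r2 = bvc_rate(south_bvc, walled_circle, (10.0, -30.0))
        assert r1 == r2 > 0

    def test_short_range_cell_silent_at_centre(self, south_bvc, walled_circle):
        assert bvc_rate(south_bvc, walled_circle, (0.0, 0.0)) < 0.05 * south_bvc.a_max

    def test_rate_near_peak_at_preferred_offset(self, south_bvc, walled_circle):
        # 8 cm north of the southernmost wall point
        r = bvc_rate(south_bvc, walled_circle, (0.0, -75.0 + 8.0))
        assert r == pytest.approx(south_bvc.a_max, rel=0.02)

    def test_peak_location_near_preferred_distance(self, south_bvc, walled_circle):
        field = bvc_rate_field(south_bvc, walled_circle)
        gx, gy = np.meshgrid(field.xs, field.ys, indexing="ij")
        i, j = np.unravel_index(np.argmax(field.values), field.values.shape)
        dist_from_south_wall = gy[i, j] + 75.0
        assert abs(dist_from_south_wall - south_bvc.d_pref) <= 2 * south_bvc.sigma0

    def test_outside_position_rejected(self, south_bvc, walled_circle):
        with pytest.raises(OutsideFloorError):
            bvc_rate(south_bvc, walled_circle, (100.0, 0.0))


class TestHDRate:
    def test_peak_at_preferred_heading(self):
        p = HDParams(mu=1.0, kappa=8.0, a_max=30.0)
        assert hd_rate(p, 1.0) == pytest.approx(30.0)

    def test_antipreferred_near_zero_at_high_concentration(self):
        p = HDParams(mu=0.0, kappa=20.0, a_max=30.0)
        assert hd_rate(p, math.pi) < 1e-10

    def test_integral_matches_closed_form(self):
        # int_0^{2pi} a*exp(kappa*(cos(x-mu)-1)) dx = 2*pi*a*exp(-kappa)*I0(kappa)
        p = HDParams(mu=0.7, kappa=4.0, a_max=12.0)
        xs = np.linspace(0, 2 * math.pi, 20001)
        numeric = np.trapezoid(hd_rate(p, xs), xs)
        closed = 2 * math.pi * p.a_max * math.exp(-p.kappa) * i0(p.kappa)
        assert numeric == pytest.approx(closed, rel=1e-6)


class TestBoundaryOffRate:
    def test_no_suppression_gives_uniform_baseline(self, south_bvc, walled_circle):
        p = BoundaryOffParams(baseline=7.0, suppression=0.0, bvc=south_bvc)
        for pos in [(0, 0), (0, -60), (40, 20)]:
            assert boundary_off_rate(p, walled_circle, pos) == pytest.approx(7.0)

    def test_full_suppression_silences_bvc_peak(self, south_bvc, walled_circle):
        p = BoundaryOffParams(baseline=7.0, suppression=1.0, bvc=south_bvc)
        field = bvc_rate_field(south_bvc, walled_circle)
        i, j = np.unravel_index(np.argmax(field.values), field.values.shape)
        pos = (field.xs[i], field.ys[j])
        assert boundary_off_rate(p, walled_circle, pos) < 0.05 * p.baseline

    def test_barrier_elicits_low_zone_on_predicted_side(self, south_bvc, walled_circle):
        # south-tuned suppressing BVC: after an east-west barrier, a low-rate
        # zone (<40% baseline) appears just north of the barrier
        p = BoundaryOffParams(baseline=7.0, suppression=1.0, bvc=south_bvc)
        env_b = insert_barrier(walled_circle, (0, 0), 0.0)
        before = boundary_off_rate(p, walled_circle, (0.0, 1.5 + south_bvc.d_pref))
        after = boundary_off_rate(p, env_b, (0.0, 1.5 + south_bvc.d_pref))
        assert before > 0.9 * p.baseline
        assert after < 0.4 * p.baseline


class TestSimulateTrajectory:
    def test_sample_count_and_rate(self, walled_circle):
        traj = simulate_trajectory(walled_circle, duration=120.0, seed=0)
        assert len(traj) == 6000  # 50 Hz x 120 s
        assert np.allclose(np.diff(traj.t), 0.02)

    def test_deterministic_given_seed(self, walled_circle):
        a = simulate_trajectory(walled_circle, duration=30.0, seed=3)
        b = simulate_trajectory(walled_circle, duration=30.0, seed=3)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.hd, b.hd)

    def test_confined_to_eroded_floor(self, walled_circle):
        traj = simulate_trajectory(walled_circle, duration=60.0, seed=1, wall_clearance=5.0)
        assert np.hypot(traj.x, traj.y).max() <= 70.0 + 1e-9

    def test_speed_below_tracking_cap(self, walled_circle):
        traj = simulate_trajectory(walled_circle, duration=60.0, seed=2)
        assert traj.speed().max() <= 200.0

    def test_infeasible_clearance_rejected(self, walled_square):
        with pytest.raises(ValueError):
            simulate_trajectory(walled_square, duration=10.0, seed=0, wall_clearance=60.0)


class TestGenerateSpikes:
    def test_constant_rate_poisson_count(self, walled_circle):
        traj = simulate_trajectory(walled_circle, duration=1000.0, seed=4)
        spikes = generate_spikes(lambda tr: np.full(len(tr), 5.0), traj, seed=0)
        assert abs(len(spikes) - 5000) < 3 * math.sqrt(5000)

    def test_zero_rate_gives_empty_train(self, walled_circle):
        traj = simulate_trajectory(walled_circle, duration=10.0, seed=4)
        assert len(generate_spikes(lambda tr: np.zeros(len(tr)), traj, seed=0)) == 0

    def test_negative_rate_rejected(self, walled_circle):
        traj = simulate_trajectory(walled_circle, duration=5.0, seed=4)
        with pytest.raises(ValueError):
            generate_spikes(lambda tr: np.full(len(tr), -1.0), traj, seed=0)

    def test_deterministic_given_seed(self, walled_circle):
        traj = simulate_trajectory(walled_circle, duration=20.0, seed=4)
        a = generate_spikes(lambda tr: np.full(len(tr), 8.0), traj, seed=5)
        b = generate_spikes(lambda tr: np.full(len(tr), 8.0), traj, seed=5)
        assert np.array_equal(a.times, b.times)

    def test_expected_count_equals_rate_integral(self, walled_circle):
        # inhomogeneous rate: mean count over seeds matches the time-integral
        traj = simulate_trajectory(walled_circle, duration=200.0, seed=4)
        rate_fn = lambda tr: 5.0 + 4.0 * np.sin(2 * math.pi * tr.t / 50.0)
        target = np.sum(rate_fn(traj)) * traj.dt
        counts = [len(generate_spikes(rate_fn, traj, seed=s)) for s in range(30)]
        sem = math.sqrt(target / 30)
        assert abs(np.mean(counts) - target) < 4 * sem

    def test_invalid_theta_depth_rejected(self, walled_circle):
        traj = simulate_trajectory(walled_circle, duration=5.0, seed=4)
        with pytest.raises(ValueError):
            generate_spikes(lambda tr: np.ones(len(tr)), traj, seed=0, theta={"f0": 8, "depth": 1.5})
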