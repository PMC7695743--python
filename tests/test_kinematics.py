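import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pursuitkin.kinematics import (
    AngleSeries,
    RateSeries,
    compute_angles,
    compute_rates,
    compute_x_prime,
    extract_saccades,
    smooth_track,
    wrap_azimuth,
)
from pursuitkin.track import PursuitTrack

FRAME = 1.0 / 190.0


def track_from_positions(pur, tar=None, rate=190.0):
    pur = np.asarray(pur, dtype=float)
    n = len(pur)
    if tar is None:
        tar = np.tile([1.0, 0.0, 0.0], (n, 1))
    else:
        tar = np.asarray(tar, dtype=float)
        if tar.ndim == 1:
            tar = np.tile(tar, (n, 1))
    return PursuitTrack(np.arange(n) / rate, pur, tar, frame_rate=rate)


class TestWrap:
    @given(st.floats(-1e4, 1e4))
    def test_wrap_range(self, a):
        w = wrap_azimuth(a)
        assert -180.0 < w <= 180.0

    @given(st.floats(-1e4, 1e4))
    def test_wrap_is_mod_360(self, a):
        w = wrap_azimuth(a)
        assert abs((a - w) % 360.0) < 1e-6 or abs((a - w) % 360.0 - 360.0) < 1e-6


class TestComputeAngles:
    def test_collinear_geometry(self):
        pur = [[0, 0, 0], [0.1, 0, 0], [0.2, 0, 0]]
        a = compute_angles(track_from_positions(pur, [1.0, 0.0, 0.0]))
        assert np.allclose(a.theta_ph, 0.0)
        assert np.allclose(a.theta_ah[:2], 0.0)
        assert np.allclose(a.theta_eh, 0.0, atol=1e-12)
        assert np.allclose(a.theta_av[:2], 0.0)

    def test_zenith_target(self):
        pur = [[0, 0, 0], [0.1, 0, 0], [0.2, 0, 0]]
        a = compute_angles(track_from_positions(pur, [0.0, 0.0, 1.0]))
        assert a.theta_av[0] == pytest.approx(90.0)

    def test_oblique_bearings_hand_trigonometry(self):
        pur = [[-0.1, 0, 0], [0, 0, 0], [0.1, 0, 0]]
        a = compute_angles(track_from_positions(pur, [1.0, 1.0, 0.0]))
        # at the origin frame: heading +x, target at 45 deg azimuth
        assert a.theta_ah[1] == pytest.approx(45.0, abs=1e-9)
        assert a.theta_eh[1] == pytest.approx(45.0, abs=1e-9)
        b = compute_angles(track_from_positions(pur, [1.0, 0.0, 1.0]))
        assert b.theta_av[1] == pytest.approx(45.0, abs=1e-9)

    def test_error_angle_identity_everywhere(self):
        rng = np.random.default_rng(0)
        pur = np.cumsum(rng.normal(0, 0.01, (50, 3)), axis=0)
        tar = pur + rng.uniform(0.1, 0.5, (50, 3))
        a = compute_angles(track_from_positions(pur, tar))
        assert np.allclose(a.theta_eh, wrap_azimuth(a.theta_ah - a.theta_ph))
        assert np.allclose(a.theta_ev, a.theta_av - a.theta_pv)

    def test_azimuth_and_elevation_ranges(self):
        rng = np.random.default_rng(1)
        pur = np.cumsum(rng.normal(0, 0.01, (100, 3)), axis=0)
        tar = pur + rng.normal(0, 0.3, (100, 3))
        a = compute_angles(track_from_positions(pur, tar))
        for az in (a.theta_ph, a.theta_ah, a.theta_eh):
            assert (az > -180.0).all() and (az <= 180.0).all()
        for el in (a.theta_pv, a.theta_av):
            assert (np.abs(el) <= 90.0).all()

    def test_rigid_rotation_moves_headings_not_error(self):
        rng = np.random.default_rng(2)
        pur = np.cumsum(rng.normal(0, 0.01, (40, 3)), axis=0)
        tar = pur + rng.uniform(0.1, 0.4, (40, 3))
        a0 = compute_angles(track_from_positions(pur, tar))
        phi = 73.0
        c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        a1 = compute_angles(track_from_positions(pur @ R.T, tar @ R.T))
        assert np.allclose(a1.theta_eh, a0.theta_eh, atol=1e-8)
        assert np.allclose(a1.theta_ev, a0.theta_ev, atol=1e-8)
        assert np.allclose(wrap_azimuth(a1.theta_ph - a0.theta_ph - phi), 0.0, atol=1e-8)

    def test_stationary_frames_hold_heading_and_flag(self):
        pur = [[0, 0, 0], [0.1, 0, 0], [0.1, 0, 0], [0.1, 0.1, 0]]
        a = compute_angles(track_from_positions(pur))
        assert a.theta_ph[2] == pytest.approx(0.0)  # held from previous step
        assert a.heading_held[2]
        assert a.theta_ph[3] == pytest.approx(90.0)

    def test_never_moving_pursuer_errors(self):
        pur = np.zeros((5, 3))
        with pytest.raises(ValueError):
            compute_angles(track_from_positions(pur))

    def test_angular_size(self):
        pur = [[0, 0, 0], [0.1, 0, 0], [0.2, 0, 0]]
        a = compute_angles(track_from_positions(pur, [1.0, 0.0, 0.0]), target_diameter=0.008)
        assert a.rho[0] == pytest.approx(2 * np.degrees(np.arctan(0.004 / 1.0)), rel=1e-6)
        assert ((a.rho > 0) & (a.rho < 180)).all()

    def test_mirror_flips_horizontal_angles(self):
        rng = np.random.default_rng(3)
        pur = np.cumsum(rng.normal(0, 0.01, (30, 3)), axis=0)
        tar = pur + rng.uniform(0.1, 0.4, (30, 3))
        a0 = compute_angles(track_from_positions(pur, tar))
        a1 = compute_angles(track_from_positions(pur, tar), mirror=True)
        assert np.allclose(wrap_azimuth(a1.theta_eh + a0.theta_eh), 0.0, atol=1e-8)
        assert np.allclose(a1.theta_ev, a0.theta_ev, atol=1e-8)


class TestXPrime:
    def test_straight_horizontal_steps(self):
        pur = [[0.1 * k, 0, 0] for k in range(5)]
        xp = compute_x_prime(track_from_positions(pur))
        assert np.allclose(xp, [0.0, 0.1, 0.2, 0.3, 0.4])

    def test_pure_vertical_motion_gives_zero(self):
        pur = [[0, 0, 0.1 * k] for k in range(5)]
        xp = compute_x_prime(track_from_positions(pur))
        assert np.allclose(xp, 0.0)

    def test_quarter_circle_arc_length(self):
        th = np.linspace(0, np.pi / 2, 1000)
        pur = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])
        xp = compute_x_prime(track_from_positions(pur, rate=1000.0))
        assert xp[-1] == pytest.approx(np.pi / 2, abs=1e-4)

    def test_non_decreasing(self):
        rng = np.random.default_rng(4)
        pur = np.cumsum(rng.normal(0, 0.01, (100, 3)), axis=0)
        xp = compute_x_prime(track_from_positions(pur))
        assert (np.diff(xp) >= 0).all()


def angle_series_from(theta, rate=190.0):
    theta = np.asarray(theta, dtype=float)
    n = theta.size
    z = np.zeros(n)
    return AngleSeries(
        time=np.arange(n) / rate,
        theta_ph=theta, theta_pv=z, theta_ah=theta, theta_av=z,
        theta_eh=z, theta_ev=z, r_a=np.ones(n), r_p=np.ones(n),
        x_prime=z, rho=np.ones(n), frame_rate=rate,
    )


class TestComputeRates:
    def test_linear_ramp(self):
        t = np.arange(200) * FRAME
        r = compute_rates(angle_series_from(10.0 * t), window=0)
        assert np.abs(r.omega_ph - 10.0).max() < 1e-6

    def test_constant_angle_zero_rate(self):
        r = compute_rates(angle_series_from(np.full(100, 33.0)))
        assert np.abs(r.omega_ph).max() < 1e-9

    def test_sine_matches_analytic_derivative(self):
        t = np.arange(400) * FRAME
        theta = 30.0 * np.sin(2 * np.pi * t)
        r = compute_rates(angle_series_from(theta), window=5)
        expect = 30.0 * 2 * np.pi * np.cos(2 * np.pi * t)
        interior = slice(5, -5)
        rel = np.abs(r.omega_ph[interior] - expect[interior]).max() / np.abs(expect).max()
        assert rel < 0.01

    def test_unwraps_through_180(self):
        # steady rotation crossing +/-180 must not spike
        t = np.arange(300) * FRAME
        theta = wrap_azimuth(170.0 + 100.0 * t)
        r = compute_rates(angle_series_from(theta), window=0)
        assert np.abs(r.omega_ph - 100.0).max() < 1e-6

    def test_linearity_identity(self):
        rng = np.random.default_rng(5)
        t = np.arange(300) * FRAME
        a = angle_series_from(np.cumsum(rng.normal(0, 0.2, t.size)))
        r = compute_rates(a, window=5)
        assert np.allclose(r.omega_eh, r.omega_ah - r.omega_ph, atol=1e-9)

    def test_short_series_errors(self):
        with pytest.raises(ValueError):
            compute_rates(angle_series_from(np.zeros(3)), window=5)

    def test_nonuniform_time_errors(self):
        a = angle_series_from(np.zeros(10))
        bad = AngleSeries(**{**a.__dict__, "time": a.time**1.1 + a.time})
        with pytest.raises(ValueError):
            compute_rates(bad)

    def test_integration_roundtrip(self):
        # differentiate then cumulatively integrate: recover up to a constant
        t = np.arange(400) * FRAME
        theta = 20 * np.sin(2 * np.pi * 0.7 * t) + 5 * t
        r = compute_rates(angle_series_from(theta), window=0)
        rebuilt = theta[0] + np.concatenate(
            [[0.0], np.cumsum((r.omega_ph[1:] + r.omega_ph[:-1]) / 2 * FRAME)]
        )
        assert np.abs(rebuilt - theta)[:-2].max() < 0.05


class TestSaccades:
    def make_rates(self, omega):
        omega = np.asarray(omega, dtype=float)
        n = omega.size
        z = np.zeros(n)
        return RateSeries(np.arange(n) * FRAME, omega, z, z, z, z, z, frame_rate=190.0)

    def test_three_inserted_events(self):
        omega = np.zeros(600)
        for start in (100, 300, 500):
            omega[start : start + 8] = 3000.0
        ev = extract_saccades(self.make_rates(omega), np.ones(600))
        assert len(ev) == 3
        assert all(e.peak_rate == 3000.0 for e in ev)

    def test_quiet_trace_no_events(self):
        ev = extract_saccades(self.make_rates(np.zeros(200)), np.ones(200))
        assert ev == []

    def test_subthreshold_ignored(self):
        omega = np.full(200, 1000.0)
        assert extract_saccades(self.make_rates(omega), np.ones(200)) == []

    def test_speed_dip_lead_recovered(self):
        # dip inserted 10 ms (2 frames) before the rate peak
        n = 400
        omega = np.zeros(n)
        omega[200:207] = [2000, 2500, 3000, 3500, 3000, 2500, 2000]
        speed = np.ones(n)
        peak_idx = 203
        dip_idx = peak_idx - 2
        speed[dip_idx - 1 : dip_idx + 2] = [0.8, 0.5, 0.8]
        ev = extract_saccades(self.make_rates(omega), speed)
        assert len(ev) == 1
        assert ev[0].lead == pytest.approx(2 * FRAME, abs=FRAME + 1e-9)
        assert ev[0].speed_min == 0.5

    def test_negative_rate_events_detected(self):
        omega = np.zeros(300)
        omega[100:110] = -4000.0
        ev = extract_saccades(self.make_rates(omega), np.ones(300))
        assert len(ev) == 1 and ev[0].peak_rate == -4000.0


class TestSmoothTrack:
    def test_preserves_linear_motion(self, straight_track):
        sm = smooth_track(straight_track, window=5, polyorder=2)
        assert np.abs(sm.pursuer_xyz - straight_track.pursuer_xyz).max() < 1e-12

    def test_window_too_long_errors(self, straight_track):
        with pytest.raises(ValueError):
            smooth_track(straight_track, window=11)

    def test_reduces_noise(self, rng):
        n = 200
        t = np.arange(n) * FRAME
        clean = np.column_stack([t, np.zeros(n), np.zeros(n)])
        noisy = clean + rng.normal(0, 0.005, (n, 3))
        track = PursuitTrack(t, noisy, clean + 1.0, frame_rate=190.0)
        sm = smooth_track(track, 21, 2)
        assert np.std(sm.pursuer_xyz - clean) < 0.5 * np.std(noisy - clean)
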