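"""Angle estimation: relative angular velocity, dominant-axis energy and
realignment, the continuous and resetting algorithms, drift and selection."""

import warnings

import numpy as np
import pytest

import fingertap as ft
from fingertap.angles import (
    DRIFT_SWITCH_RAD,
    axis_energy,
    dominant_axis,
    estimate_drift,
    realign_index_frame,
    realignment_rotation,
    relative_angular_velocity,
    run_alc,
    run_alr,
    select_algorithm,
)
from fingertap.kinematics import axis_rotation, quaternion_integrate, raw_angle
from fingertap.session import AngleTrace, GyroSession
from fingertap.simulate import PatternSpec, SensorSpec, generate_session, quiet_sensor

from conftest import random_rotations


class TestRelativeAngularVelocity:
    def test_aligned_equal_motion_cancels(self):
        w = np.array([1.0, 2.0, 3.0])
        assert np.allclose(relative_angular_velocity(np.eye(3), w, w), 0.0)

    def test_quarter_z_turn_permutes_components(self):
        R = axis_rotation("z", np.pi / 2)
        out = relative_angular_velocity(R, np.array([1.0, 0.0, 0.0]), np.zeros(3))
        assert np.allclose(out, [0.0, 1.0, 0.0], atol=1e-15)

    def test_matches_brute_force_product(self, rng):
        for R in random_rotations(10, seed=6):
            w1 = rng.normal(size=3)
            w2 = rng.normal(size=3)
            expected = np.array(
                [sum(R[i, j] * w1[j] for j in range(3)) - w2[i] for i in range(3)]
            )
            assert np.allclose(relative_angular_velocity(R, w1, w2), expected)

    def test_vectorized_over_series(self, rng):
        R = random_rotations(1, seed=7)[0]
        w1 = rng.normal(size=(20, 3))
        w2 = rng.normal(size=(20, 3))
        out = relative_angular_velocity(R, w1, w2)
        for i in range(20):
            assert np.allclose(out[i], R @ w1[i] - w2[i])


class TestAxisEnergy:
    def test_pure_y_rotation(self):
        w = np.zeros((100, 3))
        w[:, 1] = 2.0
        e = axis_energy(w, 0.005)
        assert e[0] == 0.0 and e[2] == 0.0 and e[1] > 0.0

    def test_constructed_energy_ratios(self):
        # components built with energy ratio 0.21 : 1 : 0.11
        n, dt = 4000, 0.005
        t = np.arange(n) * dt
        w = np.stack(
            [
                np.sqrt(0.21) * np.sin(2 * np.pi * 2.0 * t),
                1.0 * np.sin(2 * np.pi * 2.0 * t + 1.0),
                np.sqrt(0.11) * np.sin(2 * np.pi * 2.0 * t + 2.0),
            ],
            axis=1,
        )
        e = axis_energy(w, dt)
        assert e[0] / e[1] == pytest.approx(0.21, rel=0.01)
        assert e[2] / e[1] == pytest.approx(0.11, rel=0.01)

    def test_sinusoid_closed_form(self):
        A, T, dt = 3.0, 10.0, 0.005
        t = np.arange(0, T, dt)
        w = np.zeros((t.shape[0], 3))
        w[:, 1] = A * np.sin(2 * np.pi * 1.0 * t)
        assert axis_energy(w, dt)[1] == pytest.approx(A * A * T / 2, rel=0.01)


class TestRealignment:
    @staticmethod
    def _first_pass(synth):
        session = synth.session
        w = ft.detect_calibration_window(session)
        cal = ft.estimate_initial_rotation(session, w)
        res = run_alc(session, cal.R0, start=w.end)
        off = (synth.tapping_start) - w.end
        return session, cal, res.w_rel[max(off, 0) :]

    def test_y_dominant_pattern_untouched(self, noisy_pattern1):
        session, cal, w_rel = self._first_pass(noisy_pattern1)
        _, Q, _ = realign_index_frame(session, cal.R0, w_rel, session.dt)
        assert np.allclose(Q, np.eye(3))

    def test_pure_z_mount_realigned_to_y(self):
        synth = generate_session(
            PatternSpec.preset(1, index_mount=(np.pi / 2, 0.0, 0.0)), seed=2
        )
        session, cal, w_rel = self._first_pass(synth)
        sess2, Q, R02 = realign_index_frame(session, cal.R0, w_rel, session.dt)
        assert not np.allclose(Q, np.eye(3))
        res2 = run_alc(sess2, R02, start=cal.window.end)
        e = axis_energy(res2.w_rel, session.dt)
        assert e[1] == max(e)

    def test_oblique_axis_realigned(self):
        synth = generate_session(
            PatternSpec.preset(1, index_mount=(np.pi / 4, 0.0, 0.0)), seed=2
        )
        session, cal, w_rel = self._first_pass(synth)
        sess2, Q, R02 = realign_index_frame(session, cal.R0, w_rel, session.dt)
        res2 = run_alc(sess2, R02, start=cal.window.end)
        e = axis_energy(res2.w_rel, session.dt)
        assert e[1] / e.sum() > 0.9

    def test_idempotent(self):
        synth = generate_session(
            PatternSpec.preset(1, index_mount=(np.pi / 2, 0.0, 0.0)), seed=2
        )
        session, cal, _ = self._first_pass(synth)
        res = run_alc(session, cal.R0, start=cal.window.end)
        sess2, Q1, R01 = realign_index_frame(session, cal.R0, res.w_rel, session.dt)
        res2 = run_alc(sess2, R01, start=cal.window.end)
        _, Q2, _ = realign_index_frame(sess2, R01, res2.w_rel, sess2.dt)
        assert np.allclose(Q2, np.eye(3))

    def test_minimal_rotation_maps_axis_to_y(self):
        for v in ([0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 1.0], [0.3, -0.5, 0.8]):
            Q = realignment_rotation(np.asarray(v) / np.linalg.norm(v))
            assert np.allclose(Q @ (np.asarray(v) / np.linalg.norm(v)), [0, 1, 0], atol=1e-12)
            assert np.allclose(Q.T @ Q, np.eye(3), atol=1e-12)

    def test_dominant_axis_reduces_to_energy_comparison(self):
        w = np.zeros((500, 3))
        w[:, 2] = np.sin(np.linspace(0, 20, 500))
        axis, _ = dominant_axis(w, 0.005)
        assert np.allclose(np.abs(axis), [0, 0, 1], atol=1e-12)


class TestContinuousAlgorithm:
    def test_zero_relative_motion_constant_angle(self):
        n = 400
        w = np.zeros((n, 3))
        w[:, 0] = 1.5  # both sensors see the same motion
        session = GyroSession(t=np.arange(n) * 0.005, w_thumb=w, w_index=w)
        res = run_alc(session, np.eye(3))
        assert np.allclose(res.trace.alpha, res.trace.alpha[0], atol=1e-12)

    def test_tracks_truth_with_moving_hand(self):
        # noise-free, pure y-axis relative rotation while the whole hand rolls
        synth = generate_session(PatternSpec.preset(5), quiet_sensor(), seed=1)
        session = synth.session
        w = ft.detect_calibration_window(session)
        cal = ft.estimate_initial_rotation(session, w)
        res = run_alc(session, cal.R0, start=synth.tapping_start)
        theta = res.trace.theta - res.trace.theta[0]
        truth = synth.theta_true[synth.tapping_start :]
        # second-order coupling between hand rates and tap rates in the
        # Euler-factored 5 ms update leaves a sub-degree residual
        assert np.degrees(np.abs(theta - truth)).max() < 1.0

    def test_matches_quaternion_oracle_on_scissor_streams(self):
        rng = np.random.default_rng(8)
        dt, n = 0.005, 3000
        t = np.arange(n) * dt
        w = np.zeros((n, 3))
        w[:, 1] = 4.5 * np.sin(2 * np.pi * 2.0 * t)
        for ax in (0, 2):
            w[:, ax] = 0.2 * np.sin(2 * np.pi * rng.uniform(0.5, 3.0) * t + rng.uniform(0, 6))
        session = GyroSession(t=t, w_thumb=np.zeros((n, 3)), w_index=-w)
        res = run_alc(session, np.eye(3))
        Rq = quaternion_integrate(w, dt)
        alpha_q = np.unwrap(np.arctan2(Rq[:, 2, 0], Rq[:, 0, 0]))
        assert np.degrees(np.abs(np.unwrap(res.trace.alpha) - alpha_q)).max() < 0.1

    def test_orthonormality_preserved_over_full_sequence(self, noisy_pattern1):
        session = noisy_pattern1.session
        res = run_alc(session, np.eye(3))
        assert np.linalg.norm(res.R_final.T @ res.R_final - np.eye(3)) < 1e-9


class TestResettingAlgorithm:
    def test_zero_motion_zero_trace(self):
        n = 200
        session = GyroSession(
            t=np.arange(n) * 0.005, w_thumb=np.zeros((n, 3)), w_index=np.zeros((n, 3))
        )
        trace = run_alr(session, np.eye(3))
        assert np.allclose(trace.theta, 0.0)

    def test_agrees_with_continuous_on_clean_tapping(self, clean_pattern1):
        synth = clean_pattern1
        session = synth.session
        w = ft.detect_calibration_window(session)
        cal = ft.estimate_initial_rotation(session, w)
        alc = run_alc(session, cal.R0, start=synth.tapping_start)
        alr = run_alr(session, cal.R0, start=synth.tapping_start)
        d = (alc.trace.theta - alc.trace.theta[0]) - alr.theta
        assert np.degrees(np.abs(d)).max() < 0.5

    def test_beats_continuous_under_bias_induced_drift(self):
        # constant gyro bias tumbles the full matrix; the frozen-row
        # projection only accumulates a linear ramp that baseline removal fixes
        spec = PatternSpec.preset(2, thumb_mount=(0.0, 0.0, 0.0))
        sensor = SensorSpec(initial_bias_dps=np.array([[4.0, 4.0, 4.0], [0.0, 0.0, 0.0]]))
        synth = generate_session(spec, sensor, seed=4)
        rep = ft.run_pipeline(
            synth.session,
            truth_theta=synth.theta_true,
            truth_boundaries=synth.tap_boundaries,
        )
        assert rep.alr.agreement.rmse_deg < rep.alc.agreement.rmse_deg


class TestDriftAndSelection:
    def test_clean_session_drift_small(self, clean_pattern1):
        synth = clean_pattern1
        session = synth.session
        w = ft.detect_calibration_window(session)
        cal = ft.estimate_initial_rotation(session, w)
        res = run_alc(session, cal.R0, start=w.end)
        drift = estimate_drift(res.trace, synth.tapping_start - w.end)
        assert np.degrees(drift) < 2.0

    def test_constant_bias_accumulates_linearly(self):
        # bias b on the thumb y-channel with aligned frames: drift ~ b * T
        spec = PatternSpec.preset(1, thumb_mount=(0.0, 0.0, 0.0))
        b_dps, T = 3.0, 15.0
        sensor = SensorSpec(
            initial_bias_dps=np.array([[0.0, b_dps, 0.0], [0.0, 0.0, 0.0]]),
            white_noise_sigma_dps=0.0,
            bias_walk_dps_sqrt_s=0.0,
            resolution_bits=32,
        )
        synth = generate_session(spec, sensor, seed=0)
        session = synth.session
        w = ft.detect_calibration_window(session)
        cal = ft.estimate_initial_rotation(session, w)
        res = run_alc(session, cal.R0, start=synth.tapping_start)
        drift = np.degrees(estimate_drift(res.trace, 0))
        assert drift == pytest.approx(b_dps * T, rel=0.15)

    def test_shift_invariance(self):
        t = np.arange(100) * 0.005
        alpha = np.sin(t)
        tr1 = AngleTrace(t, alpha, -alpha, "AL-C")
        tr2 = AngleTrace(t, alpha + 0.7, -(alpha + 0.7), "AL-C")
        assert estimate_drift(tr1, 0) == pytest.approx(estimate_drift(tr2, 0))

    @pytest.mark.parametrize(
        "drift_deg,expected",
        [(70.0, "AL-R"), (10.0, "AL-C"), (60.0, "AL-C")],
    )
    def test_drift_rule(self, drift_deg, expected):
        assert select_algorithm(np.radians(drift_deg)) == expected
        assert DRIFT_SWITCH_RAD == pytest.approx(np.radians(60.0))
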