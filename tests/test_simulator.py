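"""Simulator: ground-truth construction, orientation synthesis, inverse gyro
kinematics, sensor corruption model, and whole-session assembly."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fingertap.kinematics import axis_rotation, raw_angle, rotation_distance
from fingertap.mocap import relative_rotation
from fingertap.simulate import (
    PatternSpec,
    SensorSpec,
    apply_sensor_model,
    generate_session,
    generate_truth,
    orientations_to_gyro,
    quiet_sensor,
    truth_to_orientations,
)


class TestGenerateTruth:
    def test_tap_count_is_rate_times_duration(self):
        _, theta, taps, _ = generate_truth(PatternSpec.preset(1), seed=0)
        assert len(taps) == 30
        assert theta.min() >= 0.0

    def test_skip_reduces_count_and_prolongs_taps(self):
        spec = PatternSpec.preset(9)
        _, _, taps, _ = generate_truth(spec, seed=1)
        held = sum(
            round((tap["end"] - tap["start"]) / 200 * spec.tap_rate) - 1
            for tap in taps
            if tap["style"] != "normal"
        )
        assert len(taps) == 30 - held
        assert held >= spec.n_skips  # every skip holds at least one period

    def test_zero_at_closures(self):
        _, theta, taps, _ = generate_truth(PatternSpec.preset(1), seed=2)
        for tap in taps:
            assert theta[tap["start"]] < 1e-9

    def test_tremor_spectral_line(self):
        spec = PatternSpec.preset(6)
        t, theta, _, _ = generate_truth(spec, seed=3)
        base = generate_truth(PatternSpec.preset(1), seed=3)[1]
        tremor = theta - base
        n = t.shape[0]
        spectrum = np.abs(np.fft.rfft(tremor)) * 2 / n
        freqs = np.fft.rfftfreq(n, t[1] - t[0])
        k = np.argmin(np.abs(freqs - spec.tremor_freq))
        # amplitude-modulated by the normalized tap envelope (mean 1/2)
        envelope_mean = np.mean(np.clip(base / spec.aperture_amp, 0, 1))
        assert spectrum[k] == pytest.approx(spec.tremor_amp * envelope_mean, rel=0.10)


class TestTruthToOrientations:
    def test_rest_pose_is_identity(self):
        R1, R2 = truth_to_orientations(np.zeros(10), PatternSpec.preset(1))
        assert np.allclose(R1, np.eye(3)) and np.allclose(R2, np.eye(3))

    def test_relative_raw_angle_reproduces_truth_under_any_hand_motion(self):
        rng = np.random.default_rng(20)
        spec = PatternSpec.preset(1, contact_offset=np.radians(12.0))
        theta = np.radians(40.0) * 0.5 * (1 - np.cos(np.linspace(0, 6 * np.pi, 400)))
        hand = np.cumsum(rng.normal(0, 0.01, (400, 3)), axis=0)
        M1 = Rotation.random(rng=np.random.default_rng(5)).as_matrix()
        R1, R2 = truth_to_orientations(
            theta, spec, hand_angles=hand, thumb_mount=M1
        )
        rel = relative_rotation(R1, R2)
        alpha = np.unwrap(np.arctan2(rel[:, 2, 0], rel[:, 0, 0]))
        recon = -(alpha - alpha[0])  # theta - theta[0] up to the fixed offset
        assert np.abs(recon - (theta - theta[0])).max() < 1e-9

    def test_whole_hand_motion_leaves_relative_rotation_constant(self):
        hand = np.stack(
            [np.linspace(0, 1.0, 300), np.zeros(300), np.sin(np.linspace(0, 3, 300))],
            axis=1,
        )
        R1, R2 = truth_to_orientations(np.zeros(300), PatternSpec.preset(1), hand_angles=hand)
        rel = relative_rotation(R1, R2)
        assert np.abs(rel - rel[0]).max() < 1e-12


class TestOrientationsToGyro:
    def test_constant_rate(self):
        dt, w = 0.005, 1.7
        R = np.stack([axis_rotation("y", w * i * dt) for i in range(200)])
        out = orientations_to_gyro(R, dt)
        assert np.allclose(out, [0.0, w, 0.0], atol=1e-10)

    def test_sinusoidal_angle_matches_analytic_rate(self):
        dt = 0.005
        t = np.arange(1000) * dt
        a = 0.6 * np.sin(2 * np.pi * 1.5 * t)
        adot = 0.6 * 2 * np.pi * 1.5 * np.cos(2 * np.pi * 1.5 * t)
        R = np.stack([axis_rotation("x", ai) for ai in a])
        out = orientations_to_gyro(R, dt)
        mid = slice(1, -1)
        assert np.abs(out[mid, 0] - adot[mid]).max() < 1e-3 * np.abs(adot).max()

    def test_static_pose_zero(self):
        R = np.tile(axis_rotation("z", 0.4), (50, 1, 1))
        assert np.allclose(orientations_to_gyro(R, 0.005), 0.0)


class TestSensorModel:
    def test_quantization_only(self):
        spec = SensorSpec(white_noise_sigma_dps=0.0, bias_walk_dps_sqrt_s=0.0)
        w = np.radians(np.linspace(-100, 100, 501))[:, None] * np.ones(3)
        out = np.degrees(apply_sensor_model(w, spec, 0))
        step = 2 * 2000 / 2**12
        assert step == pytest.approx(4000 / 4096)
        assert np.abs(out - np.degrees(w)).max() <= step / 2 + 1e-12
        assert np.allclose(np.round(out / step), out / step)

    def test_saturation_clips_exactly(self):
        spec = SensorSpec(white_noise_sigma_dps=0.0, bias_walk_dps_sqrt_s=0.0)
        w = np.radians(np.array([[2500.0, -2500.0, 0.0]]))
        out = np.degrees(apply_sensor_model(w, spec, 0))
        assert out[0, 0] == pytest.approx(2000.0, abs=1e-9)
        assert out[0, 1] == pytest.approx(-2000.0, abs=1e-9)

    def test_same_seed_identical_streams(self):
        w = np.zeros((500, 3))
        a = apply_sensor_model(w, SensorSpec(), np.random.default_rng(5))
        b = apply_sensor_model(w, SensorSpec(), np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestGenerateSession:
    def test_default_session_layout(self):
        synth = generate_session(PatternSpec.preset(1), seed=0)
        # 0.5 still + 2.0 calibration + 0.5 settle + 15.0 tapping at 200 Hz
        assert len(synth.session) == 3600
        assert synth.tapping_start == 600
        assert synth.calibration_span == (100, 500)

    def test_deterministic_for_same_seed(self):
        a = generate_session(PatternSpec.preset(6), seed=9)
        b = generate_session(PatternSpec.preset(6), seed=9)
        assert np.array_equal(a.session.w_thumb, b.session.w_thumb)
        assert np.array_equal(a.session.markers_index, b.session.markers_index)
        c = generate_session(PatternSpec.preset(6), seed=10)
        assert not np.array_equal(a.session.w_thumb, c.session.w_thumb)

    def test_truth_consistency_before_corruption(self, clean_pattern1):
        synth = clean_pattern1
        rel = relative_rotation(synth.R_thumb, synth.R_index)
        alpha = np.unwrap(np.arctan2(rel[:, 2, 0], rel[:, 0, 0]))
        recon = -(alpha - alpha[0])
        assert np.abs(recon - synth.theta_true).max() < 1e-9

    def test_calibration_truth_matches_relative_rotation_at_rest(self, clean_pattern1):
        synth = clean_pattern1
        rel0 = relative_rotation(synth.R_thumb[0], synth.R_index[0])
        assert rotation_distance(rel0, synth.R0_true) < 1e-12

    def test_pattern1_energy_fractions_near_observed_regime(self):
        # y must dominate; transverse fractions stay within +/-50% of the
        # observed 21% (x) and 11% (z) regime, i.e. below ~0.3 of y
        from fingertap.angles import axis_energy, relative_angular_velocity

        synth = generate_session(PatternSpec.preset(1), seed=1)
        s = synth.session
        wr = relative_angular_velocity(
            synth.R0_true, s.w_thumb[synth.tapping_start :], s.w_index[synth.tapping_start :]
        )
        e = axis_energy(wr, s.dt)
        assert e[1] == max(e)
        assert e[0] / e[1] < 0.32 and e[2] / e[1] < 0.32

    def test_full_pipeline_recovers_calibration_on_clean_session(self, clean_pattern1):
        import fingertap as ft

        synth = clean_pattern1
        w = ft.detect_calibration_window(synth.session)
        cal = ft.estimate_initial_rotation(synth.session, w)
        assert rotation_distance(cal.R0, synth.R0_true) < 1e-3

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            PatternSpec.preset(12)
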