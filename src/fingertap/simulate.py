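"""Rigid-body finger-tapping simulator.

Generates ground-truth tapping-angle trajectories for eleven stereotyped
tapping patterns observed clinically (moderate, fast/wide, fast/small,
slow/small, hand rotation while tapping, tremor, thumb-orientation drift,
strong impacts, skipped taps held open or closed, and thumb slip at closure),
turns them into lab-frame rigid-body orientations for the two fingertip
sensors, differentiates those into exact body-frame gyroscope signals, and
corrupts them with a MEMS sensor model (white noise, bias random walk,
quantization, saturation).  Virtual three-marker boards rigidly attached to
each sensor frame provide a motion-capture reference path.

The kinematic model is scissor-like: finger bending is neglected and the
thumb rotates relative to the index finger about the index y-axis by the
tapping angle.  Mounting rotations of both sensors and a whole-hand pose are
composed around that relative rotation, so the simulated session exercises
the same autocalibration and drift problems as a real recording.

A session follows the measurement protocol: fingers closed and still, then
~2 s of whole-hand circle drawing with fingers pressed together (the
autocalibration segment), a short settle pause, then 15 s of tapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.spatial.transform import Rotation as _Rotation

from .kinematics import euler_to_matrix
from .session import GyroSession

__all__ = [
    "PatternSpec",
    "SensorSpec",
    "SyntheticSession",
    "generate_truth",
    "truth_to_orientations",
    "orientations_to_gyro",
    "apply_sensor_model",
    "generate_session",
    "MARKER_GEOMETRY_MM",
]

# T-board marker geometry in the sensor frame (mm): markers 1-2 along local x,
# marker 3 offset along local y.
MARKER_GEOMETRY_MM = np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0], [0.0, 20.0, 0.0]])


@dataclass(frozen=True)
class PatternSpec:
    """Parametrization of one tapping pattern.

    Angles are radians, rates Hz, durations seconds.  ``preset`` builds the
    eleven stock patterns; every amplitude here is an engineering default (the
    clinical patterns are described qualitatively), exposed for adjustment.
    """

    pattern_id: int = 1
    tap_rate: float = 2.0
    aperture_amp: float = np.radians(40.0)
    duration: float = 15.0
    # pattern extras (inactive at 0 / None)
    tremor_amp: float = 0.0
    tremor_freq: float = 5.0
    n_skips: int = 0
    skip_style: str | None = None  # "open" | "closed"
    skip_hold_periods: tuple[int, int] = (1, 2)  # inclusive range of held periods
    impact_rate_peak: float = 0.0  # rad/s at closure; 0 disables
    impact_width: float = 0.03
    slip_amp: float = 0.0  # about-z transient at closure
    slip_width: float = 0.10
    thumb_drift_amp: float = 0.0  # slow thumb-frame drift over the sequence
    hand_motion: str = "static"  # "static" | "slow_rotation"
    hand_roll_amp: float = np.radians(30.0)
    hand_roll_freq: float = 0.2
    # session layout
    still_s: float = 0.5
    calibration_s: float = 2.0
    settle_s: float = 0.5
    circle_amp: float = 0.7  # rad, calibration circle excitation
    circle_freq: float = 1.2  # Hz
    # frames
    thumb_mount: tuple[float, float, float] | None = None  # None: random +/-45 deg
    index_mount: tuple[float, float, float] | None = None  # None: identity
    contact_offset: float = 0.0  # raw angle at finger contact

    @staticmethod
    def preset(pattern_id: int, **overrides: Any) -> "PatternSpec":
        """Stock parametrization of patterns 1-11."""
        base = dict(pattern_id=pattern_id)
        table: dict[int, dict[str, Any]] = {
            1: dict(tap_rate=2.0, aperture_amp=np.radians(40.0)),
            2: dict(tap_rate=3.0, aperture_amp=np.radians(60.0)),
            3: dict(tap_rate=4.0, aperture_amp=np.radians(15.0)),
            4: dict(tap_rate=1.0, aperture_amp=np.radians(10.0)),
            5: dict(hand_motion="slow_rotation"),
            6: dict(tremor_amp=np.radians(3.0), tremor_freq=5.0),
            7: dict(thumb_drift_amp=np.radians(10.0)),
            8: dict(impact_rate_peak=np.radians(2000.0)),
            9: dict(n_skips=2, skip_style="open"),
            10: dict(n_skips=2, skip_style="closed"),
            11: dict(slip_amp=np.radians(20.0)),
        }
        if pattern_id not in table:
            raise ValueError(f"pattern_id must be 1..11, got {pattern_id}")
        base.update(table[pattern_id])
        base.update(overrides)
        return PatternSpec(**base)


@dataclass(frozen=True)
class SensorSpec:
    """MEMS gyroscope model (units deg/s at the sensor interface)."""

    sample_rate: float = 200.0
    resolution_bits: int = 12
    full_scale_dps: float = 2000.0
    white_noise_sigma_dps: float = 0.3
    bias_walk_dps_sqrt_s: float = 0.05
    # scalar: per-axis uniform draw in +/- value (independently per sensor);
    # (3,): exact bias on both sensors; (2, 3): exact per-sensor biases
    initial_bias_dps: Any = 0.0

    @property
    def quantization_step_dps(self) -> float:
        return 2.0 * self.full_scale_dps / 2**self.resolution_bits


@dataclass
class SyntheticSession:
    """A generated session bundled with its ground truth."""

    session: GyroSession
    theta_true: np.ndarray  # rad, full session grid (zero outside tapping)
    tap_boundaries: np.ndarray  # full-grid sample indices of true closures
    taps: list[dict]  # per-tap {start, end, style} on the full grid
    R_thumb: np.ndarray  # (N,3,3) lab<-thumb-sensor
    R_index: np.ndarray  # (N,3,3) lab<-index-sensor
    R0_true: np.ndarray  # thumb->index rotation during calibration
    calibration_span: tuple[int, int]
    tapping_start: int
    thumb_mount: np.ndarray
    index_mount: np.ndarray
    spec: PatternSpec
    sensor_spec: SensorSpec
    seed: int = 0
    events: list[dict] = field(default_factory=list)

    @property
    def t(self) -> np.ndarray:
        return self.session.t


def _raised_cosine(tau: np.ndarray, period: float, amp: float) -> np.ndarray:
    return 0.5 * amp * (1.0 - np.cos(2.0 * np.pi * tau / period))


def _hann_bump(t: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    """C1 positive bump of total width ``width`` centered at ``center``."""
    u = t - center
    out = np.zeros_like(t)
    m = np.abs(u) < width / 2.0
    out[m] = 0.5 * amp * (1.0 + np.cos(2.0 * np.pi * u[m] / width))
    return out


def _place_skips(
    n_slots: int, n_skips: int, hold_range: tuple[int, int], rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Choose (slot, held_periods) for skip events, non-overlapping, away from
    the first and last slot so every sequence starts and ends with a plain tap."""
    picks: list[tuple[int, int]] = []
    occupied: set[int] = set()
    attempts = 0
    while len(picks) < n_skips and attempts < 200:
        attempts += 1
        hold = int(rng.integers(hold_range[0], hold_range[1] + 1))
        slot = int(rng.integers(1, n_slots - 1 - hold))
        span = set(range(slot - 1, slot + hold + 2))
        if span & occupied:
            continue
        occupied |= span
        picks.append((slot, hold))
    return sorted(picks)


def generate_truth(
    spec: PatternSpec, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray, list[dict], dict[str, np.ndarray]]:
    """Ground-truth tapping angle for the tapping segment.

    Returns
    -------
    t : (N,) seconds, starting at 0
    theta : (N,) radians, >= 0, zero at closures
    taps : list of {"start", "end", "style"} half-open sample ranges; the
        boundaries are the true closure instants
    extras : auxiliary angle series used by :func:`truth_to_orientations`
        ("slip" about-z transients, "thumb_drift" slow thumb-frame drift)
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = 200.0  # truth is built on the sensor timebase
    T = 1.0 / spec.tap_rate
    n_slots = int(round(spec.duration * spec.tap_rate))
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    theta = np.zeros(n)

    skips = (
        _place_skips(n_slots, spec.n_skips, spec.skip_hold_periods, rng)
        if spec.n_skips
        else []
    )
    skip_at = {slot: hold for slot, hold in skips}

    taps: list[dict] = []
    slot = 0
    while slot < n_slots:
        hold = skip_at.get(slot, 0)
        m = 1 + hold
        t0, t1 = slot * T, (slot + m) * T
        i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), n)
        tau = t[i0:i1] - t0
        if hold == 0:
            theta[i0:i1] = _raised_cosine(tau, T, spec.aperture_amp)
            style = "normal"
        elif spec.skip_style == "open":
            seg = np.empty_like(tau)
            rise = tau < T / 2.0
            fall = tau >= m * T - T / 2.0
            seg[rise] = _raised_cosine(tau[rise], T, spec.aperture_amp)
            seg[fall] = _raised_cosine(tau[fall] - (m - 1) * T, T, spec.aperture_amp)
            seg[~rise & ~fall] = spec.aperture_amp
            theta[i0:i1] = seg
            style = "skip_open"
        else:  # held (nearly) closed: plain tap followed by a closed tail
            seg = np.zeros_like(tau)
            active = tau < T
            seg[active] = _raised_cosine(tau[active], T, spec.aperture_amp)
            theta[i0:i1] = seg
            style = "skip_closed"
        taps.append({"start": i0, "end": i1, "style": style})
        slot += m

    if spec.tremor_amp > 0.0:
        envelope = np.clip(theta / spec.aperture_amp, 0.0, 1.0)
        theta = theta + spec.tremor_amp * np.sin(2 * np.pi * spec.tremor_freq * t) * envelope

    closures = [tap["end"] / fs for tap in taps if tap["end"] < n]
    if spec.impact_rate_peak > 0.0:
        amp = spec.impact_rate_peak * spec.impact_width / np.pi
        for tc in closures:
            theta += _hann_bump(t, tc, spec.impact_width, amp)

    slip = np.zeros(n)
    if spec.slip_amp > 0.0:
        for tc in closures:
            slip += _hann_bump(t, tc, spec.slip_width, spec.slip_amp)

    thumb_drift = (
        spec.thumb_drift_amp * t / spec.duration
        if spec.thumb_drift_amp > 0.0
        else np.zeros(n)
    )
    return t, theta, taps, {"slip": slip, "thumb_drift": thumb_drift}


def _hand_angles(spec: PatternSpec, n_total: int, fs: float, tap_start: int) -> np.ndarray:
    """Per-sample extrinsic x-y-z angles of the whole-hand pose H(t).

    The calibration segment draws vigorous "circles": three out-of-phase
    sinusoidal angles with a raised-cosine on/off ramp, exciting all axes.
    Pattern 5 adds a slow roll during tapping.
    """
    t = np.arange(n_total) / fs
    ang = np.zeros((n_total, 3))
    c0 = spec.still_s
    c1 = spec.still_s + spec.calibration_s
    m = (t >= c0) & (t < c1)
    tc = t[m] - c0
    ramp = 0.3
    env = np.ones_like(tc)
    env = np.minimum(env, np.clip(tc / ramp, 0.0, 1.0))
    env = np.minimum(env, np.clip((spec.calibration_s - tc) / ramp, 0.0, 1.0))
    env = 0.5 * (1.0 - np.cos(np.pi * np.clip(env, 0.0, 1.0)))  # smooth the ramp
    w = 2 * np.pi * spec.circle_freq
    for k, phase in enumerate((0.0, 2 * np.pi / 3, 4 * np.pi / 3)):
        ang[m, k] = spec.circle_amp * env * np.sin(w * tc + phase)
    if spec.hand_motion == "slow_rotation":
        tt = t[tap_start:] - t[tap_start]
        env2 = np.clip(tt / 1.0, 0.0, 1.0)
        ang[tap_start:, 0] += (
            spec.hand_roll_amp * env2 * np.sin(2 * np.pi * spec.hand_roll_freq * tt)
        )
    return ang


def truth_to_orientations(
    theta: np.ndarray,
    spec: PatternSpec,
    *,
    slip: np.ndarray | None = None,
    thumb_drift: np.ndarray | None = None,
    hand_angles: np.ndarray | None = None,
    thumb_mount: np.ndarray | None = None,
    index_mount: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Lab-frame sensor orientations realizing a tapping-angle trajectory.

    The index sensor follows the hand pose (times its mounting rotation); the
    thumb sensor carries the relative motion:

        ``R_rel = M2^T Rz(slip) Ry(theta - contact) Rx(drift) M1``

    so that the raw angle of ``R_index^T R_thumb`` equals
    ``-(theta - contact_offset)`` for any hand motion, matching the sign
    convention ``theta = -alpha``.

    Returns ``(R_thumb, R_index)`` as (N, 3, 3) stacks (sensor -> lab).
    """
    n = theta.shape[0]
    zeros = np.zeros(n)
    slip = zeros if slip is None else slip
    thumb_drift = zeros if thumb_drift is None else thumb_drift
    M1 = np.eye(3) if thumb_mount is None else thumb_mount
    M2 = np.eye(3) if index_mount is None else index_mount

    a = theta - spec.contact_offset
    rel = (
        _Rotation.from_matrix(M2).inv()
        * _Rotation.from_euler("z", slip[:, None])
        * _Rotation.from_euler("y", a[:, None])
        * _Rotation.from_euler("x", thumb_drift[:, None])
        * _Rotation.from_matrix(M1)
    )
    if hand_angles is None:
        H = _Rotation.identity(n)
    else:
        H = _Rotation.from_euler("xyz", hand_angles)
    R_index = H * _Rotation.from_matrix(M2)
    R_thumb = R_index * rel
    return R_thumb.as_matrix(), R_index.as_matrix()


def orientations_to_gyro(R: np.ndarray, dt: float) -> np.ndarray:
    """Body-frame angular velocity from a smooth orientation trajectory.

    Central differences through the rotation log: for interior samples
    ``omega[i] = rotvec(R[i-1]^T R[i+1]) / (2 dt)``, one-sided at the ends.
    Exact for constant rates, O(dt^2) otherwise.
    """
    r = _Rotation.from_matrix(R)
    n = len(r)
    w = np.empty((n, 3))
    if n < 2:
        return np.zeros((n, 3))
    w[1:-1] = (r[:-2].inv() * r[2:]).as_rotvec() / (2.0 * dt)
    w[0] = (r[0].inv() * r[1]).as_rotvec() / dt
    w[-1] = (r[-2].inv() * r[-1]).as_rotvec() / dt
    return w


def apply_sensor_model(
    omega: np.ndarray, spec: SensorSpec, rng: int | np.random.Generator = 0
) -> np.ndarray:
    """Corrupt an exact rad/s stream with the MEMS error model.

    Adds a constant bias, a bias random walk, and white noise (all specified
    in deg/s), clips at the full-scale range, and quantizes to the step
    implied by the ADC resolution.  Deterministic for a given generator state.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    w = np.degrees(np.asarray(omega, dtype=float))
    n = w.shape[0]
    dt = 1.0 / spec.sample_rate

    bias0 = np.asarray(spec.initial_bias_dps, dtype=float)
    if bias0.ndim == 0:
        bias0 = rng.uniform(-float(bias0), float(bias0), 3) if float(bias0) else np.zeros(3)
    walk = np.cumsum(
        rng.normal(0.0, spec.bias_walk_dps_sqrt_s * np.sqrt(dt), (n, 3)), axis=0
    )
    noise = rng.normal(0.0, spec.white_noise_sigma_dps, (n, 3))
    w = w + bias0 + walk + noise
    w = np.clip(w, -spec.full_scale_dps, spec.full_scale_dps)
    step = spec.quantization_step_dps
    w = np.round(w / step) * step
    return np.radians(w)


def generate_session(
    spec: PatternSpec | None = None,
    sensor_spec: SensorSpec | None = None,
    seed: int = 0,
) -> SyntheticSession:
    """Simulate one complete recorded session.

    Timeline: ``still_s`` of rest, ``calibration_s`` of whole-hand circles with
    fingers pressed together, ``settle_s`` pause, then ``duration`` of tapping.
    Returns the corrupted gyro session (with virtual marker boards) together
    with the noise-free ground truth.
    """
    spec = spec or PatternSpec()
    sensor = sensor_spec or SensorSpec()
    rng = np.random.default_rng(seed)
    fs = sensor.sample_rate
    dt = 1.0 / fs

    if spec.thumb_mount is not None:
        M1 = euler_to_matrix(np.asarray(spec.thumb_mount, dtype=float))
    else:
        M1 = euler_to_matrix(rng.uniform(-np.pi / 4, np.pi / 4, 3))
    M2 = (
        euler_to_matrix(np.asarray(spec.index_mount, dtype=float))
        if spec.index_mount is not None
        else np.eye(3)
    )

    t_tap, theta_tap, taps_tap, extras = generate_truth(spec, rng)
    n_still = int(round(spec.still_s * fs))
    n_cal = int(round(spec.calibration_s * fs))
    n_settle = int(round(spec.settle_s * fs))
    n_pre = n_still + n_cal + n_settle
    n_tap = theta_tap.shape[0]
    n = n_pre + n_tap
    t = np.arange(n) / fs

    theta = np.zeros(n)
    theta[n_pre:] = theta_tap
    slip = np.zeros(n)
    slip[n_pre:] = extras["slip"]
    drift = np.zeros(n)
    drift[n_pre:] = extras["thumb_drift"]
    hand = _hand_angles(spec, n, fs, n_pre)

    R1, R2 = truth_to_orientations(
        theta,
        spec,
        slip=slip,
        thumb_drift=drift,
        hand_angles=hand,
        thumb_mount=M1,
        index_mount=M2,
    )
    w1 = orientations_to_gyro(R1, dt)
    w2 = orientations_to_gyro(R2, dt)
    bias = np.asarray(sensor.initial_bias_dps, dtype=float)
    if bias.ndim == 2:  # explicit per-sensor biases
        s1 = replace(sensor, initial_bias_dps=bias[0])
        s2 = replace(sensor, initial_bias_dps=bias[1])
    else:
        s1 = s2 = sensor
    w1n = apply_sensor_model(w1, s1, rng)
    w2n = apply_sensor_model(w2, s2, rng)

    markers_thumb = np.einsum("nij,kj->nki", R1, MARKER_GEOMETRY_MM)
    markers_index = np.einsum("nij,kj->nki", R2, MARKER_GEOMETRY_MM) + np.array(
        [80.0, 0.0, 0.0]
    )

    # thumb->index rotation during calibration (theta = slip = drift = 0)
    R0_true = M2.T @ euler_to_matrix(
        np.array([0.0, -spec.contact_offset, 0.0])
    ) @ M1

    taps = [
        {"start": tp["start"] + n_pre, "end": tp["end"] + n_pre, "style": tp["style"]}
        for tp in taps_tap
    ]
    boundaries = np.array([tp["start"] for tp in taps] + [taps[-1]["end"]])

    session = GyroSession(
        t=t,
        w_thumb=w1n,
        w_index=w2n,
        markers_thumb=markers_thumb,
        markers_index=markers_index,
        meta={
            "synthetic": True,
            "task_id": spec.pattern_id,
            "seed": seed,
            "sample_rate": fs,
        },
    )
    return SyntheticSession(
        session=session,
        theta_true=theta,
        tap_boundaries=boundaries,
        taps=taps,
        R_thumb=R1,
        R_index=R2,
        R0_true=R0_true,
        calibration_span=(n_still, n_still + n_cal),
        tapping_start=n_pre,
        thumb_mount=M1,
        index_mount=M2,
        spec=spec,
        sensor_spec=sensor,
        seed=seed,
        events=[tp for tp in taps if tp["style"] != "normal"],
    )


def quiet_sensor() -> SensorSpec:
    """Sensor model with all stochastic errors and quantization disabled."""
    return SensorSpec(
        white_noise_sigma_dps=0.0,
        bias_walk_dps_sqrt_s=0.0,
        initial_bias_dps=0.0,
        resolution_bits=32,
    )
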