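"""Autocalibration: locate the co-movement window and estimate the initial
thumb-to-index rotation.

While the fingers are pressed together and the whole hand draws circles, both
gyroscopes sense the same angular-velocity vector expressed in their own
frames, ``w_index = R @ w_thumb``.  The window is recognized from the
measurement itself: both magnitudes vigorous and nearly equal for long
enough.  The rotation is parametrized by three Euler angles (so it is
orthonormal by construction) and found by Nelder-Mead simplex minimization of
the summed squared component residuals over the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import minimize

from .errors import CalibrationNotFoundError, LowExcitationWarning
from .kinematics import EulerXYZ, euler_to_matrix
from .session import CalibrationResult, CalibrationWindow, GyroSession

__all__ = [
    "CalibrationConfig",
    "detect_calibration_window",
    "calibration_cost",
    "estimate_initial_rotation",
]


@dataclass(frozen=True)
class CalibrationConfig:
    """Thresholds for window detection and optimizer policy.

    The defaults are engineering choices: 30 deg/s on both smoothed magnitudes
    counts as "vigorous", a relative magnitude mismatch under 10% as
    "practically equal", and a qualifying run must last at least 0.5 s.  The
    window is searched only in the first half of the recording, where the
    protocol places the calibration move.
    """

    vigor_dps: float = 30.0
    mismatch_max: float = 0.10
    min_duration_s: float = 0.5
    magnitude_smooth_s: float = 0.05
    search_fraction: float = 0.5
    fatol: float = 1e-10
    max_iter: int = 5000
    low_excitation_ratio: float = 0.02  # min/max eigenvalue of the window's
    # angular-velocity second-moment matrix below this flags weak axes


_RESTART_POINTS = [
    (np.pi / 4, 0.0, 0.0),
    (-np.pi / 4, 0.0, 0.0),
    (0.0, np.pi / 4, 0.0),
    (0.0, -np.pi / 4, 0.0),
    (0.0, 0.0, np.pi / 4),
    (0.0, 0.0, -np.pi / 4),
]


def detect_calibration_window(
    session: GyroSession, config: CalibrationConfig | None = None
) -> CalibrationWindow:
    """Earliest window where both sensors move vigorously with matched magnitudes.

    Raises :class:`CalibrationNotFoundError` when no contiguous run of at
    least ``min_duration_s`` qualifies within the searched region.
    """
    config = config or CalibrationConfig()
    if len(session) == 0:
        raise CalibrationNotFoundError("empty session")
    dt = session.dt
    m1 = np.linalg.norm(session.w_thumb, axis=1)
    m2 = np.linalg.norm(session.w_index, axis=1)
    k = max(1, int(round(config.magnitude_smooth_s / dt)))
    m1 = uniform_filter1d(m1, k, mode="nearest")
    m2 = uniform_filter1d(m2, k, mode="nearest")

    vigor = np.radians(config.vigor_dps)
    hi = np.maximum(m1, m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        mismatch = np.where(hi > 0, np.abs(m1 - m2) / hi, 1.0)
    ok = (m1 > vigor) & (m2 > vigor) & (mismatch < config.mismatch_max)
    limit = int(len(session) * config.search_fraction)
    ok[limit:] = False

    min_len = max(1, int(round(config.min_duration_s / dt)))
    # earliest run of True at least min_len long
    idx = np.flatnonzero(np.diff(np.r_[0, ok.view(np.int8), 0]))
    for start, stop in zip(idx[::2], idx[1::2]):
        if stop - start >= min_len:
            return CalibrationWindow(int(start), int(stop))
    raise CalibrationNotFoundError(
        "no co-movement interval of sufficient duration found"
    )


def calibration_cost(
    euler: EulerXYZ | np.ndarray, w_thumb: np.ndarray, w_index: np.ndarray
) -> float:
    """Summed squared residual ``|w_index - R(euler) @ w_thumb|^2`` over the window.

    Units (rad/s)^2; non-negative; zero iff the rotation maps every thumb
    sample exactly onto the index sample.
    """
    w1 = np.atleast_2d(np.asarray(w_thumb, dtype=float))
    w2 = np.atleast_2d(np.asarray(w_index, dtype=float))
    if w1.shape != w2.shape:
        raise ValueError("thumb and index series must have equal shapes")
    R = euler_to_matrix(euler)
    resid = w2 - w1 @ R.T
    return float(np.sum(resid * resid))


def _excitation_ratio(w: np.ndarray) -> float:
    m = w.T @ w
    ev = np.linalg.eigvalsh(m)
    return float(ev[0] / ev[-1]) if ev[-1] > 0 else 0.0


def estimate_initial_rotation(
    session: GyroSession,
    window: CalibrationWindow,
    config: CalibrationConfig | None = None,
) -> CalibrationResult:
    """Minimize the calibration cost over Euler angles with Nelder-Mead.

    Deterministic: starts from (0, 0, 0); if the achieved cost stays above the
    estimated noise floor, six fixed +/-45 deg restarts guard against local
    minima and the best result is kept.  A weakly excited window (all motion
    about one axis) is flagged, since the about-axis angle is then poorly
    identifiable.
    """
    config = config or CalibrationConfig()
    w1 = session.w_thumb[window.start : window.end]
    w2 = session.w_index[window.start : window.end]

    def run(x0):
        return minimize(
            calibration_cost,
            np.asarray(x0, dtype=float),
            args=(w1, w2),
            method="Nelder-Mead",
            options={
                "fatol": config.fatol,
                "xatol": 1e-8,
                "maxiter": config.max_iter,
                "maxfev": config.max_iter,
            },
        )

    best = run((0.0, 0.0, 0.0))
    # noise floor: residual power that pure sensor noise would leave behind
    floor = max(1e-12, 1e-6 * float(np.sum(w2 * w2)))
    if best.fun > floor:
        for x0 in _RESTART_POINTS:
            res = run(x0)
            if res.fun < best.fun:
                best = res

    low_exc = _excitation_ratio(w1) < config.low_excitation_ratio
    if low_exc:
        warnings.warn(
            "calibration window excites fewer than three axes; "
            "one Euler angle may be unidentifiable",
            LowExcitationWarning,
            stacklevel=2,
        )
    euler = EulerXYZ(*np.asarray(best.x, dtype=float))
    return CalibrationResult(
        euler=euler,
        R0=euler_to_matrix(euler),
        residual_cost=float(best.fun),
        window=window,
        converged=bool(best.success),
        low_excitation=low_exc,
    )
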