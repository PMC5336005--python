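"""Reference tapping angle from optical marker boards.

Each finger carries a rigid T-board with three markers: markers 1-2 along the
board's local x-axis, marker 3 offset along local y.  Per frame the board
frame is orthogonalized (Gram-Schmidt on x then y, exact for a rigid board),
the thumb-relative-to-index rotation is ``R = R_index^T R_thumb``, and the
raw angle follows the same atan2 extraction as the gyro path.  The reference
angle is reported with a constant offset so it is zero at the start of the
tapping sequence; whole-hand motion cancels exactly in the relative rotation.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateFrameError
from .session import AngleTrace

__all__ = [
    "board_rotation",
    "relative_rotation",
    "reference_angle_trace",
    "rigidity_violations",
]

_COLLINEAR_TOL = 1e-9


def board_rotation(markers: np.ndarray) -> np.ndarray:
    """Board-to-lab rotation matrix from one or many marker triads.

    Parameters
    ----------
    markers : (3, 3) or (N, 3, 3) array
        Rows are the lab-frame positions of markers 1..3 (any length unit).

    Returns
    -------
    (3, 3) or (N, 3, 3) rotation with columns = board axes in the lab frame:
    x along marker1->marker2, y the orthogonalized marker1->marker3
    direction, z their cross product.

    Raises
    ------
    DegenerateFrameError
        When the markers are collinear (or coincident) in any frame.
    """
    m = np.asarray(markers, dtype=float)
    single = m.ndim == 2
    if single:
        m = m[None]
    ex = m[:, 1] - m[:, 0]
    nx = np.linalg.norm(ex, axis=1, keepdims=True)
    if np.any(nx < _COLLINEAR_TOL):
        raise DegenerateFrameError("markers 1 and 2 coincide")
    ex = ex / nx
    v = m[:, 2] - m[:, 0]
    ey = v - np.sum(v * ex, axis=1, keepdims=True) * ex
    ny = np.linalg.norm(ey, axis=1, keepdims=True)
    if np.any(ny < _COLLINEAR_TOL * np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1.0)):
        raise DegenerateFrameError("collinear markers: board frame undefined")
    ey = ey / ny
    ez = np.cross(ex, ey)
    R = np.stack([ex, ey, ez], axis=-1)
    return R[0] if single else R


def relative_rotation(R_thumb: np.ndarray, R_index: np.ndarray) -> np.ndarray:
    """Thumb-to-index rotation ``R_index^T @ R_thumb`` (inverse = transpose);
    accepts single matrices or (N, 3, 3) stacks."""
    R1 = np.asarray(R_thumb, dtype=float)
    R2 = np.asarray(R_index, dtype=float)
    return np.swapaxes(R2, -1, -2) @ R1


def rigidity_violations(markers: np.ndarray, tolerance_mm: float = 2.0) -> np.ndarray:
    """Frame indices where any pairwise marker distance deviates from its
    median over time by more than ``tolerance_mm``."""
    m = np.asarray(markers, dtype=float)
    pairs = [(0, 1), (0, 2), (1, 2)]
    d = np.stack([np.linalg.norm(m[:, i] - m[:, j], axis=1) for i, j in pairs], axis=1)
    ref = np.median(d, axis=0)
    return np.flatnonzero(np.any(np.abs(d - ref) > tolerance_mm, axis=1))


def reference_angle_trace(
    markers_thumb: np.ndarray,
    markers_index: np.ndarray,
    t: np.ndarray,
    tapping_start: int = 0,
) -> AngleTrace:
    """Reference tapping angle from synchronized marker streams.

    ``theta_ref = -alpha_ref + offset`` with the offset chosen so
    ``theta_ref`` is zero at ``tapping_start`` (the baseline is not removed on
    the reference path; a constant suffices because the cameras do not drift).
    """
    R1 = board_rotation(markers_thumb)
    R2 = board_rotation(markers_index)
    rel = relative_rotation(R1, R2)
    r11 = rel[:, 0, 0]
    r31 = rel[:, 2, 0]
    if np.any(r11 * r11 + r31 * r31 < 1e-12):
        raise DegenerateFrameError("thumb x-axis parallel to index y-axis in a frame")
    alpha = np.arctan2(r31, r11)
    alpha = np.unwrap(alpha)
    theta = -alpha
    theta = theta - theta[tapping_start]
    return AngleTrace(
        t=np.asarray(t, dtype=float), alpha=alpha, theta=theta, algorithm="MOCAP"
    )
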