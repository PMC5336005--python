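"""Rotation-matrix algebra for the two-finger sensor problem.

All rotations are proper, right-handed 3x3 orthonormal matrices stored as
``numpy.ndarray``.  The inter-sensor rotation ``R`` maps vector components
expressed in the thumb sensor frame into the index-finger sensor frame,
``v_index = R @ v_thumb``.  Angles are radians and angular velocities rad/s
throughout the library; file I/O converts to the clinical degree units.

The raw tapping angle ``alpha`` is the signed angle (right-hand rule about
the index y-axis) between the projection of the thumb longitudinal axis onto
the index x-z plane and the index x-axis: ``alpha = atan2(r31, r11)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import asin, atan2, cos, sin

import numpy as np
from scipy.spatial.transform import Rotation as _Rotation

from .errors import DegenerateProjectionError

__all__ = [
    "EulerXYZ",
    "axis_rotation",
    "euler_to_matrix",
    "matrix_to_euler",
    "small_angle_update",
    "raw_angle",
    "quaternion_integrate",
    "is_rotation",
    "rotation_distance",
]

_IDENT = np.eye(3)


@dataclass(frozen=True)
class EulerXYZ:
    """Euler angles (radians) of the composition ``R = Rz(phi_z) @ Ry(phi_y) @ Rx(phi_x)``.

    The x-rotation is applied first, then y, then z, all about the axes of
    the *index* (target) frame.
    """

    phi_x: float
    phi_y: float
    phi_z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.phi_x, self.phi_y, self.phi_z], dtype=float)

    def as_degrees(self) -> np.ndarray:
        return np.degrees(self.as_array())


def axis_rotation(axis: str, angle: float) -> np.ndarray:
    """Right-handed rotation matrix about a named coordinate axis.

    Parameters
    ----------
    axis : {'x', 'y', 'z'}
    angle : float
        Rotation angle in radians.
    """
    c, s = cos(angle), sin(angle)
    if axis == "x":
        return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    if axis == "y":
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    if axis == "z":
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    raise ValueError(f"axis must be one of 'x', 'y', 'z', got {axis!r}")


def euler_to_matrix(euler: EulerXYZ | np.ndarray) -> np.ndarray:
    """Compose ``Rz(phi_z) @ Ry(phi_y) @ Rx(phi_x)``; orthonormal by construction."""
    if isinstance(euler, EulerXYZ):
        px, py, pz = euler.phi_x, euler.phi_y, euler.phi_z
    else:
        px, py, pz = np.asarray(euler, dtype=float)
    return axis_rotation("z", pz) @ axis_rotation("y", py) @ axis_rotation("x", px)


def matrix_to_euler(R: np.ndarray) -> EulerXYZ:
    """Recover the x-y-z Euler angles of ``R = Rz @ Ry @ Rx``.

    Away from gimbal lock (|phi_y| = pi/2) the decomposition is unique with
    phi_x, phi_z in (-pi, pi] and phi_y in [-pi/2, pi/2].
    """
    r31 = float(np.clip(R[2, 0], -1.0, 1.0))
    phi_y = asin(-r31)
    if abs(r31) > 1.0 - 1e-12:  # gimbal lock: only phi_x +/- phi_z defined
        phi_x = atan2(-R[1, 2], R[1, 1])
        phi_z = 0.0
    else:
        phi_x = atan2(R[2, 1], R[2, 2])
        phi_z = atan2(R[1, 0], R[0, 0])
    return EulerXYZ(phi_x, phi_y, phi_z)


def small_angle_update(R: np.ndarray, dphi: np.ndarray) -> np.ndarray:
    """One strapdown step: premultiply ``R`` by the three per-axis increments.

    ``R_next = Rz(dphi_z) @ Ry(dphi_y) @ Rx(dphi_x) @ R`` with exact sines and
    cosines of the increments (no first-order truncation).  The product of
    orthonormal factors stays orthonormal to round-off, so no explicit
    re-orthonormalization is required per step.
    """
    dx, dy, dz = dphi
    cx, sx = cos(dx), sin(dx)
    cy, sy = cos(dy), sin(dy)
    cz, sz = cos(dz), sin(dz)
    # Rz @ Ry @ Rx written out once; this runs in the per-sample hot loop.
    D = np.array(
        [
            [cz * cy, cz * sy * sx - sz * cx, cz * sy * cx + sz * sx],
            [sz * cy, sz * sy * sx + cz * cx, sz * sy * cx - cz * sx],
            [-sy, cy * sx, cy * cx],
        ]
    )
    return D @ R


def raw_angle(R: np.ndarray, eps: float = 1e-12) -> float:
    """Raw tapping angle ``alpha = atan2(r31, r11)`` in (-pi, pi].

    Raises
    ------
    DegenerateProjectionError
        If the thumb x-axis is parallel to the index y-axis
        (``r11**2 + r31**2 < eps``), so the projection is undefined.
    """
    r11 = R[0, 0]
    r31 = R[2, 0]
    if r11 * r11 + r31 * r31 < eps:
        raise DegenerateProjectionError(
            "thumb x-axis parallel to index y-axis; tapping angle undefined"
        )
    return atan2(r31, r11)


def quaternion_integrate(
    omega: np.ndarray, dt: float, R0: np.ndarray | None = None
) -> np.ndarray:
    """Integrate a relative angular-velocity stream with unit quaternions.

    Space-frame (premultiplicative) convention: each step applies the rotation
    vector ``omega[n] * dt`` on the left, and the quaternion is renormalized by
    the backend at every composition.  This is an independent integration path
    used to cross-check the rotation-matrix chain of the continuous algorithm.

    Parameters
    ----------
    omega : (N, 3) array
        Angular velocity in the (fixed) index frame, rad/s.
    dt : float
        Uniform sample interval, seconds.
    R0 : (3, 3) array, optional
        Initial rotation (identity when omitted).

    Returns
    -------
    (N, 3, 3) array
        Rotation matrix *before* applying increment ``n``, matching the
        convention that sample ``n`` of the continuous algorithm reads the
        matrix and then updates it.
    """
    omega = np.asarray(omega, dtype=float)
    n = omega.shape[0]
    q = _Rotation.identity() if R0 is None else _Rotation.from_matrix(R0)
    out = np.empty((n, 3, 3))
    for i in range(n):
        out[i] = q.as_matrix()
        q = _Rotation.from_rotvec(omega[i] * dt) * q
    return out


def is_rotation(R: np.ndarray, tol: float = 1e-9) -> bool:
    """True when ``R`` is orthonormal with determinant +1 within ``tol``."""
    R = np.asarray(R)
    return (
        R.shape == (3, 3)
        and np.allclose(R.T @ R, _IDENT, atol=tol)
        and abs(np.linalg.det(R) - 1.0) < tol
    )


def rotation_distance(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Geodesic angle (radians) between two rotations."""
    c = (np.trace(Ra.T @ Rb) - 1.0) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))
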