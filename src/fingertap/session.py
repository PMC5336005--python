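"""Data containers shared across the pipeline.

A :class:`GyroSession` is one recorded sequence: a uniform timebase plus the
thumb and index tri-axial angular velocities (rad/s internally) and optional
synchronized marker-board trajectories (mm, lab frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class GyroSession:
    """Paired thumb/index angular-velocity streams on one uniform timebase.

    Attributes
    ----------
    t : (N,) array, seconds
    w_thumb, w_index : (N, 3) arrays, rad/s, in each sensor's own frame
    markers_thumb, markers_index : (N, 3, 3) arrays or None
        Lab-frame positions (mm) of the three board markers, row per marker.
    meta : dict
        Free-form metadata (subject id, hand, task id, seed if synthetic).
    """

    t: np.ndarray
    w_thumb: np.ndarray
    w_index: np.ndarray
    markers_thumb: np.ndarray | None = None
    markers_index: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.w_thumb = np.asarray(self.w_thumb, dtype=float)
        self.w_index = np.asarray(self.w_index, dtype=float)
        n = self.t.shape[0]
        if self.w_thumb.shape != (n, 3) or self.w_index.shape != (n, 3):
            raise ValueError("angular-velocity arrays must be (N, 3) matching t")

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    @property
    def has_markers(self) -> bool:
        return self.markers_thumb is not None and self.markers_index is not None


@dataclass
class AngleTrace:
    """Tapping-angle time series produced by one estimation algorithm.

    ``alpha`` is the raw signed angle; ``theta`` is its sign reversal (and
    after :func:`fingertap.segmentation.remove_baseline`, the baseline-free
    clinical angle: zero at every finger closure).  ``final_drift`` is the
    absolute difference of ``alpha`` between the closed-finger instants at the
    start and end of the tapping segment, radians.
    """

    t: np.ndarray
    alpha: np.ndarray
    theta: np.ndarray
    algorithm: str  # "AL-C" | "AL-R" | "MOCAP"
    final_drift: float = 0.0

    def __len__(self) -> int:
        return self.t.shape[0]

    def slice(self, start: int, stop: int | None = None) -> "AngleTrace":
        sl = np.s_[start:stop]
        return AngleTrace(
            self.t[sl], self.alpha[sl], self.theta[sl], self.algorithm, self.final_drift
        )


@dataclass
class TapSet:
    """Per-tap segmentation of an angle trace.

    Tap ``k`` spans the half-open index range ``[boundaries[k], boundaries[k+1])``
    where the boundaries are the closure minima of theta; ``maxima[k]`` is the
    opening peak inside tap ``k``.  Feature arrays are filled by
    :func:`fingertap.segmentation.extract_tap_features` (radians / seconds).
    """

    boundaries: np.ndarray  # (K+1,) int sample indices, strictly increasing
    maxima: np.ndarray  # (K,) int
    duration_s: np.ndarray | None = None
    aperture_rad: np.ndarray | None = None
    peak_opening_rad_s: np.ndarray | None = None
    peak_closing_rad_s: np.ndarray | None = None

    @property
    def n_taps(self) -> int:
        return max(self.boundaries.shape[0] - 1, 0)

    def intervals(self) -> list[tuple[int, int]]:
        b = self.boundaries
        return [(int(b[k]), int(b[k + 1])) for k in range(self.n_taps)]

    def to_frame(self, t: np.ndarray):
        """Per-tap table in clinical units (degrees, deg/s)."""
        import pandas as pd

        rows = {
            "tap_index": np.arange(self.n_taps),
            "t_start_s": t[self.boundaries[:-1]],
            "t_end_s": t[self.boundaries[1:]],
        }
        if self.duration_s is not None:
            rows["duration_s"] = self.duration_s
            rows["aperture_deg"] = np.degrees(self.aperture_rad)
            rows["peak_open_dps"] = np.degrees(self.peak_opening_rad_s)
            rows["peak_close_dps"] = np.degrees(self.peak_closing_rad_s)
        return pd.DataFrame(rows)


@dataclass
class CalibrationWindow:
    """Half-open sample range ``[start, end)`` of the autocalibration segment."""

    start: int
    end: int

    @property
    def n(self) -> int:
        return self.end - self.start

    def duration(self, dt: float) -> float:
        return self.n * dt


@dataclass
class CalibrationResult:
    """Initial thumb-to-index rotation estimated from the calibration window."""

    euler: Any  # EulerXYZ
    R0: np.ndarray
    residual_cost: float  # (rad/s)^2, summed over the window
    window: CalibrationWindow
    converged: bool = True
    low_excitation: bool = False


@dataclass
class AgreementReport:
    """Agreement between an estimated trace and a reference: per-tap ICC
    averaged over the sequence, per-tap RMS error, and absolute/relative
    aperture errors."""

    icc_mean: float
    rmse_deg: float
    aperture_abs_err_deg: float
    aperture_rel_err: float
    icc_per_tap: np.ndarray | None = None
    rmse_per_tap_deg: np.ndarray | None = None
    aperture_abs_per_pair_deg: np.ndarray | None = None
    aperture_rel_per_pair: np.ndarray | None = None
    n_pairs: int = 0

    def summary(self) -> dict[str, float]:
        return {
            "icc_mean": float(self.icc_mean),
            "rmse_deg": float(self.rmse_deg),
            "aperture_abs_err_deg": float(self.aperture_abs_err_deg),
            "aperture_rel_err": float(self.aperture_rel_err),
            "n_pairs": int(self.n_pairs),
        }
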