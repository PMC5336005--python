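"""Session file formats.

Gyro CSV: header ``t_s,w1x,w1y,w1z,w2x,w2y,w2z``, angular velocities in
deg/s (sensor 1 = thumb, 2 = index).  Marker CSV: ``t_s`` plus 18 columns
(x/y/z in mm for thumb markers 1-3 then index markers 1-3, lab frame).
Truth JSON carries the simulator ground truth; report JSON the pipeline
output.  Everything internal is radians; these readers/writers convert.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import SessionFormatError
from .session import GyroSession

__all__ = [
    "read_gyro_csv",
    "write_gyro_csv",
    "read_marker_csv",
    "write_marker_csv",
    "write_truth_json",
    "read_truth_json",
    "write_trace_csv",
    "write_taps_tsv",
]

GYRO_COLUMNS = ["t_s", "w1x", "w1y", "w1z", "w2x", "w2y", "w2z"]

_MARKER_COLUMNS = ["t_s"] + [
    f"{finger}{m}{ax}" for finger in ("thumb", "index") for m in (1, 2, 3) for ax in "xyz"
]

_MAX_NAN_RUN_S = 0.025
_JITTER_TOL_S = 1e-6


def write_gyro_csv(path: str | Path, session: GyroSession) -> None:
    data = np.column_stack(
        [session.t, np.degrees(session.w_thumb), np.degrees(session.w_index)]
    )
    pd.DataFrame(data, columns=GYRO_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_gyro_csv(path: str | Path) -> GyroSession:
    """Read and validate a gyro CSV (deg/s on disk, rad/s in memory).

    Raises :class:`SessionFormatError` for missing columns, non-monotone or
    non-uniform time, or NaN runs longer than 25 ms; shorter gaps are filled
    by linear interpolation.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in GYRO_COLUMNS if c not in df.columns]
    if missing:
        raise SessionFormatError(f"missing columns: {missing}")
    t = df["t_s"].to_numpy(dtype=float)
    if t.shape[0] < 2:
        raise SessionFormatError("need at least two samples")
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise SessionFormatError("time column is not strictly increasing")
    if np.ptp(dts) > _JITTER_TOL_S:
        raise SessionFormatError("sampling is not uniform within tolerance")
    w = df[GYRO_COLUMNS[1:]].to_numpy(dtype=float)
    if np.isnan(w).any():
        dt = float(dts[0])
        max_run = int(np.ceil(_MAX_NAN_RUN_S / dt))
        for col in range(w.shape[1]):
            bad = np.isnan(w[:, col])
            if not bad.any():
                continue
            runs = np.diff(np.r_[0, bad.view(np.int8), 0])
            lengths = np.flatnonzero(runs == -1) - np.flatnonzero(runs == 1)
            if lengths.max() > max_run or bad[0] or bad[-1]:
                raise SessionFormatError("NaN run exceeds 25 ms (or touches an edge)")
            good = ~bad
            w[bad, col] = np.interp(t[bad], t[good], w[good, col])
        import warnings

        warnings.warn("short NaN gaps filled by linear interpolation", stacklevel=2)
    return GyroSession(
        t=t,
        w_thumb=np.radians(w[:, :3]),
        w_index=np.radians(w[:, 3:]),
        meta={"source": str(path)},
    )


def write_marker_csv(path: str | Path, session: GyroSession) -> None:
    if not session.has_markers:
        raise ValueError("session has no marker streams")
    data = np.column_stack(
        [
            session.t,
            session.markers_thumb.reshape(len(session), 9),
            session.markers_index.reshape(len(session), 9),
        ]
    )
    pd.DataFrame(data, columns=_MARKER_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_marker_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns ``(t, markers_thumb, markers_index)`` with marker arrays (N, 3, 3)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in _MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise SessionFormatError(f"missing columns: {missing}")
    t = df["t_s"].to_numpy(dtype=float)
    vals = df[_MARKER_COLUMNS[1:]].to_numpy(dtype=float)
    n = t.shape[0]
    return t, vals[:, :9].reshape(n, 3, 3), vals[:, 9:].reshape(n, 3, 3)


def write_truth_json(path: str | Path, synth) -> None:
    """Serialize a :class:`~fingertap.simulate.SyntheticSession` ground truth."""
    payload = {
        "seed": synth.seed,
        "pattern_id": synth.spec.pattern_id,
        "sample_rate": synth.sensor_spec.sample_rate,
        "tapping_start": int(synth.tapping_start),
        "calibration_span": list(synth.calibration_span),
        "theta_true_deg": np.degrees(synth.theta_true).tolist(),
        "tap_boundaries": synth.tap_boundaries.tolist(),
        "taps": synth.taps,
        "R0_true": synth.R0_true.tolist(),
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(synth.spec).items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_truth_json(path: str | Path) -> dict[str, Any]:
    payload = json.loads(Path(path).read_text())
    payload["theta_true"] = np.radians(np.asarray(payload.pop("theta_true_deg")))
    payload["tap_boundaries"] = np.asarray(payload["tap_boundaries"], dtype=int)
    payload["R0_true"] = np.asarray(payload["R0_true"])
    return payload


def write_trace_csv(path: str | Path, trace) -> None:
    pd.DataFrame(
        {
            "t_s": trace.t,
            "alpha_deg": np.degrees(trace.alpha),
            "theta_deg": np.degrees(trace.theta),
            "algorithm": trace.algorithm,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def write_taps_tsv(path: str | Path, tapset, t: np.ndarray) -> None:
    tapset.to_frame(t).to_csv(path, sep="\t", index=False, float_format="%.6g")
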