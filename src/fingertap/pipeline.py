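"""End-to-end session processing.

``run_pipeline`` chains: autocalibration window detection -> initial-rotation
estimation -> continuous (AL-C) and resetting (AL-R) angle estimation over
the tapping segment (with dominant-axis realignment when needed) -> the
drift rule selecting between them -> tap segmentation, baseline removal and
per-tap features -> optional agreement metrics against a marker-board or
simulator ground-truth reference.  The result is a deterministic
:class:`SessionReport` serializable to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__ as _pkg_version
from .angles import (
    DRIFT_SWITCH_RAD,
    estimate_drift,
    realign_index_frame,
    relative_angular_velocity,
    run_alc,
    run_alr,
    select_algorithm,
)
from .calibration import (
    CalibrationConfig,
    detect_calibration_window,
    estimate_initial_rotation,
)
from .errors import FingertapError, NoTapsError, PairingError
from .metrics import agreement_report
from .mocap import reference_angle_trace
from .segmentation import SegmentationConfig, extract_tap_features, segment
from .session import AgreementReport, AngleTrace, GyroSession, TapSet

__all__ = ["PipelineConfig", "SessionReport", "AlgorithmResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline thresholds in one serializable place."""

    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    guard_s: float = 0.25  # gap between calibration window end and tapping segment
    drift_switch_rad: float = DRIFT_SWITCH_RAD
    realign: bool = True
    reorthonormalize_every: int = 0
    min_ref_aperture_rad: float = np.radians(2.0)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        cal = CalibrationConfig(**payload.pop("calibration", {}))
        seg = SegmentationConfig(**payload.pop("segmentation", {}))
        return PipelineConfig(calibration=cal, segmentation=seg, **payload)


@dataclass
class AlgorithmResult:
    """One algorithm's trace over the tapping segment plus its segmentation."""

    trace: AngleTrace  # theta baseline-corrected
    taps: TapSet
    period_s: float
    final_drift_rad: float
    agreement: AgreementReport | None = None
    error: str | None = None


@dataclass
class SessionReport:
    calibration: Any = None  # CalibrationResult
    realignment: np.ndarray | None = None
    tapping_start: int = 0
    alc: AlgorithmResult | None = None
    alr: AlgorithmResult | None = None
    selected: str | None = None
    config: PipelineConfig = field(default_factory=PipelineConfig)
    version: str = _pkg_version
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def selected_result(self) -> AlgorithmResult | None:
        return self.alc if self.selected == "AL-C" else self.alr

    def to_dict(self) -> dict[str, Any]:
        """JSON-friendly summary (traces summarized, not embedded)."""

        def _alg(res: AlgorithmResult | None) -> dict[str, Any] | None:
            if res is None:
                return None
            out: dict[str, Any] = {
                "final_drift_deg": float(np.degrees(res.final_drift_rad)),
                "error": res.error,
            }
            if res.error is None:
                out.update(
                    {
                        "n_taps": int(res.taps.n_taps),
                        "period_s": float(res.period_s),
                        "mean_aperture_deg": float(
                            np.degrees(np.mean(res.taps.aperture_rad))
                        ),
                        "mean_duration_s": float(np.mean(res.taps.duration_s)),
                        "agreement": res.agreement.summary() if res.agreement else None,
                    }
                )
            return out

        cal = self.calibration
        return {
            "version": self.version,
            "calibration": None
            if cal is None
            else {
                "window": [cal.window.start, cal.window.end],
                "euler_deg": cal.euler.as_degrees().tolist(),
                "residual_cost": cal.residual_cost,
                "converged": cal.converged,
                "low_excitation": cal.low_excitation,
            },
            "realigned": self.realignment is not None
            and not np.allclose(self.realignment, np.eye(3)),
            "tapping_start": int(self.tapping_start),
            "alc": _alg(self.alc),
            "alr": _alg(self.alr),
            "selected": self.selected,
            "errors": self.errors,
            "config": json.loads(self.config.to_json()),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _segment_and_score(
    trace: AngleTrace,
    drift: float,
    config: PipelineConfig,
    theta_ref: np.ndarray | None,
    ref_taps: TapSet | None,
    dt: float,
) -> AlgorithmResult:
    try:
        taps, corrected, period = segment(trace.theta, dt, config.segmentation)
    except (NoTapsError, FingertapError) as exc:
        return AlgorithmResult(
            trace=trace, taps=TapSet(np.array([], dtype=int), np.array([], dtype=int)),
            period_s=float("nan"), final_drift_rad=drift, error=str(exc),
        )
    out_trace = AngleTrace(trace.t, trace.alpha, corrected, trace.algorithm, drift)
    result = AlgorithmResult(
        trace=out_trace, taps=taps, period_s=period, final_drift_rad=drift
    )
    if theta_ref is not None and ref_taps is not None:
        try:
            result.agreement = agreement_report(
                corrected, theta_ref, taps, ref_taps, dt, config.min_ref_aperture_rad
            )
        except (PairingError, ValueError) as exc:
            result.error = f"agreement: {exc}"
    return result


def run_pipeline(
    session: GyroSession,
    config: PipelineConfig | None = None,
    *,
    reference: str | None = "auto",
    truth_theta: np.ndarray | None = None,
    truth_boundaries: np.ndarray | None = None,
    algorithm: str = "auto",
) -> SessionReport:
    """Process one session end to end.

    Parameters
    ----------
    session : GyroSession
    config : PipelineConfig, optional
    reference : {"auto", "markers", None}
        "auto" uses marker boards when present (or explicit truth arrays when
        given); None skips agreement metrics.
    truth_theta, truth_boundaries : arrays, optional
        Simulator ground truth on the session timebase: the noise-free angle
        and the true closure indices.  Takes precedence over markers.
    algorithm : {"auto", "alc", "alr"}
        "auto" applies the 60-degree final-drift rule.
    """
    config = config or PipelineConfig()
    report = SessionReport(config=config)
    dt = session.dt

    window = detect_calibration_window(session, config.calibration)
    cal = estimate_initial_rotation(session, window, config.calibration)
    report.calibration = cal

    tap_start = min(window.end + int(round(config.guard_s / dt)), len(session) - 1)
    report.tapping_start = tap_start

    Q = np.eye(3)
    R0 = cal.R0
    work = session
    if config.realign:
        # decide the dominant axis with the calibration rotation held fixed:
        # for scissor-like motion this gives the exact rotation axis and is
        # immune to the tumbling a drifting integrated matrix can develop
        wr_fixed = relative_angular_velocity(
            cal.R0, session.w_thumb[tap_start:], session.w_index[tap_start:]
        )
        work, Q, R0 = realign_index_frame(session, cal.R0, wr_fixed, dt)
    report.realignment = Q

    # AL-C from the window end; the settle gap keeps the matrix near R0
    alc_full = run_alc(
        work, R0, start=window.end,
        reorthonormalize_every=config.reorthonormalize_every,
    )
    rel_offset = tap_start - window.end

    drift_alc = estimate_drift(alc_full.trace, rel_offset)
    alc_trace = alc_full.trace.slice(rel_offset)
    alr_trace = run_alr(work, R0, start=tap_start)
    drift_alr = estimate_drift(alr_trace, 0)

    theta_ref = None
    ref_taps = None
    if truth_theta is not None and truth_boundaries is not None:
        theta_ref = np.asarray(truth_theta, dtype=float)[tap_start:]
        b = np.asarray(truth_boundaries, dtype=int) - tap_start
        b = b[b >= 0]
        if b.size >= 2:
            maxima = np.array(
                [b[k] + int(np.argmax(theta_ref[b[k] : b[k + 1]])) for k in range(b.size - 1)]
            )
            ref_taps = extract_tap_features(theta_ref, TapSet(b, maxima), dt)
    elif reference in ("auto", "markers") and session.has_markers:
        ref = reference_angle_trace(
            session.markers_thumb, session.markers_index, session.t, tap_start
        )
        theta_ref = ref.theta[tap_start:]
        try:
            rt, ref_corr, _ = segment(theta_ref, dt, config.segmentation)
            ref_taps = rt
            theta_ref = ref_corr
        except FingertapError:
            ref_taps = None

    report.alc = _segment_and_score(
        alc_trace, drift_alc, config, theta_ref, ref_taps, dt
    )
    report.alr = _segment_and_score(
        alr_trace, drift_alr, config, theta_ref, ref_taps, dt
    )

    if algorithm == "alc":
        report.selected = "AL-C"
    elif algorithm == "alr":
        report.selected = "AL-R"
    else:
        report.selected = select_algorithm(drift_alc, config.drift_switch_rad)
    return report
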