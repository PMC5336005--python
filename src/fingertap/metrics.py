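"""Agreement metrics between an estimated angle trace and a reference.

Per-tap intraclass correlation (two-way random, absolute agreement, single
measures, computed from the ANOVA decomposition), per-tap RMS error, and
absolute/relative aperture errors with taps paired by maximal temporal
overlap.  The per-tap statistics are averaged over the sequence, mirroring
how the error measures are reported clinically.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import PairingError
from .session import AgreementReport, TapSet

__all__ = [
    "icc_per_tap",
    "rmse",
    "aperture_errors",
    "pair_taps",
    "agreement_report",
]


def icc_per_tap(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    The paired samples within one tap are the targets; the two measurement
    methods are the raters.  With mean squares from the two-way ANOVA
    (MSR rows/targets, MSC columns/raters, MSE residual) and k = 2 raters,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Absolute agreement: a constant offset between the series lowers the
    coefficient.  Returns NaN when both series have zero variance (the
    statistic is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length 1-D series")
    n = x.shape[0]
    if n < 2:
        return float("nan")
    data = np.stack([x, y], axis=1)  # n targets x k raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return float("nan")
    return float((msr - mse) / denom)


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-square difference of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def _overlap_matrix(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> np.ndarray:
    out = np.zeros((len(a), len(b)))
    for i, (s1, e1) in enumerate(a):
        for j, (s2, e2) in enumerate(b):
            out[i, j] = max(0, min(e1, e2) - max(s1, s2))
    return out


def pair_taps(est: TapSet, ref: TapSet) -> list[tuple[int, int]]:
    """Pair estimated and reference taps by maximal total temporal overlap.

    One-to-one assignment (Hungarian algorithm on negative overlap); pairs
    with zero overlap are discarded, so a missed or extra tap simply stays
    unpaired.  Raises :class:`PairingError` when no pair overlaps at all.
    """
    ov = _overlap_matrix(est.intervals(), ref.intervals())
    if ov.size == 0 or ov.max() == 0:
        raise PairingError("estimated and reference tap sets do not overlap")
    rows, cols = linear_sum_assignment(-ov)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if ov[i, j] > 0]


def aperture_errors(
    est: TapSet, ref: TapSet, min_ref_aperture: float = np.radians(2.0)
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Mean absolute and relative per-tap aperture errors over paired taps.

    Relative errors use the reference aperture as denominator; reference taps
    narrower than ``min_ref_aperture`` are excluded from the relative mean (a
    division guard).  Returns ``(abs_mean, rel_mean, abs_per_pair,
    rel_per_pair)`` in radians / dimensionless.
    """
    if est.aperture_rad is None or ref.aperture_rad is None:
        raise ValueError("both tap sets need extracted features")
    pairs = pair_taps(est, ref)
    abs_err = np.array(
        [abs(est.aperture_rad[i] - ref.aperture_rad[j]) for i, j in pairs]
    )
    ref_ap = np.array([ref.aperture_rad[j] for _, j in pairs])
    ok = ref_ap >= min_ref_aperture
    rel_err = abs_err[ok] / ref_ap[ok]
    rel_mean = float(rel_err.mean()) if rel_err.size else float("nan")
    return float(abs_err.mean()), rel_mean, abs_err, rel_err


def agreement_report(
    theta_est: np.ndarray,
    theta_ref: np.ndarray,
    est_taps: TapSet,
    ref_taps: TapSet,
    dt: float,
    min_ref_aperture: float = np.radians(2.0),
) -> AgreementReport:
    """Sequence-level agreement between an estimate and a reference.

    Both angle series must share the (gyro) timebase; taps for the ICC and
    RMS statistics come from the estimate's segmentation, mirrored onto the
    reference by time, while aperture errors pair the two independent tap
    sets by overlap.  Per-tap ICC and RMS error are averaged over taps
    (undefined ICCs skipped); errors are reported in degrees.
    """
    theta_est = np.asarray(theta_est, dtype=float)
    theta_ref = np.asarray(theta_ref, dtype=float)
    if theta_est.shape != theta_ref.shape:
        raise ValueError("estimate and reference must share one timebase")
    iccs, rmses = [], []
    for s, e in est_taps.intervals():
        seg_e = theta_est[s : e + 1]
        seg_r = theta_ref[s : e + 1]
        iccs.append(icc_per_tap(seg_e, seg_r))
        rmses.append(rmse(seg_e, seg_r))
    iccs = np.array(iccs)
    rmses = np.degrees(np.array(rmses))
    abs_mean, rel_mean, abs_pp, rel_pp = aperture_errors(
        est_taps, ref_taps, min_ref_aperture
    )
    return AgreementReport(
        icc_mean=float(np.nanmean(iccs)) if iccs.size else float("nan"),
        rmse_deg=float(rmses.mean()) if rmses.size else float("nan"),
        aperture_abs_err_deg=float(np.degrees(abs_mean)),
        aperture_rel_err=rel_mean,
        icc_per_tap=iccs,
        rmse_per_tap_deg=rmses,
        aperture_abs_per_pair_deg=np.degrees(abs_pp),
        aperture_rel_per_pair=rel_pp,
        n_pairs=abs_pp.shape[0],
    )
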