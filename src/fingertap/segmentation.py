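"""Tap segmentation and baseline removal.

The closure minima of the tapping angle delimit individual taps.  The stages
are: estimate the average tapping period from the autocorrelation of theta,
smooth with a short moving average (contact bumps, tremor, sensor noise),
walk through the sequence placing one closure minimum per period with a local
heuristic search, refine the minima on the unsmoothed series, subtract the
piecewise-linear baseline through the minima, and read per-tap features.

The walk is robust to the clinically important irregularities: a held-open
skip shows no closure for several periods (the search window extends until a
genuine near-baseline minimum appears), a held-closed skip produces a long
flat valley (spurious sub-aperture "taps" inside it are merged into their
predecessor), and tremor produces shallow dips that are only accepted near
the running closure level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelmin, find_peaks

from .errors import AperiodicSignalError, NoTapsError
from .session import TapSet

__all__ = [
    "SegmentationConfig",
    "estimate_period",
    "smooth",
    "find_tap_boundaries",
    "remove_baseline",
    "extract_tap_features",
    "segment",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable thresholds; the defaults suit 15 s sequences at 200 Hz.

    ``search_halfwidth`` is the half-width of the minima search window as a
    fraction of the period; ``closure_tol_frac`` is how far above the running
    closure level (fraction of the typical aperture) a candidate minimum may
    sit and still count as a closure; ``aperture_floor_frac`` merges detected
    taps whose aperture is below this fraction of the median into their
    predecessor.  All of these are the manual-override hooks for difficult
    sequences.
    """

    min_lag_s: float = 0.2
    max_lag_s: float = 3.0
    autocorr_prominence: float = 0.3  # of the zero-lag value
    smooth_frac: float = 1.0 / 8.0  # moving-average width as fraction of period
    search_halfwidth: float = 0.35
    closure_tol_frac: float = 0.30
    aperture_floor_frac: float = 0.25
    min_amplitude_rad: float = np.radians(2.0)
    max_window_extensions: int = 4


def estimate_period(
    theta: np.ndarray, dt: float, config: SegmentationConfig | None = None
) -> float:
    """Average tapping period from the autocorrelation of the angle trace.

    The mean-removed autocorrelation is scanned over lags in
    ``[min_lag_s, max_lag_s]``; the first local maximum exceeding
    ``autocorr_prominence`` of the zero-lag value wins.  Invariant to adding a
    constant and to a sign flip of theta.

    Raises :class:`AperiodicSignalError` when no peak qualifies.
    """
    config = config or SegmentationConfig()
    x = np.asarray(theta, dtype=float)
    if x.shape[0] * dt < 2.0:
        raise AperiodicSignalError("need at least 2 s of signal")
    x = x - x.mean()
    r = np.correlate(x, x, mode="full")[x.shape[0] - 1 :]
    if r[0] <= 0:
        raise AperiodicSignalError("zero-variance signal")
    r = r / r[0]
    lo = max(1, int(round(config.min_lag_s / dt)))
    hi = min(r.shape[0] - 1, int(round(config.max_lag_s / dt)))
    if hi <= lo:
        raise AperiodicSignalError("signal too short for the lag range")
    peaks, _ = find_peaks(r[lo : hi + 1])
    for p in peaks:
        if r[lo + p] >= config.autocorr_prominence:
            return (lo + p) * dt
    raise AperiodicSignalError("no prominent autocorrelation peak in the lag range")


def smooth(theta: np.ndarray, period: float, dt: float, frac: float = 1.0 / 8.0) -> np.ndarray:
    """Centered (zero-phase) moving average with an odd window of
    ``round(period * frac / dt)`` samples; near the edges the window shrinks
    symmetrically instead of padding."""
    x = np.asarray(theta, dtype=float)
    w = int(round(period * frac / dt))
    w = max(w, 1)
    if w % 2 == 0:
        w += 1
    if w == 1:
        return x.copy()
    h = w // 2
    c = np.concatenate([[0.0], np.cumsum(x)])
    n = x.shape[0]
    idx = np.arange(n)
    left = np.maximum(idx - h, 0)
    right = np.minimum(idx + h, n - 1)
    # shrink symmetrically so the window stays centered
    half = np.minimum(idx - left, right - idx)
    lo = idx - half
    hi = idx + half
    return (c[hi + 1] - c[lo]) / (hi - lo + 1)


def _local_minima(x: np.ndarray, lo: int, hi: int, order: int) -> np.ndarray:
    """Indices of local minima of x within [lo, hi), including the array
    endpoints when they fall inside the window (sequences start and end at a
    closure, whose minimum sits on the boundary)."""
    seg = x[lo:hi]
    if seg.shape[0] < 3:
        cands = np.arange(lo, hi)
        return cands
    rel = argrelmin(seg, order=max(order, 1), mode="clip")[0] + lo
    ends = []
    if lo == 0:
        ends.append(0)
    if hi == x.shape[0]:
        ends.append(hi - 1)
    return np.unique(np.concatenate([rel, np.array(ends, dtype=int)])) if ends else rel


def find_tap_boundaries(
    theta: np.ndarray,
    period: float,
    dt: float,
    config: SegmentationConfig | None = None,
    theta_smooth: np.ndarray | None = None,
) -> TapSet:
    """Locate closure minima (tap boundaries) and per-tap opening maxima.

    The average period seeds the walk: from each accepted closure the next is
    searched in a window of +/- ``search_halfwidth`` periods around the
    prediction.  Candidates are local minima of the smoothed trace accepted
    only near the running closure level (tracked with a drift slope through
    the previous anchors); if none qualifies the window extends by whole
    periods, which is what a held-open skip requires.  Accepted minima are
    refined to the minimum of the raw series within half a smoothing window.

    Raises :class:`NoTapsError` for signals without at least two closures or
    with sub-threshold amplitude.
    """
    config = config or SegmentationConfig()
    x = np.asarray(theta, dtype=float)
    n = x.shape[0]
    xs = smooth(x, period, dt, config.smooth_frac) if theta_smooth is None else theta_smooth
    p = period / dt
    hw = config.search_halfwidth * p
    order = max(1, int(round(0.05 * p)))

    # typical per-period amplitude, robust to slow drift
    n_chunks = max(1, int(n // p))
    amps = [
        np.ptp(xs[int(k * p) : int((k + 1) * p) + 1])
        for k in range(n_chunks)
        if int((k + 1) * p) <= n
    ]
    amp = float(np.median(amps)) if amps else float(np.ptp(xs))
    if amp < config.min_amplitude_rad:
        raise NoTapsError("signal amplitude below the minimum tap aperture")
    tol = config.closure_tol_frac * amp

    boundaries: list[int] = []
    # first closure: deepest acceptable minimum in the opening window
    lo, hi = 0, min(n, int(round((1.0 + config.search_halfwidth) * p)) + 1)
    cands = _local_minima(xs, lo, hi, order)
    if cands.size:
        floor0 = xs[lo:hi].min()
        ok = cands[xs[cands] <= floor0 + tol]
        if ok.size:
            # earliest candidate within a small margin of the deepest, so a
            # flat lead-in is preferred over the closure ending the first tap
            good = ok[xs[ok] <= xs[ok].min() + 0.1 * amp]
            boundaries.append(int(good[0]))
    if not boundaries:
        raise NoTapsError("no initial closure found")

    while True:
        m = boundaries[-1]
        if len(boundaries) >= 2:
            m_prev = boundaries[-2]
            slope = (xs[m] - xs[m_prev]) / (m - m_prev)
        else:
            slope = 0.0
        lo = max(int(round(m + p - hw)), m + 1)
        if lo >= n:
            break
        found = None
        # grow the window end by whole periods: a held-open skip shows no
        # closure for several periods, and a cumulative window cannot land
        # out of phase with the closures
        for ext in range(config.max_window_extensions + 1):
            hi = min(int(round(m + (1.0 + ext) * p + hw)) + 1, n)
            cands = _local_minima(xs, lo, hi, order)
            if cands.size:
                base_pred = xs[m] + slope * (cands - m)
                depth = xs[cands] - base_pred
                ok = depth <= tol
                if ok.any():
                    dmin = depth[ok].min()
                    # earliest candidate within a small margin of the deepest
                    good = cands[ok & (depth <= dmin + 0.1 * amp)]
                    found = int(good[0])
                    break
            if hi >= n:
                break
        if found is None:
            break
        boundaries.append(found)

    if len(boundaries) < 2:
        raise NoTapsError("fewer than two closures found")

    # refine on the raw series within half a smoothing window
    w = int(round(period * config.smooth_frac / dt))
    h = max(w // 2, 1)
    refined = []
    for b in boundaries:
        lo = max(b - h, 0)
        hi = min(b + h + 1, n)
        refined.append(lo + int(np.argmin(x[lo:hi])))
    boundaries = sorted(set(refined))

    boundaries = _merge_small_taps(x, xs, boundaries, config)
    if len(boundaries) < 2:
        raise NoTapsError("fewer than two closures after merging")

    maxima = np.array(
        [
            boundaries[k] + int(np.argmax(xs[boundaries[k] : boundaries[k + 1] + 1]))
            for k in range(len(boundaries) - 1)
        ]
    )
    return TapSet(boundaries=np.asarray(boundaries, dtype=int), maxima=maxima)


def _merge_small_taps(
    x: np.ndarray, xs: np.ndarray, boundaries: list[int], config: SegmentationConfig
) -> list[int]:
    """Merge taps whose aperture falls below the floor.

    Interior sub-floor taps (flat-valley artifacts of a held-closed skip) are
    appended to their predecessor; a sub-floor first/last tap is dropped.
    """
    b = list(boundaries)
    while len(b) >= 2:
        aps = np.array([np.ptp(xs[b[k] : b[k + 1] + 1]) for k in range(len(b) - 1)])
        floor = max(config.aperture_floor_frac * float(np.median(aps)),
                    0.5 * config.min_amplitude_rad)
        small = np.flatnonzero(aps < floor)
        if small.size == 0:
            break
        k = int(small[0])
        if k == 0:
            del b[0]
        elif k == len(aps) - 1:
            del b[-1]
        else:
            del b[k]  # merge into the preceding tap
    return b


def remove_baseline(theta: np.ndarray, tapset: TapSet) -> np.ndarray:
    """Subtract the piecewise-linear interpolant through the closure minima.

    Before the first and after the last minimum the nearest anchor value is
    extended, so theta at every boundary becomes exactly zero.
    """
    x = np.asarray(theta, dtype=float)
    b = tapset.boundaries
    if b.size == 0:
        raise NoTapsError("empty tap set")
    idx = np.arange(x.shape[0])
    baseline = np.interp(idx, b, x[b])
    return x - baseline


def extract_tap_features(theta_corrected: np.ndarray, tapset: TapSet, dt: float) -> TapSet:
    """Fill per-tap duration, aperture, and peak opening/closing speeds.

    Aperture is max - min of the baseline-free angle inside the tap; speeds
    are the extrema of the central-difference derivative (opening positive).
    """
    x = np.asarray(theta_corrected, dtype=float)
    v = np.gradient(x, dt)
    b = tapset.boundaries
    k = tapset.n_taps
    duration = np.diff(b) * dt
    aperture = np.empty(k)
    v_open = np.empty(k)
    v_close = np.empty(k)
    for i in range(k):
        seg = x[b[i] : b[i + 1] + 1]
        vseg = v[b[i] : b[i + 1] + 1]
        aperture[i] = np.ptp(seg)
        v_open[i] = vseg.max()
        v_close[i] = vseg.min()
    return TapSet(
        boundaries=b,
        maxima=tapset.maxima,
        duration_s=duration,
        aperture_rad=aperture,
        peak_opening_rad_s=v_open,
        peak_closing_rad_s=v_close,
    )


def segment(
    theta: np.ndarray, dt: float, config: SegmentationConfig | None = None
) -> tuple[TapSet, np.ndarray, float]:
    """Full segmentation chain; returns (tapset with features,
    baseline-corrected theta, period)."""
    config = config or SegmentationConfig()
    period = estimate_period(theta, dt, config)
    tapset = find_tap_boundaries(theta, period, dt, config)
    corrected = remove_baseline(theta, tapset)
    tapset = extract_tap_features(corrected, tapset, dt)
    return tapset, corrected, period
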