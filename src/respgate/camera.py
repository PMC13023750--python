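"""Camera-based respiratory surrogate extraction and temporal alignment.

The camera surrogate is derived from chest video by dividing each frame into
equally sized rectangular patches, scoring each patch's mean-intensity time
series by the fraction of its spectral power inside the breathing band, and
combining the band-dominant patches in a weight-normalized, sign-aligned sum.

Because the camera signal exhibits processing- and physiology-related
latency relative to the self-gating signal, the two surrogates are aligned
by normalized cross-correlation over a bounded lag search before binning.
The delay is modelled as constant over the scan. Both signals are linearly
resampled to the coarser of the two rates; the lag search runs on that
common discrete grid (optional parabolic sub-sample refinement).
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import AlignmentResult, RespiratorySignal, VideoStream
from .self_gating import BREATHING_BAND_HZ, _band_fraction

__all__ = ["extract_camera_signal", "align_signals"]


def extract_camera_signal(
    v: VideoStream,
    patch_grid: tuple = (6, 8),
    band=BREATHING_BAND_HZ,
    weight_floor: float = 0.3,
) -> RespiratorySignal:
    """Derive a respiratory signal from chest video by patch analysis.

    The frame is tiled by ``patch_grid`` (rows, cols) rectangles (remainder
    pixels truncated). Each patch contributes its mean-centered mean-intensity
    series, weighted by its in-band spectral power fraction; patches below
    ``weight_floor`` are dropped. Contributing patches are sign-aligned to the
    highest-weight patch so antiphase patches reinforce rather than cancel.

    Raises if no patch shows respiratory-band motion.
    """
    rows, cols = patch_grid
    n_y, n_x, n_t = v.frames.shape
    if rows < 1 or cols < 1 or rows > n_y or cols > n_x:
        raise ValueError("patch grid must tile the frame")
    ph, pw = n_y // rows, n_x // cols

    series = np.empty((rows * cols, n_t))
    for i in range(rows):
        for j in range(cols):
            patch = v.frames[i * ph : (i + 1) * ph, j * pw : (j + 1) * pw, :]
            series[i * cols + j] = patch.mean(axis=(0, 1))
    series = series - series.mean(axis=1, keepdims=True)

    weights = np.zeros(rows * cols)
    for idx in range(rows * cols):
        sd = series[idx].std()
        if sd > 0:
            frac = _band_fraction(series[idx] / sd, v.frame_rate, band)
            if frac >= weight_floor:
                weights[idx] = frac
    if not np.any(weights > 0):
        raise ValueError("no respiratory motion detected in any patch")

    ref = int(np.argmax(weights))
    out = np.zeros(n_t)
    for idx in np.nonzero(weights)[0]:
        c = float(np.dot(series[idx], series[ref]))
        sign = 1.0 if c >= 0 else -1.0
        out += weights[idx] * sign * series[idx]
    out /= weights.sum()

    t = np.arange(n_t) / v.frame_rate
    return RespiratorySignal(t=t, amplitude=out, rate=v.frame_rate, source="VE")


def _resample_common(x: RespiratorySignal, y: RespiratorySignal):
    """Linear resampling of both signals to the coarser common uniform grid."""
    rate = min(x.rate, y.rate)
    t_lo = max(x.t[0], y.t[0])
    t_hi = min(x.t[-1], y.t[-1])
    if t_hi <= t_lo:
        raise ValueError("signals have no overlapping time support")
    n = int(np.floor((t_hi - t_lo) * rate)) + 1
    grid = t_lo + np.arange(n) / rate
    xa = np.interp(grid, x.t, x.amplitude)
    ya = np.interp(grid, y.t, y.amplitude)
    return grid, xa - xa.mean(), ya - ya.mean(), 1.0 / rate


def _lagged_corr(xa: np.ndarray, ya: np.ndarray, k: int) -> float:
    """Pearson correlation of x(t) with y(t + k dt) over the overlap."""
    if k >= 0:
        xs, ys = xa[: xa.size - k or None], ya[k:]
    else:
        xs, ys = xa[-k:], ya[: ya.size + k]
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    denom = np.sqrt(np.sum(xs**2) * np.sum(ys**2))
    if denom == 0:
        return 0.0
    return float(np.dot(xs, ys) / denom)


def align_signals(
    x: RespiratorySignal,
    y: RespiratorySignal,
    max_lag_ms: float = 5000.0,
    min_overlap_s: float = 10.0,
    refine: bool = False,
) -> AlignmentResult:
    """Estimate the delay of ``y`` relative to ``x`` by normalized cross-correlation.

    Positive delay means ``y`` lags ``x``. The peak is located by the largest
    |correlation| (an inverted surrogate aligns at its anticorrelation peak
    and is flagged for polarity review); the signed peak correlation is
    reported. ``aligned_signal`` is ``y`` advanced by the estimated delay.

    Raises when either signal has (numerically) zero variance or the overlap
    after the extreme lag falls below ``min_overlap_s``; a peak on the search
    boundary attaches a warning.
    """
    if x.amplitude.std() == 0 or y.amplitude.std() == 0:
        raise ValueError("cannot align signals with zero variance")
    grid, xa, ya, dt = _resample_common(x, y)
    k_max = int(np.floor(max_lag_ms / 1000.0 / dt))
    if (grid[-1] - grid[0]) - k_max * dt < min_overlap_s:
        raise ValueError(
            f"overlapping support after a {max_lag_ms} ms lag is below "
            f"{min_overlap_s} s"
        )

    lags = np.arange(-k_max, k_max + 1)
    corr = np.array([_lagged_corr(xa, ya, int(k)) for k in lags])
    best = int(np.argmax(np.abs(corr)))
    peak = float(corr[best])
    delay_s = lags[best] * dt

    if refine and 0 < best < lags.size - 1:
        c0, c1, c2 = np.abs(corr[best - 1 : best + 2])
        denom = c0 - 2 * c1 + c2
        if denom < 0:
            delay_s += 0.5 * (c0 - c2) / denom * dt

    boundary = best in (0, lags.size - 1)
    if boundary:
        warnings.warn("correlation peak on the lag-search boundary", stacklevel=2)
    negative = peak < 0
    if negative:
        warnings.warn(
            "peak correlation is negative: review surrogate polarity", stacklevel=2
        )

    aligned = y.copy(t=y.t - delay_s)
    return AlignmentResult(
        delay_ms=delay_s * 1000.0,
        peak_correlation=peak,
        aligned_signal=aligned,
        search_range_ms=max_lag_ms,
        grid_dt_s=dt,
        boundary_peak=boundary,
        negative_peak=negative,
    )
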