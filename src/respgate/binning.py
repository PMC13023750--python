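"""Retrospective respiratory binning and surrogate-agreement metrics.

Time points are sorted into equally populated respiratory bins by surrogate
amplitude; with the end-expiration-high polarity convention, bin 0 (the
reconstruction target) covers the expiratory plateau and the last bin the
deepest inspiration. Agreement between two gating methods is quantified by
the maximum of the normalized cross-correlation between the surrogates, a
binary classification view of the end-expiratory bin (accuracy, F1), and a
row-normalized bin consistency matrix.

"Equally populated" is implemented as rank terciles with deterministic
remainder placement (extra samples go to the end-expiratory side first) and
ties broken by the earlier time index.
"""

from __future__ import annotations

import warnings

import numpy as np

from .camera import _lagged_corr, _resample_common
from .containers import (
    POLARITY_END_EXP_HIGH,
    AgreementReport,
    BinAssignment,
    RespiratorySignal,
)

__all__ = [
    "assign_bins",
    "max_cross_correlation",
    "classification_metrics",
    "consistency_matrix",
    "agreement_report",
]


def assign_bins(r: RespiratorySignal, n_bins: int = 3) -> BinAssignment:
    """Sort time points into ``n_bins`` equally populated respiratory bins.

    Requires the end-expiration-high polarity convention (see
    ``orient_polarity``). Samples are ranked by amplitude descending (ties:
    earlier time point ranks first); the top block becomes bin 0
    (end-expiration), the bottom block the deepest-inspiration bin. Bin
    populations differ by at most one, with the remainder spread from bin 0
    downward.
    """
    if r.polarity != POLARITY_END_EXP_HIGH:
        raise ValueError(
            "bin assignment requires polarity 'end-expiration-high'; "
            "run orient_polarity first"
        )
    n = r.amplitude.size
    if n < n_bins:
        raise ValueError("need at least n_bins time points")
    order = np.argsort(-r.amplitude, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
    labels = np.empty(n, dtype=int)
    thresholds = []
    pos = 0
    for b, size in enumerate(sizes):
        block = order[pos : pos + size]
        labels[block] = b
        if b < n_bins - 1:
            thresholds.append(float(r.amplitude[block].min()))
        pos += size
    return BinAssignment(
        labels=labels,
        t=r.t,
        thresholds=np.asarray(thresholds),
        counts=np.asarray(sizes),
    )


def max_cross_correlation(
    x: RespiratorySignal, y: RespiratorySignal, max_lag_s: float = 5.0
) -> float:
    """Maximum over lags of the normalized cross-correlation of two surrogates.

    The signals are resampled to their coarser common grid and the Pearson
    correlation of the overlapping segments is maximized over integer lags
    up to ``max_lag_s``. The result lies in [-1, 1] and is invariant to
    positive affine rescaling of either signal.
    """
    if x.amplitude.std() == 0 or y.amplitude.std() == 0:
        raise ValueError("cross-correlation undefined for zero-variance signals")
    _, xa, ya, dt = _resample_common(x, y)
    k_max = min(int(np.floor(max_lag_s / dt)), xa.size - 2)
    corr = [_lagged_corr(xa, ya, int(k)) for k in range(-k_max, k_max + 1)]
    return float(np.max(corr))


def _check_compatible(a: BinAssignment, b: BinAssignment) -> None:
    if a.labels.size != b.labels.size:
        raise ValueError("bin assignments must have equal length")
    if a.n_bins != b.n_bins or a.end_exp_label != b.end_exp_label:
        raise ValueError("bin assignments must share the bin convention")


def classification_metrics(a: BinAssignment, b: BinAssignment):
    """Binary accuracy and F1 of end-expiratory bin assignment.

    The end-expiratory bin is the positive class, the remaining bins the
    negative class; ``a`` is the reference, ``b`` the prediction. F1 is 0
    when no true positive exists but positives were labelled, and 1 when
    neither arm labels any positive (vacuous agreement).
    """
    _check_compatible(a, b)
    pos = a.end_exp_label
    ap = a.labels == pos
    bp = b.labels == pos
    tp = int(np.sum(ap & bp))
    tn = int(np.sum(~ap & ~bp))
    fp = int(np.sum(~ap & bp))
    fn = int(np.sum(ap & ~bp))
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    denom = 2 * tp + fp + fn
    f1 = 1.0 if denom == 0 else 2 * tp / denom
    return accuracy, f1


def consistency_matrix(a: BinAssignment, b: BinAssignment) -> np.ndarray:
    """Row-normalized bin agreement percentages.

    Entry (i, j) is the percentage of reference-bin-i time points that the
    prediction assigned to bin j; each row sums to 100. An empty reference
    bin yields a NaN row and a warning.
    """
    _check_compatible(a, b)
    nb = a.n_bins
    m = np.zeros((nb, nb))
    for i in range(nb):
        sel = a.labels == i
        total = int(sel.sum())
        if total == 0:
            m[i] = np.nan
            warnings.warn(f"reference bin {i} is empty", stacklevel=2)
            continue
        for j in range(nb):
            m[i, j] = 100.0 * np.sum(sel & (b.labels == j)) / total
    return m


def agreement_report(
    x: RespiratorySignal,
    y: RespiratorySignal,
    delay_ms: float = 0.0,
    n_bins: int = 3,
    max_lag_s: float = 5.0,
    reference: str = "SG",
    prediction: str = "VE",
) -> AgreementReport:
    """Full surrogate/bin agreement summary between two gating signals.

    ``x`` is the reference arm, ``y`` the (already aligned) prediction arm.
    Bins are computed independently per surrogate from each signal's own
    amplitude distribution. Both surrogates must be resampled comparisons:
    the bin-level metrics are evaluated on the coarser common time grid.
    """
    grid, xa, ya, dt = _resample_common(x, y)
    rate = 1.0 / dt
    xs = RespiratorySignal(grid, xa, rate, polarity=x.polarity, source=x.source)
    ys = RespiratorySignal(grid, ya, rate, polarity=y.polarity, source=y.source)
    bins_x = assign_bins(xs, n_bins)
    bins_y = assign_bins(ys, n_bins)
    accuracy, f1 = classification_metrics(bins_x, bins_y)
    consistency = consistency_matrix(bins_x, bins_y)
    return AgreementReport(
        cross_correlation=max_cross_correlation(x, y, max_lag_s),
        zero_lag_correlation=_lagged_corr(xa, ya, 0),
        delay_ms=delay_ms,
        accuracy=accuracy,
        f1=f1,
        consistency=consistency,
        n_timepoints=grid.size,
        reference=reference,
        prediction=prediction,
    )
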