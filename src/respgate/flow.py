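"""2D-plane hemodynamics and method-agreement statistics.

An axial slice orthogonal to the vessel is extracted from the 4D velocity
volume, the through-plane velocity is integrated over the vessel lumen to a
volumetric flow curve Q(t) [mL/s], and stroke volume / peak flow are derived
from it. Agreement between gating methods (and against a 2D reference) is
assessed with ordinary least squares correlation, Bland-Altman bias and
limits of agreement, and paired Wilcoxon signed-rank tests.

Plane extraction is axis-aligned nearest-slice; relative Bland-Altman
differences use the mean-of-pair denominator; stroke volume uses rectangular
integration over the uniformly sampled cardiac cycle (trapezoidal optional).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import VelocityField4D, VesselMask

__all__ = [
    "FlowCurve",
    "BlandAltmanResult",
    "CorrelationResult",
    "extract_axial_plane",
    "compute_flow_curve",
    "stroke_volume",
    "peak_flow",
    "bland_altman",
    "correlation_fit",
    "paired_wilcoxon",
]


@dataclass
class FlowCurve:
    """Volumetric flow over the cardiac cycle (mL/s per phase)."""

    phase_times: np.ndarray
    flow: np.ndarray
    rr_interval: float

    def __post_init__(self) -> None:
        self.phase_times = np.asarray(self.phase_times, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.phase_times.shape != self.flow.shape:
            raise ValueError("phase_times and flow lengths must match")
        if self.rr_interval <= 0:
            raise ValueError("rr_interval must be positive")

    @property
    def n_phases(self) -> int:
        return self.flow.size


@dataclass
class BlandAltmanResult:
    """Bias and 1.96-SD limits of agreement of paired differences."""

    bias: float
    loa_low: float
    loa_high: float
    n: int
    relative: bool = False

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")


@dataclass
class CorrelationResult:
    """Ordinary least-squares fit of b on a with coefficient of determination."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        self.r_squared = min(self.r_squared, 1.0)


def extract_axial_plane(
    f: VelocityField4D, m: VesselMask, slice_index: int, axis: int = 2
):
    """Through-plane velocity maps on one slice orthogonal to ``axis``.

    Returns ``(plane_series, plane_mask)`` where ``plane_series`` holds the
    velocity component normal to the slice for every cardiac phase
    (shape: in-plane grid x n_phases) and ``plane_mask`` the vessel mask on
    that slice. Raises if the plane mask is empty.
    """
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    n_slices = f.components.shape[1 + axis]
    if not 0 <= slice_index < n_slices:
        raise ValueError("slice_index outside the grid")
    comp = f.components[axis]
    plane = np.take(comp, slice_index, axis=axis)
    plane_mask = np.take(m.mask, slice_index, axis=axis)
    if not plane_mask.any():
        raise ValueError("vessel mask is empty on the requested slice")
    return plane, plane_mask


def compute_flow_curve(
    plane_series: np.ndarray,
    plane_mask: np.ndarray,
    pixel_area_cm2: float,
    phase_times: np.ndarray,
    rr_interval: float,
) -> FlowCurve:
    """Integrate through-plane velocity over the lumen: Q = sum(v) * area.

    Velocities in cm/s and pixel area in cm^2 give flow in mL/s.
    """
    if pixel_area_cm2 <= 0:
        raise ValueError("pixel_area_cm2 must be positive")
    q = plane_series[plane_mask].sum(axis=0) * pixel_area_cm2
    return FlowCurve(phase_times=phase_times, flow=q, rr_interval=rr_interval)


def stroke_volume(q: FlowCurve, method: str = "rectangular") -> float:
    """Stroke volume in mL: integral of Q over one full cardiac cycle.

    Retrospective gating samples the cycle uniformly, so the default is the
    rectangular rule with dt = RR / n_phases; ``method="trapezoidal"`` closes
    the cycle periodically instead.
    """
    if q.n_phases == 0:
        raise ValueError("empty flow curve")
    dt = q.rr_interval / q.n_phases
    if method == "rectangular":
        return float(np.sum(q.flow) * dt)
    if method == "trapezoidal":
        closed = np.append(q.flow, q.flow[0])
        return float(np.trapezoid(closed, dx=dt))
    raise ValueError(f"unknown integration method {method!r}")


def peak_flow(q: FlowCurve) -> float:
    """Maximum of the flow curve in mL/s."""
    if q.n_phases == 0:
        raise ValueError("empty flow curve")
    return float(np.max(q.flow))


def bland_altman(a, b, relative: bool = False) -> BlandAltmanResult:
    """Bland-Altman bias and limits of agreement of paired values.

    ``relative=True`` uses percentage differences with the mean-of-pair
    denominator: 100 * (a - b) / ((a + b) / 2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1D arrays with n >= 2")
    if relative:
        denom = 0.5 * (a + b)
        if np.any(denom == 0):
            raise ValueError("relative differences undefined where a + b = 0")
        d = 100.0 * (a - b) / denom
    else:
        d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=a.size,
        relative=relative,
    )


def correlation_fit(a, b) -> CorrelationResult:
    """Ordinary least squares of b on a with R^2 = 1 - SS_res / SS_tot."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length arrays with n >= 3")
    if np.var(a) == 0:
        raise ValueError("zero variance in the predictor")
    if np.var(b) == 0:
        # constant response: slope 0 fit explains nothing
        return CorrelationResult(slope=0.0, intercept=float(b.mean()), r_squared=0.0, n=a.size)
    res = stats.linregress(a, b)
    return CorrelationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=a.size,
    )


def paired_wilcoxon(a, b) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon convention). The exact null
    distribution is used for n <= 25 without ties in |differences|; the
    normal approximation with tie correction otherwise. All-zero differences
    return p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("need equal-length arrays")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero: p = 1", stacklevel=2)
        return 1.0
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.pvalue)
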