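"""3D vector-field agreement metrics between two velocity reconstructions.

Given two reconstructions u (reference gating) and v (comparison gating) of
the same acquisition and a binary vessel mask M, the module computes:

* the masked vector RMSE per cardiac phase, averaged over phases;
* the mean directional error over systolic frames,
  mean of 1 - <u_i, v_i> / (|u_i| |v_i|), range [0, 2];
* a pixelwise correlation of velocity magnitudes over all masked voxels and
  phases (slope, intercept, R^2);
* peak velocity via a maximum intensity projection (MIP) of the velocity
  magnitude across the slice dimension at peak systole, followed by a
  sliding-kernel search: among all kernel placements fully inside the 2D
  mask, the placement with the highest mean is selected and the maximum
  pixel inside it is the peak velocity.

Systolic frames are those whose mask-mean velocity magnitude reaches a
configurable fraction (default one half) of the cycle maximum; "peak
systole" is the frame maximizing the mask-mean magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .containers import VelocityField4D, VesselMask
from .flow import CorrelationResult, correlation_fit

__all__ = [
    "velocity_magnitude",
    "rmse_masked",
    "masked_sum_squared_error",
    "mean_directional_error",
    "detect_systolic_frames",
    "mip_map",
    "peak_velocity",
    "PeakVelocityResult",
    "pixelwise_magnitude_correlation",
]


@dataclass
class PeakVelocityResult:
    """Peak velocity and the winning sliding-kernel placement."""

    velpeak: float
    kernel_origin: tuple
    kernel_mean: float

    def __post_init__(self) -> None:
        if self.velpeak < self.kernel_mean - 1e-12:
            raise ValueError("peak velocity cannot be below the kernel mean")


def velocity_magnitude(f: VelocityField4D) -> np.ndarray:
    """Euclidean norm of the velocity vector per voxel and phase (cm/s)."""
    return np.sqrt(np.sum(f.components**2, axis=0))


def _check_pair(u: VelocityField4D, v: VelocityField4D, m: VesselMask) -> None:
    if u.components.shape != v.components.shape:
        raise ValueError("velocity fields must have matching shapes")
    if m.mask.shape != u.grid_shape:
        raise ValueError("mask shape must match the velocity grid")
    if not m.mask.any():
        raise ValueError("vessel mask is empty")


def masked_sum_squared_error(
    u: VelocityField4D, v: VelocityField4D, m: VesselMask
) -> np.ndarray:
    """Raw per-phase sum over masked voxels of squared vector differences."""
    _check_pair(u, v, m)
    diff2 = np.sum((u.components - v.components) ** 2, axis=0)  # (x,y,z,ph)
    return diff2[m.mask].sum(axis=0)


def rmse_masked(u: VelocityField4D, v: VelocityField4D, m: VesselMask) -> float:
    """Masked vector RMSE in cm/s, averaged across cardiac phases.

    Per phase: sqrt(mean over masked voxels of |u_i - v_i|^2), with the
    squared norm over the three vector components; the returned value is the
    mean of the per-phase RMS values.
    """
    _check_pair(u, v, m)
    sse = masked_sum_squared_error(u, v, m)
    per_phase = np.sqrt(sse / m.n_voxels)
    return float(per_phase.mean())


def mean_directional_error(
    u: VelocityField4D,
    v: VelocityField4D,
    m: VesselMask,
    systolic_frames,
    eps: float = None,
) -> float:
    """Mean of 1 - cosine similarity between paired vectors, over systole.

    Voxels where either vector norm is at or below ``eps`` (default 1% of
    the reference venc) are excluded, since direction is undefined for
    near-zero vectors. Returns NaN with a warning if no voxel passes the
    floor in any systolic frame. Range [0, 2]; invariant to positive
    per-voxel rescaling of either field.
    """
    _check_pair(u, v, m)
    frames = np.atleast_1d(np.asarray(systolic_frames, dtype=int))
    if frames.size == 0:
        raise ValueError("systolic_frames must be nonempty")
    if eps is None:
        eps = 0.01 * u.venc
    uu = u.components[:, m.mask, :]  # (3, n_mask, n_phases)
    vv = v.components[:, m.mask, :]
    per_frame = []
    for fr in frames:
        a = uu[:, :, fr]
        b = vv[:, :, fr]
        na = np.linalg.norm(a, axis=0)
        nb = np.linalg.norm(b, axis=0)
        ok = (na > eps) & (nb > eps)
        if not np.any(ok):
            continue
        cos = np.sum(a[:, ok] * b[:, ok], axis=0) / (na[ok] * nb[ok])
        per_frame.append(np.mean(1.0 - cos))
    if not per_frame:
        warnings.warn("no voxel exceeds the norm floor in any systolic frame", stacklevel=2)
        return float("nan")
    return float(np.mean(per_frame))


def detect_systolic_frames(
    f: VelocityField4D, m: VesselMask, threshold_fraction: float = 0.5
) -> np.ndarray:
    """Frames whose mask-mean velocity magnitude reaches the cycle maximum fraction."""
    if m.mask.shape != f.grid_shape:
        raise ValueError("mask shape must match the velocity grid")
    if not m.mask.any():
        raise ValueError("vessel mask is empty")
    mean_mag = velocity_magnitude(f)[m.mask].mean(axis=0)
    return np.nonzero(mean_mag >= threshold_fraction * mean_mag.max())[0]


def mip_map(velmag: np.ndarray, m: VesselMask, axis: int = 2):
    """Masked maximum intensity projection across the slice dimension.

    ``velmag`` is a 3D scalar field (one cardiac phase). Per in-plane
    position the maximum is taken over masked voxels only; positions with no
    masked voxel are excluded from the returned 2D mask (and set to NaN in
    the map).
    """
    if velmag.shape != m.mask.shape:
        raise ValueError("velmag and mask shapes must match")
    if not m.mask.any():
        raise ValueError("vessel mask is empty")
    masked = np.where(m.mask, velmag, -np.inf)
    mip = masked.max(axis=axis)
    mask2d = m.mask.any(axis=axis)
    mip = np.where(mask2d, mip, np.nan)
    return mip, mask2d


def peak_velocity(
    mip: np.ndarray, mask2d: np.ndarray, kernel: int = 4
) -> PeakVelocityResult:
    """Sliding-kernel peak-velocity extraction on a masked MIP map.

    Among all ``kernel x kernel`` placements whose pixels are all inside the
    2D mask, the placement with the highest mean velocity is selected (ties
    broken by the smallest row-major origin) and the maximum pixel inside
    that kernel is returned as the peak velocity.
    """
    if mip.shape != mask2d.shape:
        raise ValueError("mip and mask shapes must match")
    if kernel < 1 or kernel > min(mip.shape):
        raise ValueError("kernel does not fit inside the map")
    win_vals = sliding_window_view(np.where(mask2d, mip, 0.0), (kernel, kernel))
    win_mask = sliding_window_view(mask2d, (kernel, kernel))
    valid = win_mask.all(axis=(2, 3))
    if not valid.any():
        raise ValueError(
            "no fully masked kernel placement: use a smaller kernel size"
        )
    means = win_vals.mean(axis=(2, 3))
    means = np.where(valid, means, -np.inf)
    flat = int(np.argmax(means))  # ties -> smallest row-major origin
    i, j = np.unravel_index(flat, means.shape)
    return PeakVelocityResult(
        velpeak=float(win_vals[i, j].max()),
        kernel_origin=(int(i), int(j)),
        kernel_mean=float(means[i, j]),
    )


def pixelwise_magnitude_correlation(
    u: VelocityField4D, v: VelocityField4D, m: VesselMask
) -> CorrelationResult:
    """OLS fit of v-magnitude on u-magnitude over all masked voxels and phases."""
    _check_pair(u, v, m)
    umag = velocity_magnitude(u)[m.mask].ravel()
    vmag = velocity_magnitude(v)[m.mask].ravel()
    return correlation_fit(umag, vmag)
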