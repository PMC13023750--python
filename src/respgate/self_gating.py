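"""Respiratory surrogate extraction from k-space-center profile streams.

The self-gating chain is: inverse Fourier transform of each coil's profile
stream along the readout axis, magnitude, sum-of-squares (SOS) combination
across coils, PCA over time, and selection of the principal component with
the largest fraction of spectral power inside the expected breathing band
(0.1-0.7 Hz by default).

PCA orientation: observations are time points and variables are spatial
positions, so the surrogate is the temporal score series of the selected
component. Scores are normalized to unit variance before the spectral
comparison so the selection statistic (in-band power fraction) is
scale-invariant and does not simply favor the first component. The PCA sign
indeterminacy is resolved only by :func:`orient_polarity`, never inside the
extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import PCA

from .containers import (
    POLARITY_END_EXP_HIGH,
    POLARITY_UNKNOWN,
    ProfileStream,
    ProjectionMatrix,
    RespiratorySignal,
)

__all__ = [
    "profiles_to_projection",
    "extract_respiratory_component",
    "orient_polarity",
    "ComponentDiagnostics",
    "BREATHING_BAND_HZ",
]

BREATHING_BAND_HZ = (0.1, 0.7)


def profiles_to_projection(s: ProfileStream) -> ProjectionMatrix:
    """Inverse-FT each coil profile and combine by sum of squares.

    Uses the centered orthonormal inverse FFT along the k-space axis, takes
    magnitudes, and returns ``X_sos = sqrt(sum_c |X_c|^2)``. An all-zero
    stream yields an all-zero projection (flagged with a warning).
    """
    x = np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(s.profiles, axes=1), axis=1, norm="ortho"),
        axes=1,
    )
    xsos = np.sqrt(np.sum(np.abs(x) ** 2, axis=0))
    if not np.any(xsos > 0):
        warnings.warn("all-zero profile stream: projection is identically zero", stacklevel=2)
    dx = s.fov_mm / s.n_kx
    x_mm = (np.arange(s.n_kx) + 0.5) * dx
    return ProjectionMatrix(xsos=xsos, x_mm=x_mm, t_s=s.times)


@dataclass
class ComponentDiagnostics:
    """Per-component diagnostics of the band-power selection."""

    chosen_index: int
    band_hz: tuple
    band_fraction: np.ndarray
    explained_variance_ratio: np.ndarray
    transposed_band_fraction: np.ndarray
    low_band_power: bool = False


def _band_fraction(series: np.ndarray, rate: float, band) -> float:
    """Fraction of Welch spectral power inside the band (Hann, 50% overlap)."""
    nperseg = min(series.size, 512)
    f, p = sps.welch(series, fs=rate, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    total = p.sum()
    if total <= 0:
        return 0.0
    sel = (f >= band[0]) & (f <= band[1])
    return float(p[sel].sum() / total)


def extract_respiratory_component(
    x: ProjectionMatrix,
    band=BREATHING_BAND_HZ,
    n_components: int = 10,
    band_fraction_floor: float = 0.2,
):
    """Select the respiratory surrogate among the leading PCA components.

    Rows (spatial positions) are mean-centered over time, PCA is computed
    with time points as observations, the temporal scores are normalized to
    unit variance, and the component maximizing the in-band fraction of
    Welch spectral power is returned as the surrogate (polarity unknown).

    Returns ``(signal, diagnostics)``. Raises if the projection has no
    temporal variance or the band is not resolvable at the sampling rate; a
    winning band fraction below ``band_fraction_floor`` attaches a warning.
    """
    n_x, n_t = x.xsos.shape
    rate = x.rate
    if not 0.0 < band[0] < band[1] < rate / 2.0:
        raise ValueError("band must lie within (0, rate/2)")
    if n_t <= 2 * n_components:
        raise ValueError("need n_t > 2 * n_components time points")

    data = x.xsos.T  # observations = time points, variables = positions
    data = data - data.mean(axis=0, keepdims=True)
    total_var = float(np.sum(data**2))
    if total_var <= 1e-12 * max(1.0, float(np.sum(x.xsos**2))):
        raise ValueError("projection has no temporal variance: no respiratory component")

    k = min(n_components, n_x, n_t - 1)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(data)  # (n_t, k)

    band_fracs = np.zeros(k)
    for j in range(k):
        s = scores[:, j]
        sd = s.std()
        if sd > 0:
            band_fracs[j] = _band_fraction(s / sd, rate, band)
    chosen = int(np.argmax(band_fracs))

    # audit of the transposed interpretation: observations = spatial
    # positions, variables = time points; the principal axes are temporal
    alt = x.xsos - x.xsos.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(alt, full_matrices=False)
    alt_fracs = np.array([_band_fraction(vt[j], rate, band) for j in range(min(k, vt.shape[0]))])

    diag = ComponentDiagnostics(
        chosen_index=chosen,
        band_hz=tuple(band),
        band_fraction=band_fracs,
        explained_variance_ratio=pca.explained_variance_ratio_,
        transposed_band_fraction=alt_fracs,
    )
    if band_fracs[chosen] < band_fraction_floor:
        diag.low_band_power = True
        warnings.warn(
            f"winning band-power fraction {band_fracs[chosen]:.3f} below floor "
            f"{band_fraction_floor}: surrogate may not be respiratory",
            stacklevel=2,
        )

    s = scores[:, chosen]
    s = s / s.std()
    sig = RespiratorySignal(
        t=x.t_s, amplitude=s, rate=rate, polarity=POLARITY_UNKNOWN, source="SG"
    )
    return sig, diag


def orient_polarity(r: RespiratorySignal, min_duration_s: float = 30.0) -> RespiratorySignal:
    """Fix the surrogate sign so the end-expiratory plateau sits high.

    End-expiration is the most occupied respiratory state, so the half of
    the amplitude range holding more samples is taken as the plateau; the
    sign is chosen to place it at the high end. Idempotent. A (near-)
    balanced occupancy keeps the sign and flags ambiguity with a warning.
    """
    if r.duration < min_duration_s:
        raise ValueError(f"need at least {min_duration_s} s of signal to orient polarity")
    a = r.amplitude
    mid = 0.5 * (a.max() + a.min())
    n_hi = int(np.sum(a > mid))
    n_lo = int(np.sum(a < mid))
    if abs(n_hi - n_lo) <= max(1, int(0.01 * a.size)):
        warnings.warn(
            "amplitude histogram is balanced: end-expiratory polarity is ambiguous, "
            "keeping sign",
            stacklevel=2,
        )
        return r.copy(polarity=POLARITY_END_EXP_HIGH)
    if n_hi > n_lo:
        return r.copy(polarity=POLARITY_END_EXP_HIGH)
    return r.copy(amplitude=-a, polarity=POLARITY_END_EXP_HIGH)
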