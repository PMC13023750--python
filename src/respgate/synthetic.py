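"""Seeded generators for every input the gating-comparison pipeline consumes.

The generators stand in for free-breathing volunteer acquisitions with known
ground truth:

* a quasi-periodic plateaued breathing waveform (cosine-power, Lujan-type)
  whose dominant frequency lies in the physiological 0.1-0.7 Hz band and
  whose end-expiratory plateau is the most occupied amplitude state;
* a 1D superior-inferior tissue phantom (lung / myocardium / liver / fat)
  whose heart-liver interface translates with the waveform, sampled to
  multi-coil k-space-center profiles with complex Gaussian noise;
* a delayed, rescaled, noisy camera surrogate and an optional synthetic chest
  video with one breathing-modulated patch;
* paired pulsatile cylindrical-vessel velocity fields with a controlled
  Gaussian perturbation injected between the two "reconstructions", plus the
  analytic flow curve, stroke volume and peak velocity.

All generators are reproducible: the same seed yields bit-identical output.
Coordinates are 0-based, the superior-inferior axis is array axis 0, and
positions are in mm from the field-of-view edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    POLARITY_END_EXP_HIGH,
    ProfileStream,
    RespiratorySignal,
    VelocityField4D,
    VesselMask,
    VideoStream,
)
from .gre_signal import SequenceParams, TissueParams, default_tissue_table, steady_state_signal

__all__ = [
    "BreathingParams",
    "PhantomGeometry",
    "CoilModel",
    "VelocityPhantomParams",
    "generate_breathing_waveform",
    "generate_profile_stream",
    "generate_camera_signal",
    "generate_chest_video",
    "generate_velocity_phantom",
    "default_sequence",
    "default_tissues",
]

#: profile interval of the k-space-center navigator, seconds (45 ms -> 22 Hz)
DEFAULT_PROFILE_DT = 0.045


@dataclass(frozen=True)
class BreathingParams:
    """Plateaued cosine-power breathing model parameters.

    Within cycle k the interface position is

        z(t) = z0 - A_k * cos(pi * (t - t_k) / T_k) ** (2 n) + drift,

    so the signal rests near the baseline ``z0`` (end-expiratory plateau) and
    dips by the cycle amplitude ``A_k`` at the cycle edges (inspiration).
    Cycle periods and amplitudes are jittered per cycle; ``drift_rate`` adds a
    slow linear baseline drift.
    """

    z0: float = 180.0  # mm, baseline interface position
    amplitude: float = 12.0  # mm, peak-to-plateau excursion
    period: float = 4.0  # s
    shape_exponent: int = 2  # plateau sharpness n (cos^(2n))
    period_jitter_sd: float = 0.25  # s
    amplitude_jitter_sd: float = 1.0  # mm
    drift_rate: float = 0.5  # mm/min
    duration: float = 240.0  # s
    rate: float = 1.0 / DEFAULT_PROFILE_DT  # Hz

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.period <= 0 or self.rate <= 0 or self.duration <= 0:
            raise ValueError("period, rate and duration must be positive")
        if self.shape_exponent < 1:
            raise ValueError("shape_exponent must be >= 1")
        if not 0.0 < 1.0 / self.period < self.rate / 2.0:
            raise ValueError(
                "dominant breathing frequency 1/period must lie in (0, rate/2)"
            )


def generate_breathing_waveform(p: BreathingParams, seed):
    """Generate a ground-truth breathing waveform.

    Returns
    -------
    signal : RespiratorySignal
        Interface position in mm; polarity is end-expiration-high by
        construction (plateau at ``z0``).
    annotations : dict
        Ground-truth cycle starts, periods and amplitudes plus the drift
        term, for oracle use in tests.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(round(p.duration * p.rate)) / p.rate
    # draw jittered cycles until they cover the duration
    starts, periods, amps = [], [], []
    t_k = 0.0
    while t_k < p.duration:
        T_k = p.period
        if p.period_jitter_sd > 0:
            T_k = rng.normal(p.period, p.period_jitter_sd)
        T_k = max(T_k, 0.5 * p.period)
        A_k = p.amplitude
        if p.amplitude_jitter_sd > 0:
            A_k = rng.normal(p.amplitude, p.amplitude_jitter_sd)
        A_k = max(A_k, 0.0)
        starts.append(t_k)
        periods.append(T_k)
        amps.append(A_k)
        t_k += T_k
    starts_arr = np.asarray(starts)
    periods_arr = np.asarray(periods)
    amps_arr = np.asarray(amps)

    idx = np.searchsorted(starts_arr, t, side="right") - 1
    phase = np.pi * (t - starts_arr[idx]) / periods_arr[idx]
    z = p.z0 - amps_arr[idx] * np.cos(phase) ** (2 * p.shape_exponent)
    z = z + p.drift_rate / 60.0 * t

    signal = RespiratorySignal(
        t=t, amplitude=z, rate=p.rate, polarity=POLARITY_END_EXP_HIGH, source="ground-truth"
    )
    annotations = {
        "cycle_starts_s": starts_arr,
        "cycle_periods_s": periods_arr,
        "cycle_amplitudes_mm": amps_arr,
        "drift_mm_per_min": p.drift_rate,
    }
    return signal, annotations


@dataclass(frozen=True)
class PhantomGeometry:
    """1D superior-inferior tissue layout.

    ``blocks`` are ordered ``(name, start_mm, end_mm)`` segments tiling the
    FOV; ``moving_interface`` is the index of the block boundary that
    translates with breathing (the boundary between ``blocks[i-1]`` and
    ``blocks[i]``, counting boundaries from 0 at the FOV edge). With
    ``heart_coupling`` > 0 the preceding boundary (the lung edge of the
    heart) translates along with it, so the heart block shifts rigidly
    rather than stretching — the superior-inferior translation that makes
    projection-based self-gating work in the first place.
    """

    fov: float = 360.0  # mm
    n_x: int = 144
    blocks: tuple = (
        ("lung", 0.0, 140.0),
        ("myocardium", 140.0, 180.0),
        ("liver", 180.0, 260.0),
        ("fat", 260.0, 360.0),
    )
    moving_interface: int = 2  # myocardium-liver boundary
    heart_coupling: float = 1.0  # lung-edge displacement per interface mm

    def __post_init__(self) -> None:
        if self.n_x < 2 or self.fov <= 0:
            raise ValueError("need n_x >= 2 and positive fov")
        prev_end = 0.0
        for name, lo, hi in self.blocks:
            if not np.isclose(lo, prev_end) or hi <= lo:
                raise ValueError("blocks must tile the FOV without overlap")
            prev_end = hi
        if not np.isclose(prev_end, self.fov):
            raise ValueError("blocks must end at the FOV edge")
        if not 1 <= self.moving_interface <= len(self.blocks) - 1:
            raise ValueError("moving_interface must be an interior boundary index")

    @property
    def dx(self) -> float:
        return self.fov / self.n_x

    @property
    def boundaries(self) -> np.ndarray:
        return np.array([self.blocks[0][1]] + [b[2] for b in self.blocks])

    @property
    def interface_baseline_mm(self) -> float:
        return float(self.blocks[self.moving_interface - 1][2])


@dataclass(frozen=True)
class CoilModel:
    """Gaussian receive-coil sensitivity profiles along the SI axis."""

    centers_mm: tuple
    widths_mm: tuple
    gains: tuple

    def __post_init__(self) -> None:
        if len(self.centers_mm) < 1:
            raise ValueError("need at least one coil")
        if not (len(self.centers_mm) == len(self.widths_mm) == len(self.gains)):
            raise ValueError("coil parameter lengths must match")
        if any(w <= 0 for w in self.widths_mm):
            raise ValueError("coil widths must be positive")

    @property
    def n_coils(self) -> int:
        return len(self.centers_mm)

    @classmethod
    def default(cls, fov: float = 360.0, n_coils: int = 32, width: float = 60.0):
        centers = (np.arange(n_coils) + 0.5) / n_coils * fov
        return cls(
            centers_mm=tuple(centers),
            widths_mm=(width,) * n_coils,
            gains=(1.0,) * n_coils,
        )

    def sensitivities(self, x_mm: np.ndarray) -> np.ndarray:
        """Sensitivity array of shape (n_coils, n_x)."""
        c = np.asarray(self.centers_mm)[:, None]
        w = np.asarray(self.widths_mm)[:, None]
        g = np.asarray(self.gains)[:, None]
        return g * np.exp(-((x_mm[None, :] - c) ** 2) / (2.0 * w**2))


def default_sequence(b0: float = 0.6, flip: float = 15.0) -> SequenceParams:
    """Protocol sequence parameters (TR 5.9 ms, TE 3.5 ms, 15 degrees)."""
    return SequenceParams(tr=5.9, te=3.5, flip_angle=flip, b0=b0)


def default_tissues(field_t: float = 0.6) -> dict:
    """Bundled tissue parameters at the requested field strength."""
    return default_tissue_table()[field_t]


def _density_profile(
    g: PhantomGeometry, intensities: dict, interface_mm: np.ndarray
) -> np.ndarray:
    """Tissue intensity profile rho(x, t) with sub-pixel partial volume.

    ``interface_mm`` is the moving-boundary position per time point; the
    remaining boundaries are static.
    """
    n_t = interface_mm.size
    edges_lo = np.arange(g.n_x) * g.dx
    edges_hi = edges_lo + g.dx
    rho = np.zeros((g.n_x, n_t))
    base = g.boundaries  # (n_blocks + 1,)
    mi = g.moving_interface
    disp = interface_mm - base[mi]
    bounds = np.repeat(base[:, None], n_t, axis=1)
    bounds[mi] = interface_mm
    bounds[mi - 1] = base[mi - 1] + g.heart_coupling * disp
    for j, (name, _, _) in enumerate(g.blocks):
        lo, hi = bounds[j], bounds[j + 1]
        # coverage fraction of each pixel by [lo, hi)
        overlap = np.minimum(edges_hi[:, None], hi[None, :]) - np.maximum(
            edges_lo[:, None], lo[None, :]
        )
        rho += intensities[name] * np.clip(overlap / g.dx, 0.0, 1.0)
    return rho


def generate_profile_stream(
    w: RespiratorySignal,
    g: PhantomGeometry = None,
    coils: CoilModel = None,
    seq: SequenceParams = None,
    tissues: dict = None,
    snr: float = np.inf,
    seed=None,
) -> ProfileStream:
    """Sample the moving 1D phantom to multi-coil k-space-center profiles.

    For each time point the tissue profile is built with intensities from the
    spoiled-GRE signal model, the myocardium-liver interface is shifted to
    the waveform position, each coil weights the profile by its sensitivity,
    and the product is Fourier transformed along x (orthonormal FFT, so
    Parseval holds exactly). Complex white Gaussian noise is added with
    SD = |S(k0)| / snr, where |S(k0)| is the mean over coils of the noiseless
    k-space-center magnitude of the static (baseline-position) phantom.

    The waveform amplitude is interpreted as the interface position in mm and
    must stay inside the two blocks adjacent to the moving boundary.
    """
    g = g or PhantomGeometry()
    coils = coils or CoilModel.default(fov=g.fov)
    seq = seq or default_sequence()
    tissues = tissues or default_tissues(seq.b0)
    if not np.isinf(snr) and snr <= 0:
        raise ValueError("snr must be positive (or inf for noiseless)")

    interface = np.asarray(w.amplitude, dtype=float)
    base = g.boundaries
    mi = g.moving_interface
    disp = interface - base[mi]
    lung_edge = base[mi - 1] + g.heart_coupling * disp
    lower_lim = base[mi - 2] if mi >= 2 else 0.0
    if (
        interface.max() >= base[mi + 1]
        or np.any(lung_edge >= interface)
        or lung_edge.min() < lower_lim
    ):
        raise ValueError("interface excursion leaves the adjacent tissue blocks")

    intensities = {
        name: steady_state_signal(seq, tissues[name]) for name, _, _ in g.blocks
    }
    x_mm = (np.arange(g.n_x) + 0.5) * g.dx
    sens = coils.sensitivities(x_mm)  # (n_coils, n_x)

    rho = _density_profile(g, intensities, interface)  # (n_x, n_t)

    sigma = 0.0
    rng = None
    if not np.isinf(snr):
        rng = np.random.default_rng(seed)
        static = _density_profile(
            g, intensities, np.full(1, g.interface_baseline_mm)
        )[:, 0]
        static_k = np.fft.fftshift(
            np.fft.fft(np.fft.ifftshift(sens * static[None, :], axes=1), axis=1, norm="ortho"),
            axes=1,
        )
        k0 = g.n_x // 2
        sigma = float(np.mean(np.abs(static_k[:, k0]))) / snr

    # per-coil loop keeps peak memory at one coil's profile block
    s = np.empty((coils.n_coils, g.n_x, rho.shape[1]), dtype=complex)
    for c in range(coils.n_coils):
        sc = np.fft.fftshift(
            np.fft.fft(np.fft.ifftshift(sens[c, :, None] * rho, axes=0), axis=0, norm="ortho"),
            axes=0,
        )
        if sigma > 0:
            sc = sc + rng.normal(scale=sigma / np.sqrt(2.0), size=sc.shape)
            sc = sc + 1j * rng.normal(scale=sigma / np.sqrt(2.0), size=sc.shape)
        s[c] = sc

    return ProfileStream(profiles=s, dt=w.dt, kx_spacing=1.0 / g.fov, t0=float(w.t[0]))


def generate_camera_signal(
    w: RespiratorySignal,
    delay_ms: float = 500.0,
    gain: float = 1.0,
    offset: float = 0.0,
    noise_sd: float = 0.0,
    camera_rate: float = 30.0,
    seed=None,
) -> RespiratorySignal:
    """Camera surrogate: a delayed, rescaled, noisy copy of the waveform.

    ``y(t) = gain * w(t - delay) + offset + noise`` resampled to
    ``camera_rate`` by linear interpolation (edge values clamped). A
    positive delay means the camera signal lags the waveform.
    """
    if camera_rate <= 0:
        raise ValueError("camera_rate must be positive")
    rng = np.random.default_rng(seed)
    t_cam = w.t[0] + np.arange(int(np.floor(w.duration * camera_rate)) + 1) / camera_rate
    y = gain * np.interp(t_cam - delay_ms / 1000.0, w.t, w.amplitude) + offset
    if noise_sd > 0:
        y = y + rng.normal(scale=noise_sd, size=y.size)
    return RespiratorySignal(t=t_cam, amplitude=y, rate=camera_rate, source="VE")


def generate_chest_video(
    w: RespiratorySignal,
    frame_shape: tuple = (48, 64),
    patch: tuple = (8, 16, 16, 24),  # (row0, row1, col0, col1)
    frame_rate: float = 30.0,
    modulation: float = 1.0,
    noise_sd: float = 0.05,
    seed=None,
) -> VideoStream:
    """Synthetic chest video with one breathing-modulated rectangular patch.

    The patch's intensity is an affine function of the waveform (normalized
    to unit SD); the remainder of the frame is a static texture plus
    per-frame white noise.
    """
    r0, r1, c0, c1 = patch
    n_y, n_x = frame_shape
    if not (0 <= r0 < r1 <= n_y and 0 <= c0 < c1 <= n_x):
        raise ValueError("moving patch must lie inside the frame")
    rng = np.random.default_rng(seed)
    t_v = w.t[0] + np.arange(int(np.floor(w.duration * frame_rate)) + 1) / frame_rate
    wv = np.interp(t_v, w.t, w.amplitude)
    sd = wv.std()
    wv = (wv - wv.mean()) / sd if sd > 0 else wv * 0.0

    texture = rng.uniform(0.0, 1.0, size=(n_y, n_x))
    frames = np.repeat(texture[:, :, None], t_v.size, axis=2)
    frames[r0:r1, c0:c1, :] += modulation * wv[None, None, :]
    if noise_sd > 0:
        frames = frames + rng.normal(scale=noise_sd, size=frames.shape)
    return VideoStream(frames=frames, frame_rate=frame_rate)


@dataclass(frozen=True)
class VelocityPhantomParams:
    """Paired pulsatile cylindrical-vessel velocity phantom parameters.

    The vessel is axis-aligned (``axis``, default z) with a parabolic
    cross-sectional profile and a separable raised-sine systolic waveform
    ``h(t) = sin^2(pi t / t_sys)`` for ``t < t_sys = systolic_fraction * rr``
    and 0 in diastole. Field B equals field A plus an independent Gaussian
    perturbation of SD ``perturbation_sd`` inside the mask, emulating the
    discrepancy between two retrospective reconstructions.
    """

    grid_shape: tuple = (32, 32, 16)
    voxel_mm: float = 2.5
    axis: int = 2
    radius_mm: float = 15.0
    v_peak: float = 100.0  # cm/s centerline peak systolic velocity
    n_phases: int = 24
    rr_interval: float = 1.0  # s
    systolic_fraction: float = 0.35
    noise_sd: float = 0.0  # cm/s, added to both fields everywhere
    perturbation_sd: float = 2.25  # cm/s, injected between A and B in mask
    venc: float = 150.0  # cm/s

    def __post_init__(self) -> None:
        if self.radius_mm < 2 * self.voxel_mm:
            raise ValueError("vessel radius must be at least 2 voxels")
        if self.n_phases < 2:
            raise ValueError("need n_phases >= 2")
        if not 0 < self.v_peak <= self.venc:
            raise ValueError("need 0 < v_peak <= venc")
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")
        nx, ny, nz = self.grid_shape
        plane = [nx, ny, nz]
        plane.pop(self.axis)
        if self.radius_mm > 0.5 * self.voxel_mm * (min(plane) - 1):
            raise ValueError("vessel does not fit inside the grid")


def _cardiac_waveform(p: VelocityPhantomParams) -> np.ndarray:
    t = np.arange(p.n_phases) * p.rr_interval / p.n_phases
    t_sys = p.systolic_fraction * p.rr_interval
    h = np.where(t < t_sys, np.sin(np.pi * t / t_sys) ** 2, 0.0)
    return h


def generate_velocity_phantom(p: VelocityPhantomParams, seed):
    """Generate a paired velocity phantom with analytic ground truth.

    Returns
    -------
    field_a, field_b : VelocityField4D
        Two "reconstructions"; B = A + Gaussian perturbation inside the mask.
    mask : VesselMask
    truth : dict
        ``flow_curve_mls`` (analytic Q(t) = pi R^2 v_peak h(t) / 2),
        ``stroke_volume_ml``, ``peak_velocity_cms``, ``h`` and
        ``phase_times_s``.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = p.grid_shape
    coords = [np.arange(n) * p.voxel_mm for n in (nx, ny, nz)]
    centers = [(n - 1) / 2.0 * p.voxel_mm for n in (nx, ny, nz)]
    in_plane = [i for i in range(3) if i != p.axis]
    mesh = np.meshgrid(*coords, indexing="ij")
    r2 = sum((mesh[i] - centers[i]) ** 2 for i in in_plane)
    mask = r2 <= p.radius_mm**2

    h = _cardiac_waveform(p)
    phase_times = np.arange(p.n_phases) * p.rr_interval / p.n_phases
    profile = np.where(mask, p.v_peak * (1.0 - r2 / p.radius_mm**2), 0.0)

    comps = np.zeros((3, nx, ny, nz, p.n_phases))
    comps[p.axis] = profile[..., None] * h[None, None, None, :]
    if p.noise_sd > 0:
        comps = comps + rng.normal(scale=p.noise_sd, size=comps.shape)

    comps_b = comps.copy()
    if p.perturbation_sd > 0:
        pert = rng.normal(scale=p.perturbation_sd, size=comps.shape)
        comps_b = comps_b + pert * mask[None, :, :, :, None]

    voxel = (p.voxel_mm,) * 3
    field_a = VelocityField4D(comps, voxel, p.venc, phase_times)
    field_b = VelocityField4D(comps_b, voxel, p.venc, phase_times)

    r_cm = p.radius_mm / 10.0
    q = np.pi * r_cm**2 * p.v_peak * h / 2.0  # mL/s
    truth = {
        "flow_curve_mls": q,
        "stroke_volume_ml": float(np.sum(q) * p.rr_interval / p.n_phases),
        "peak_velocity_cms": float(p.v_peak * h.max()),
        "h": h,
        "phase_times_s": phase_times,
    }
    return field_a, field_b, VesselMask(mask), truth
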