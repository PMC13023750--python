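"""Core data containers and file I/O.

The pipeline passes a small set of typed containers between stages:

* :class:`ProfileStream` — multi-coil complex k-space-center profiles over
  time, the raw material of self-gating.
* :class:`ProjectionMatrix` — the coil-combined 1D projection of the excited
  volume over time.
* :class:`RespiratorySignal` — a uniformly sampled surrogate amplitude series
  with an explicit polarity convention (whether end-expiration sits at the
  high end of the amplitude axis).
* :class:`VideoStream` — a grayscale chest video used to derive the
  camera-based surrogate.
* :class:`VelocityField4D` / :class:`VesselMask` — three-component velocity
  over space and cardiac phase with a binary vessel segmentation.
* :class:`BinAssignment` / :class:`AgreementReport` — respiratory bin labels
  and the surrogate-agreement summary.

Array containers are serialized to HDF5 (h5py), masks optionally to NIfTI
(nibabel), signals and bin labels to two-column CSV.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "POLARITY_UNKNOWN",
    "POLARITY_END_EXP_HIGH",
    "RespiratorySignal",
    "ProfileStream",
    "ProjectionMatrix",
    "VideoStream",
    "VelocityField4D",
    "VesselMask",
    "BinAssignment",
    "AlignmentResult",
    "AgreementReport",
    "read_signal_csv",
    "write_signal_csv",
    "read_profile_stream",
    "write_profile_stream",
    "read_velocity_field",
    "write_velocity_field",
    "read_video",
    "write_video",
    "read_mask",
    "write_mask",
]

POLARITY_UNKNOWN = "unknown"
POLARITY_END_EXP_HIGH = "end-expiration-high"


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class RespiratorySignal:
    """Uniformly sampled respiratory surrogate amplitude series.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing and uniform.
    amplitude : array of float
        Surrogate amplitude, arbitrary units (mm for ground-truth waveforms).
    rate : float
        Sampling rate in Hz (must equal ``1 / median(diff(t))``).
    polarity : str
        Either ``"unknown"`` or ``"end-expiration-high"``.
    source : str
        Provenance tag: ``"SG"``, ``"VE"``, ``"ground-truth"`` or free text.
    """

    t: np.ndarray
    amplitude: np.ndarray
    rate: float
    polarity: str = POLARITY_UNKNOWN
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        self.amplitude = _as_float_array(self.amplitude, "amplitude")
        if self.t.ndim != 1 or self.t.shape != self.amplitude.shape:
            raise ValueError("t and amplitude must be 1D arrays of equal length")
        if self.t.size < 2:
            raise ValueError("signal needs at least two samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("t must be strictly increasing")
        if np.max(np.abs(dt - dt.mean())) > 1e-6 * max(dt.mean(), 1e-12):
            raise ValueError("t must be uniformly sampled (1e-6 relative)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def n(self) -> int:
        return self.t.size

    def copy(self, **updates) -> "RespiratorySignal":
        kwargs = dataclasses.asdict(self)
        kwargs.update(updates)
        return RespiratorySignal(**kwargs)


@dataclass
class ProfileStream:
    """Multi-coil complex k-space-center profiles over time.

    ``profiles`` has shape ``(n_coils, n_kx, n_t)``; profiles are spaced
    ``dt`` seconds apart. ``kx_spacing`` is the k-space sample spacing in
    cycles/mm (the reciprocal of the field of view).
    """

    profiles: np.ndarray
    dt: float
    kx_spacing: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=complex)
        if self.profiles.ndim != 3:
            raise ValueError("profiles must have shape (n_coils, n_kx, n_t)")
        n_coils, n_kx, _ = self.profiles.shape
        if n_coils < 1 or n_kx < 2:
            raise ValueError("need n_coils >= 1 and n_kx >= 2")
        if self.dt <= 0 or self.kx_spacing <= 0:
            raise ValueError("dt and kx_spacing must be positive")
        if not np.all(np.isfinite(self.profiles)):
            raise ValueError("profiles must be finite")

    @property
    def n_coils(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_kx(self) -> int:
        return self.profiles.shape[1]

    @property
    def n_t(self) -> int:
        return self.profiles.shape[2]

    @property
    def rate(self) -> float:
        return 1.0 / self.dt

    @property
    def fov_mm(self) -> float:
        return 1.0 / self.kx_spacing

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_t) * self.dt


@dataclass
class ProjectionMatrix:
    """Sum-of-squares combined projection magnitude over space and time."""

    xsos: np.ndarray
    x_mm: np.ndarray
    t_s: np.ndarray

    def __post_init__(self) -> None:
        self.xsos = _as_float_array(self.xsos, "xsos")
        self.x_mm = _as_float_array(self.x_mm, "x_mm")
        self.t_s = _as_float_array(self.t_s, "t_s")
        if self.xsos.ndim != 2:
            raise ValueError("xsos must be 2D (n_x, n_t)")
        if self.xsos.shape != (self.x_mm.size, self.t_s.size):
            raise ValueError("xsos shape must match coordinate lengths")
        if np.any(self.xsos < 0):
            raise ValueError("xsos entries must be non-negative")

    @property
    def rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.t_s)))


@dataclass
class VideoStream:
    """Grayscale video as a ``(n_y, n_x, n_t)`` array at ``frame_rate`` Hz."""

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = _as_float_array(self.frames, "frames")
        if self.frames.ndim != 3 or self.frames.shape[2] < 2:
            raise ValueError("frames must be (n_y, n_x, n_t) with n_t >= 2")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_t(self) -> int:
        return self.frames.shape[2]


@dataclass
class VelocityField4D:
    """Three-component velocity field over space and cardiac phase.

    ``components`` has shape ``(3, n_x, n_y, n_z, n_phases)`` in cm/s,
    ordered (vx, vy, vz). ``voxel_mm`` is the voxel edge length triplet in mm
    and ``venc`` the velocity-encoding limit in cm/s; values beyond twice the
    venc are physically implausible and trigger a warning.
    """

    components: np.ndarray
    voxel_mm: tuple
    venc: float
    phase_times: np.ndarray

    def __post_init__(self) -> None:
        self.components = _as_float_array(self.components, "components")
        if self.components.ndim != 5 or self.components.shape[0] != 3:
            raise ValueError("components must be (3, n_x, n_y, n_z, n_phases)")
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm must be three positive lengths")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        self.phase_times = _as_float_array(self.phase_times, "phase_times")
        if self.phase_times.size != self.components.shape[4]:
            raise ValueError("phase_times length must match n_phases")
        vmax = float(np.max(np.abs(self.components)))
        if vmax > 2.0 * self.venc:
            warnings.warn(
                f"velocity magnitude {vmax:.1f} cm/s exceeds 2*venc "
                f"({2 * self.venc:.1f} cm/s)",
                stacklevel=2,
            )

    @property
    def n_phases(self) -> int:
        return self.components.shape[4]

    @property
    def grid_shape(self) -> tuple:
        return self.components.shape[1:4]


@dataclass
class VesselMask:
    """Binary vessel segmentation over the spatial grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (n_x, n_y, n_z)")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class BinAssignment:
    """Per-timepoint respiratory bin labels.

    Labels run from 0 (end-expiration) to ``n_bins - 1`` (deepest
    inspiration). ``thresholds`` are the amplitude cut points separating
    adjacent bins, ordered from the end-expiratory side downward.
    """

    labels: np.ndarray
    t: np.ndarray
    thresholds: np.ndarray
    counts: np.ndarray
    end_exp_label: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.t = _as_float_array(self.t, "t")
        self.thresholds = _as_float_array(self.thresholds, "thresholds")
        self.counts = np.asarray(self.counts, dtype=int)
        if self.labels.shape != self.t.shape:
            raise ValueError("labels and t must have equal length")

    @property
    def n_bins(self) -> int:
        return self.counts.size


@dataclass
class AlignmentResult:
    """Outcome of normalized-cross-correlation alignment of two surrogates."""

    delay_ms: float
    peak_correlation: float
    aligned_signal: RespiratorySignal
    search_range_ms: float
    grid_dt_s: float
    boundary_peak: bool = False
    negative_peak: bool = False

    def to_json_dict(self) -> dict:
        return {
            "delay_ms": self.delay_ms,
            "peak_correlation": self.peak_correlation,
            "search_range_ms": self.search_range_ms,
            "grid_dt_s": self.grid_dt_s,
            "boundary_peak": self.boundary_peak,
            "negative_peak": self.negative_peak,
        }


@dataclass
class AgreementReport:
    """Surrogate- and bin-level agreement summary between two gating methods."""

    cross_correlation: float
    zero_lag_correlation: float
    delay_ms: float
    accuracy: float
    f1: float
    consistency: np.ndarray
    n_timepoints: int
    reference: str = "SG"
    prediction: str = "VE"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.consistency = np.asarray(self.consistency, dtype=float)
        rows = np.nansum(self.consistency, axis=1)
        valid = ~np.all(np.isnan(self.consistency), axis=1)
        if np.any(np.abs(rows[valid] - 100.0) > 1e-6):
            raise ValueError("consistency rows must sum to 100%")
        for name in ("accuracy", "f1"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_json_dict(self) -> dict:
        return {
            "cross_correlation": self.cross_correlation,
            "zero_lag_correlation": self.zero_lag_correlation,
            "delay_ms": self.delay_ms,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "consistency_pct": self.consistency.tolist(),
            "n_timepoints": self.n_timepoints,
            "reference": self.reference,
            "prediction": self.prediction,
            **self.extras,
        }

    def to_text(self) -> str:
        lines = [
            f"reference={self.reference} prediction={self.prediction} "
            f"n={self.n_timepoints}",
            f"max cross-correlation : {self.cross_correlation:8.4f}",
            f"zero-lag correlation  : {self.zero_lag_correlation:8.4f}",
            f"delay [ms]            : {self.delay_ms:8.1f}",
            f"accuracy              : {self.accuracy:8.4f}",
            f"F1-score              : {self.f1:8.4f}",
            "consistency matrix [% of reference bin]:",
        ]
        for i, row in enumerate(self.consistency):
            cells = "  ".join(f"{v:6.2f}" for v in row)
            lines.append(f"  bin {i}: {cells}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def write_signal_csv(sig: RespiratorySignal, path) -> None:
    df = pd.DataFrame({"time_s": sig.t, "amplitude": sig.amplitude})
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={sig.rate} polarity={sig.polarity} source={sig.source}\n")
        df.to_csv(fh, index=False)


def read_signal_csv(path) -> RespiratorySignal:
    meta = {"rate_hz": None, "polarity": POLARITY_UNKNOWN, "source": "unknown"}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    t = df["time_s"].to_numpy()
    rate = float(meta["rate_hz"]) if meta["rate_hz"] else 1.0 / float(np.median(np.diff(t)))
    return RespiratorySignal(
        t=t,
        amplitude=df["amplitude"].to_numpy(),
        rate=rate,
        polarity=str(meta["polarity"]),
        source=str(meta["source"]),
    )


def write_profile_stream(stream: ProfileStream, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("profiles", data=stream.profiles)
        h5.create_dataset("dt_s", data=stream.dt)
        h5.create_dataset("kx_spacing", data=stream.kx_spacing)
        h5.create_dataset("t0_s", data=stream.t0)


def read_profile_stream(path) -> ProfileStream:
    with h5py.File(path, "r") as h5:
        return ProfileStream(
            profiles=h5["profiles"][...],
            dt=float(h5["dt_s"][()]),
            kx_spacing=float(h5["kx_spacing"][()]),
            t0=float(h5["t0_s"][()]) if "t0_s" in h5 else 0.0,
        )


def write_velocity_field(f: VelocityField4D, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("vx", data=f.components[0])
        h5.create_dataset("vy", data=f.components[1])
        h5.create_dataset("vz", data=f.components[2])
        h5.create_dataset("voxel_mm", data=np.asarray(f.voxel_mm))
        h5.create_dataset("venc", data=f.venc)
        h5.create_dataset("phase_times_s", data=f.phase_times)


def read_velocity_field(path) -> VelocityField4D:
    with h5py.File(path, "r") as h5:
        comps = np.stack([h5["vx"][...], h5["vy"][...], h5["vz"][...]])
        return VelocityField4D(
            components=comps,
            voxel_mm=tuple(h5["voxel_mm"][...]),
            venc=float(h5["venc"][()]),
            phase_times=h5["phase_times_s"][...],
        )


def write_video(v: VideoStream, path) -> None:
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("frames", data=v.frames)
        ds.attrs["frame_rate"] = v.frame_rate


def read_video(path) -> VideoStream:
    with h5py.File(path, "r") as h5:
        return VideoStream(
            frames=h5["frames"][...],
            frame_rate=float(h5["frames"].attrs["frame_rate"]),
        )


def write_mask(m: VesselMask, path) -> None:
    """Write a vessel mask; `.nii`/`.nii.gz` go through nibabel, else HDF5."""
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.Nifti1Image(m.mask.astype(np.uint8), affine=np.eye(4))
        nib.save(img, path)
    else:
        with h5py.File(path, "w") as h5:
            h5.create_dataset("mask", data=m.mask.astype(np.uint8))


def read_mask(path) -> VesselMask:
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        return VesselMask(mask=np.asanyarray(nib.load(path).dataobj) > 0)
    with h5py.File(path, "r") as h5:
        return VesselMask(mask=h5["mask"][...] > 0)


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
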