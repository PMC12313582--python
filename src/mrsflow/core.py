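"""Core domain types and spectral conventions.

Everything downstream (simulation, processing nodes, I/O) shares the
conventions fixed here:

* Time-domain is canonical.  A :class:`TransientSet` holds complex FIDs
  indexed ``[transient, channel, point]``; nodes consume and produce it.
* The frequency axis is centred on the transmitter (carrier) frequency and
  stored **descending** in Hz so that the derived ppm axis decreases
  left-to-right, the standard NMR plotting convention.
* ``ppm[i] = hz[i] / f0 + ref_ppm`` where ``f0`` is the transmitter
  frequency in MHz (so Hz / MHz = ppm) and ``ref_ppm`` is the chemical
  shift assigned to the carrier (4.7 ppm for water-centred proton
  acquisitions, 0.0 for phosphorus).
* The forward transform is a plain (non-unitary) DFT, centre-shifted so
  the carrier lands on bin ``n // 2`` of the unreversed axis.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AxisError",
    "TransientSet",
    "Spectrum",
    "CsiGrid",
    "AlignmentResult",
    "QualityMetrics",
    "DEFAULT_REF_PPM",
    "default_ref_ppm",
    "build_axes",
    "fid_to_spectrum",
    "spectrum_to_fid",
    "ppm_to_index",
    "index_to_ppm",
]

NUCLEI = ("1H", "31P", "13C", "2H")

#: Chemical shift assigned to the carrier frequency when the acquisition
#: does not specify one.  Water-centred proton studies put the carrier on
#: water (4.7 ppm); X-nuclei conventions reference the carrier itself.
DEFAULT_REF_PPM = {"1H": 4.7, "31P": 0.0, "13C": 0.0, "2H": 4.7}

ROLES = ("metabolite", "water_reference")


class AxisError(ValueError):
    """Raised for inconsistent axis parameters (dwell, f0, n_points)."""


def default_ref_ppm(nucleus: str) -> float:
    return DEFAULT_REF_PPM.get(nucleus, 0.0)


def build_axes(n_points: int, dwell_time: float, f0: float, ref_ppm: float):
    """Frequency axes for an ``n_points`` FID sampled every ``dwell_time`` s.

    Returns ``(hz_axis, ppm_axis)``.  The raw DFT frequencies
    ``(k - n//2) / (n * dwell)`` are reversed so both axes decrease with
    index; for even ``n`` the centre bin is ``k = n/2`` (half-open
    convention), for odd ``n`` it is ``(n - 1) / 2``, matching a centre-
    shifted DFT in either case.
    """
    if n_points < 2:
        raise AxisError(f"n_points must be >= 2, got {n_points}")
    if dwell_time <= 0:
        raise AxisError(f"dwell_time must be positive, got {dwell_time}")
    if f0 <= 0:
        raise AxisError(f"f0 must be positive, got {f0}")
    k = np.arange(n_points)
    hz = (k - n_points // 2) / (n_points * dwell_time)
    hz = hz[::-1].copy()
    ppm = hz / f0 + ref_ppm
    return hz, ppm


@dataclass
class TransientSet:
    """A set of complex time-domain acquisitions sharing one axis.

    Parameters
    ----------
    data
        Complex samples ``[transient, channel, point]``.  The channel axis
        has length 1 after coil combination.
    dwell_time
        Sampling interval in seconds per point.
    f0
        Transmitter frequency in MHz.
    nucleus
        One of ``1H``, ``31P``, ``13C``, ``2H``.
    ref_ppm
        Chemical shift at the carrier; defaults per nucleus.
    role
        ``metabolite`` or ``water_reference``.
    acq_meta
        Free-form acquisition metadata (TE ms, TR ms, sequence, voxel
        dimensions mm, block tags ...).
    """

    data: np.ndarray
    dwell_time: float
    f0: float
    nucleus: str = "1H"
    ref_ppm: float | None = None
    role: str = "metabolite"
    acq_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 3:
            raise ValueError(
                "data must be [transient, channel, point], "
                f"got ndim={self.data.ndim}"
            )
        if self.data.shape[-1] < 2:
            raise AxisError("n_points must be >= 2")
        if self.dwell_time <= 0:
            raise AxisError("dwell_time must be positive")
        if self.f0 <= 0:
            raise AxisError("f0 must be positive")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.ref_ppm is None:
            self.ref_ppm = default_ref_ppm(self.nucleus)

    # -- shape accessors -------------------------------------------------
    @property
    def n_transients(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_points(self) -> int:
        return self.data.shape[2]

    @property
    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dwell_time

    def axes(self):
        return build_axes(self.n_points, self.dwell_time, self.f0, self.ref_ppm)

    @property
    def hz_axis(self) -> np.ndarray:
        return self.axes()[0]

    @property
    def ppm_axis(self) -> np.ndarray:
        return self.axes()[1]

    def replace(self, **kw) -> "TransientSet":
        """Copy with selected fields replaced; data is never aliased."""
        if "data" not in kw:
            kw["data"] = self.data.copy()
        if "acq_meta" not in kw:
            kw["acq_meta"] = dict(self.acq_meta)
        return dataclasses.replace(self, **kw)


@dataclass
class Spectrum:
    """Frequency-domain view of a single transient (single channel)."""

    values: np.ndarray
    ppm_axis: np.ndarray
    hz_axis: np.ndarray
    f0: float
    ref_ppm: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.complex128)
        if not (len(self.values) == len(self.ppm_axis) == len(self.hz_axis)):
            raise ValueError("values/ppm_axis/hz_axis length mismatch")
        if np.any(np.diff(self.ppm_axis) >= 0):
            raise ValueError("ppm_axis must be strictly decreasing")

    def __len__(self):
        return len(self.values)


@dataclass
class AlignmentResult:
    """Per-transient frequency (Hz) and phase (degrees) corrections."""

    freq_shifts: np.ndarray
    phase_shifts: np.ndarray

    def __post_init__(self):
        self.freq_shifts = np.asarray(self.freq_shifts, dtype=float)
        self.phase_shifts = np.asarray(self.phase_shifts, dtype=float)
        if self.freq_shifts.shape != self.phase_shifts.shape:
            raise ValueError("freq_shifts and phase_shifts must align")
        if not (np.all(np.isfinite(self.freq_shifts))
                and np.all(np.isfinite(self.phase_shifts))):
            raise ValueError("alignment shifts must be finite")


@dataclass
class QualityMetrics:
    """SNR of the metabolite spectrum and water linewidth."""

    snr: float
    fwhm_hz: float
    fwhm_ppm: float

    def __post_init__(self):
        if self.snr < 0:
            raise ValueError("snr must be >= 0")


@dataclass
class CsiGrid:
    """3D spatial grid of FIDs, in image space or k-space.

    ``data`` is indexed ``[x, y, z, point]``.  In k-space state the DC
    component sits at the centre index ``dim // 2`` along each spatial
    axis (centre-shifted spatial DFT).
    """

    data: np.ndarray
    dwell_time: float
    f0: float
    nucleus: str = "31P"
    ref_ppm: float | None = None
    space: str = "image"
    fov_mm: tuple = (200.0, 200.0, 80.0)
    acq_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 4:
            raise ValueError("CsiGrid data must be [x, y, z, point]")
        if self.space not in ("image", "k"):
            raise ValueError("space must be 'image' or 'k'")
        if self.ref_ppm is None:
            self.ref_ppm = default_ref_ppm(self.nucleus)

    @property
    def matrix(self):
        return self.data.shape[:3]

    @property
    def n_points(self) -> int:
        return self.data.shape[3]

    def to_kspace(self) -> "CsiGrid":
        if self.space == "k":
            return self
        k = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(
            self.data, axes=(0, 1, 2)), axes=(0, 1, 2)), axes=(0, 1, 2))
        return dataclasses.replace(self, data=k, space="k")

    def to_image(self) -> "CsiGrid":
        if self.space == "image":
            return self
        img = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(
            self.data, axes=(0, 1, 2)), axes=(0, 1, 2)), axes=(0, 1, 2))
        return dataclasses.replace(self, data=img, space="image")

    def voxel_transient_set(self, x: int, y: int, z: int) -> TransientSet:
        """Single-voxel view as a one-transient TransientSet."""
        if self.space != "image":
            raise ValueError("voxel extraction requires image space")
        return TransientSet(
            data=self.data[x, y, z][None, None, :],
            dwell_time=self.dwell_time,
            f0=self.f0,
            nucleus=self.nucleus,
            ref_ppm=self.ref_ppm,
            acq_meta={**self.acq_meta, "voxel_index": (x, y, z)},
        )


# -- transforms ----------------------------------------------------------

def fid_to_spectrum(ts: TransientSet, transient: int = 0) -> Spectrum:
    """Centre-shifted DFT of one FID, on the :func:`build_axes` grid.

    Requires single-channel data (combine coils first).
    """
    if ts.n_channels != 1:
        raise ValueError("multi-channel data: combine coils before transforming")
    if not (0 <= transient < ts.n_transients):
        raise IndexError(f"transient {transient} out of range")
    fid = ts.data[transient, 0]
    values = np.fft.fftshift(np.fft.fft(fid))[::-1]
    hz, ppm = ts.axes()
    return Spectrum(values=values, ppm_axis=ppm, hz_axis=hz,
                    f0=ts.f0, ref_ppm=ts.ref_ppm)


def spectrum_to_fid(spec: Spectrum) -> np.ndarray:
    """Inverse of :func:`fid_to_spectrum`; returns the complex FID."""
    return np.fft.ifft(np.fft.ifftshift(spec.values[::-1]))


def spectra_matrix(ts: TransientSet) -> np.ndarray:
    """All transients transformed at once; rows match the descending axes."""
    if ts.n_channels != 1:
        raise ValueError("multi-channel data: combine coils before transforming")
    s = np.fft.fftshift(np.fft.fft(ts.data[:, 0, :], axis=-1), axes=-1)
    return s[:, ::-1]


def ppm_to_index(ppm_axis: np.ndarray, ppm: float) -> int:
    """Nearest axis index for a chemical shift value."""
    return int(np.argmin(np.abs(np.asarray(ppm_axis) - ppm)))


def index_to_ppm(ppm_axis: np.ndarray, k: int) -> float:
    return float(ppm_axis[k])


def ppm_window_mask(ppm_axis: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Boolean mask selecting ``lo <= ppm <= hi`` (order-insensitive)."""
    lo, hi = min(lo, hi), max(lo, hi)
    mask = (ppm_axis >= lo) & (ppm_axis <= hi)
    if not mask.any():
        raise AxisError(f"ppm window [{lo}, {hi}] outside axis "
                        f"[{ppm_axis.min():.2f}, {ppm_axis.max():.2f}]")
    return mask
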