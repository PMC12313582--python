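"""Deterministic synthetic acquisition generator.

Produces every input shape the pipelines consume — multi-channel
single-voxel transient sets, functional block designs, phosphorus
spectra and 3D CSI grids — from a single generative description
(:class:`SimConfig`), with no external data.

The lineshape model is a Lorentzian-Gaussian (Voigt-like) decay chosen
so the *spectral* full widths at half maximum equal the configured
values exactly:

* Lorentzian component: ``exp(-pi * fwhm_L * t)``
* Gaussian component:  ``exp(-(pi * fwhm_G * t)**2 / (4 ln 2))``

Corruptions emulate what in-vivo acquisitions suffer: linear frequency
drift across transients (scanner heating / subject motion), per-transient
phase jitter, an exponentially decaying eddy-current phase shared with
the water reference, and a small number of outlier ("motion-corrupted")
transients modelled as an amplitude gain plus a large phase excursion.

One global seed is expanded into independent substreams per corruption
(noise, jitter) so enabling one corruption never perturbs the draws of
another.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import CsiGrid, TransientSet, default_ref_ppm

__all__ = ["Peak", "SimConfig", "simulate_transients",
           "simulate_water_reference", "simulate_csi", "ellipsoid_map"]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class Peak:
    """One resonance: position (ppm), amplitude, lineshape, phase."""

    ppm: float
    amplitude: float
    lorentz_fwhm_hz: float = 5.0
    gauss_fwhm_hz: float = 0.0
    phase_deg: float = 0.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be >= 0")
        if self.lorentz_fwhm_hz < 0 or self.gauss_fwhm_hz < 0:
            raise ValueError("linewidths must be >= 0")


@dataclass
class SimConfig:
    """Full generative description of a synthetic acquisition.

    ``noise_sigma`` is the standard deviation of the real and of the
    imaginary part of each complex time-domain sample, per channel.
    ``block_design`` is ``(block_len, multipliers)`` where ``multipliers``
    is a sequence of per-peak amplitude-multiplier tuples, cycled over
    blocks of ``block_len`` consecutive transients — the mechanism that
    emulates task/rest modulation in functional MRS.
    """

    peaks: list = field(default_factory=list)
    n_transients: int = 32
    n_channels: int = 1
    channel_sensitivities: tuple | None = None
    noise_sigma: float = 0.0
    freq_drift_hz_per_transient: float = 0.0
    phase_jitter_deg_sd: float = 0.0
    eddy_amp_rad: float = 0.0
    eddy_decay_s: float = 0.1
    outlier_indices: tuple = ()
    outlier_gain: float = 1.0
    outlier_phase_deg: float = 120.0
    block_design: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.channel_sensitivities is None:
            self.channel_sensitivities = tuple([1.0 + 0j] * self.n_channels)
        self.channel_sensitivities = tuple(
            complex(s) for s in self.channel_sensitivities)
        if len(self.channel_sensitivities) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_sensitivities)} sensitivities for "
                f"{self.n_channels} channels")
        for idx in self.outlier_indices:
            if not (0 <= idx < self.n_transients):
                raise ValueError(f"outlier index {idx} out of range")

    def substreams(self):
        """Independent RNGs per corruption: (noise, jitter, spare)."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(np.random.default_rng(c) for c in children)


def _peak_amplitude(cfg: SimConfig, peak_idx: int, transient: int) -> float:
    peak = cfg.peaks[peak_idx]
    amp = peak.amplitude
    if cfg.block_design is not None:
        block_len, multipliers = cfg.block_design
        block = transient // int(block_len)
        mult = multipliers[block % len(multipliers)]
        amp *= float(mult[peak_idx])
    return amp


def _envelope(peak: Peak, t: np.ndarray) -> np.ndarray:
    env = np.exp(-np.pi * peak.lorentz_fwhm_hz * t)
    if peak.gauss_fwhm_hz > 0:
        env = env * np.exp(-((np.pi * peak.gauss_fwhm_hz * t) ** 2)
                           / (4.0 * _LN2))
    return env


def simulate_transients(cfg: SimConfig, n_points: int = 4096,
                        dwell: float = 1.0 / 4000.0, f0: float = 297.2,
                        nucleus: str = "1H", ref_ppm: float | None = None,
                        role: str = "metabolite") -> TransientSet:
    """Generate a multi-transient, multi-channel FID set.

    Deterministic for a fixed ``(cfg, cfg.seed)``.
    """
    if ref_ppm is None:
        ref_ppm = default_ref_ppm(nucleus)
    rng_noise, rng_jitter, _ = cfg.substreams()
    t = np.arange(n_points) * dwell

    jitter = np.zeros(cfg.n_transients)
    if cfg.phase_jitter_deg_sd > 0:
        jitter = rng_jitter.normal(
            0.0, np.deg2rad(cfg.phase_jitter_deg_sd), cfg.n_transients)

    eddy = np.ones(n_points, dtype=complex)
    if cfg.eddy_amp_rad != 0.0:
        eddy = np.exp(1j * cfg.eddy_amp_rad * np.exp(-t / cfg.eddy_decay_s))

    base = np.zeros((cfg.n_transients, n_points), dtype=complex)
    for ti in range(cfg.n_transients):
        sig = np.zeros(n_points, dtype=complex)
        for pi, peak in enumerate(cfg.peaks):
            f_hz = (peak.ppm - ref_ppm) * f0 + \
                cfg.freq_drift_hz_per_transient * ti
            amp = _peak_amplitude(cfg, pi, ti)
            sig += amp * _envelope(peak, t) * np.exp(
                1j * (2 * np.pi * f_hz * t + np.deg2rad(peak.phase_deg)
                      + jitter[ti]))
        sig *= eddy
        if ti in cfg.outlier_indices:
            sig = sig * cfg.outlier_gain * np.exp(
                1j * np.deg2rad(cfg.outlier_phase_deg))
        base[ti] = sig

    sens = np.asarray(cfg.channel_sensitivities)
    data = base[:, None, :] * sens[None, :, None]
    if cfg.noise_sigma > 0:
        shape = (cfg.n_transients, cfg.n_channels, n_points)
        data = data + cfg.noise_sigma * (
            rng_noise.standard_normal(shape)
            + 1j * rng_noise.standard_normal(shape))
    return TransientSet(data=data, dwell_time=dwell, f0=f0, nucleus=nucleus,
                        ref_ppm=ref_ppm, role=role,
                        acq_meta={"simulated": True, "seed": cfg.seed})


def simulate_water_reference(cfg: SimConfig, n_points: int = 4096,
                             dwell: float = 1.0 / 4000.0, f0: float = 297.2,
                             nucleus: str = "1H",
                             ref_ppm: float | None = None,
                             water_amplitude: float = 100.0,
                             water_fwhm_hz: float = 10.0) -> TransientSet:
    """Unsuppressed-water companion to a metabolite simulation.

    A single dominant resonance at the carrier, sharing the eddy-current
    phase and channel sensitivities of ``cfg`` so that Klose correction
    and water-driven coil combination behave as they would on a paired
    in-vivo acquisition.  Drift, jitter, outliers and block design are
    not applied (water references are acquired separately and briefly).
    """
    if ref_ppm is None:
        ref_ppm = default_ref_ppm(nucleus)
    water_cfg = dataclasses.replace(
        cfg,
        peaks=[Peak(ppm=ref_ppm, amplitude=water_amplitude,
                    lorentz_fwhm_hz=water_fwhm_hz)],
        freq_drift_hz_per_transient=0.0,
        phase_jitter_deg_sd=0.0,
        outlier_indices=(),
        block_design=None,
    )
    return simulate_transients(water_cfg, n_points=n_points, dwell=dwell,
                               f0=f0, nucleus=nucleus, ref_ppm=ref_ppm,
                               role="water_reference")


def ellipsoid_map(matrix: tuple, semi_axes_frac=(0.4, 0.4, 0.4),
                  amplitude: float = 1.0) -> np.ndarray:
    """Centered-ellipsoid amplitude map — a crude 'brain' for CSI tests."""
    nx, ny, nz = matrix
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = (max(f * n, 0.5) for f, n in zip(semi_axes_frac, matrix))
    r2 = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    return np.where(r2 <= 1.0, amplitude, 0.0)


def simulate_csi(cfg: SimConfig, matrix: tuple = (16, 16, 8),
                 fov_mm: tuple = (200.0, 200.0, 80.0),
                 amplitude_map: np.ndarray | None = None,
                 n_points: int = 1024, dwell: float = 1.0 / 6000.0,
                 f0: float = 120.7, nucleus: str = "31P",
                 ref_ppm: float | None = None,
                 to_kspace: bool = False) -> CsiGrid:
    """Image-space CSI grid whose per-voxel FIDs scale a shared lineshape.

    ``amplitude_map`` (shape == matrix) sets the per-voxel signal
    amplitude; by default a centered ellipsoid.  Noise is drawn i.i.d.
    per voxel sample from the config's noise substream.
    """
    if any(m < 1 for m in matrix):
        raise ValueError("matrix dims must be >= 1")
    if ref_ppm is None:
        ref_ppm = default_ref_ppm(nucleus)
    if amplitude_map is None:
        amplitude_map = ellipsoid_map(matrix)
    amplitude_map = np.asarray(amplitude_map, dtype=float)
    if amplitude_map.shape != tuple(matrix):
        raise ValueError(
            f"amplitude map shape {amplitude_map.shape} != matrix {matrix}")

    single = dataclasses.replace(cfg, n_transients=1, n_channels=1,
                                 channel_sensitivities=(1.0,),
                                 noise_sigma=0.0, outlier_indices=())
    base = simulate_transients(single, n_points=n_points, dwell=dwell,
                               f0=f0, nucleus=nucleus,
                               ref_ppm=ref_ppm).data[0, 0]
    data = amplitude_map[..., None] * base[None, None, None, :]
    if cfg.noise_sigma > 0:
        rng_noise, _, _ = cfg.substreams()
        shape = data.shape
        data = data + cfg.noise_sigma * (
            rng_noise.standard_normal(shape)
            + 1j * rng_noise.standard_normal(shape))
    grid = CsiGrid(data=data, dwell_time=dwell, f0=f0, nucleus=nucleus,
                   ref_ppm=ref_ppm, space="image", fov_mm=tuple(fov_mm),
                   acq_meta={"simulated": True, "seed": cfg.seed})
    return grid.to_kspace() if to_kspace else grid
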