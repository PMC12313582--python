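"""Processing operations: coil combination, alignment, eddy-current
correction, outlier rejection, apodization, zero filling, averaging
modes, quality metrics, CSI k-space filtering and phasing tools.

Every operation maps ``TransientSet -> TransientSet`` (or produces
metrics) and is deterministic given its inputs and parameters; the
pipeline engine wraps each one as a registrable node.
"""
from __future__ import annotations

import datetime
import warnings

import numpy as np
from scipy import optimize, signal

from .core import (AlignmentResult, CsiGrid, QualityMetrics, Spectrum,
                   TransientSet, fid_to_spectrum, ppm_window_mask,
                   spectra_matrix, spectrum_to_fid)

__all__ = [
    "coil_combine", "align_frequency_phase", "eddy_current_correct",
    "remove_bad_averages", "apodize", "zero_fill", "average_all",
    "blocked_average", "moving_average", "quality_metrics",
    "hanning_filter_3d", "entropy_min_phase", "manual_adjust",
    "AdjustmentLog", "estimate_peak_frequency",
]

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# Coil combination
# ---------------------------------------------------------------------------

def _channel_noise_std(ref: TransientSet, tail_frac: float = 0.10):
    """Per-channel noise std from the final ``tail_frac`` of FID samples."""
    n_tail = max(2, int(round(tail_frac * ref.n_points)))
    tail = ref.data[:, :, -n_tail:]
    comps = np.concatenate([tail.real, tail.imag], axis=-1)
    return comps.reshape(-1, ref.n_channels, comps.shape[-1]).std(
        axis=(0, 2), ddof=0)


def coil_combine(ts: TransientSet, method: str = "adaptive",
                 water_ref: TransientSet | None = None):
    """Combine receiver channels into one, maximizing SNR.

    Methods
    -------
    ``snr2``
        Signal/noise-squared weighting: ``w_c ∝ conj(S_c) / sigma_c**2``
        with ``S_c`` the first time point of the mean reference FID and
        ``sigma_c`` the channel noise std from the FID tail.
    ``svd``
        Weights are the conjugate of the first left singular vector of
        the reference channel x time matrix.
    ``adaptive``
        Weights maximize the generalized Rayleigh quotient
        ``w† R_s w / w† R_n w`` with the signal covariance built from the
        leading 5% of FID samples and the noise covariance from the tail.

    The reference is the water acquisition when supplied, otherwise the
    input set itself.  Weights are unit-norm and globally phased so the
    combined reference FID starts real-positive.  Returns
    ``(combined TransientSet, weights)``; the same weights should be
    applied to the paired water set.
    """
    if method not in ("adaptive", "snr2", "svd"):
        raise ValueError(f"unknown coil combination method {method!r}")
    ref = water_ref if water_ref is not None else ts
    if ref.n_channels != ts.n_channels:
        raise ValueError("reference channel count differs from input")
    if ts.n_channels == 1:
        w = np.ones(1, dtype=complex)
        out = ts.replace(data=ts.data.copy())
        out.acq_meta["coil_weights"] = w
        return out, w

    mean_ref = ref.data.mean(axis=0)  # [channel, point]
    first = mean_ref[:, 0]
    dead = np.abs(first) < 1e3 * np.finfo(float).eps * np.abs(first).max()
    if dead.any():
        warnings.warn(f"zero-signal channels {np.nonzero(dead)[0].tolist()} "
                      "assigned zero weight")

    if method == "snr2":
        sigma = _channel_noise_std(ref)
        sigma = np.where(sigma > 0, sigma, np.median(sigma[sigma > 0])
                         if (sigma > 0).any() else 1.0)
        w = np.conj(first) / sigma ** 2
    elif method == "svd":
        u, _, _ = np.linalg.svd(mean_ref, full_matrices=False)
        w = np.conj(u[:, 0])
    else:  # adaptive
        n_lead = max(1, int(round(0.05 * ref.n_points)))
        n_tail = max(2, int(round(0.10 * ref.n_points)))
        lead = mean_ref[:, :n_lead]
        tail = ref.data[:, :, -n_tail:].transpose(1, 0, 2).reshape(
            ref.n_channels, -1)
        r_s = lead @ lead.conj().T / lead.shape[1]
        r_n = tail @ tail.conj().T / tail.shape[1]
        # regularize so noiseless fixtures keep R_n invertible
        r_n = r_n + 1e-12 * max(np.trace(r_s).real, 1.0) * np.eye(
            ref.n_channels)
        from scipy.linalg import eigh
        vals, vecs = eigh(r_s, r_n)
        w = vecs[:, -1]

    w = np.where(dead, 0.0, w)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("all channels have zero signal")
    w = w / norm
    combined_first = w @ first
    if np.abs(combined_first) > 0:
        w = w * np.exp(-1j * np.angle(combined_first))

    combined = np.einsum("c,tcp->tp", w, ts.data)[:, None, :]
    out = ts.replace(data=combined)
    out.acq_meta["coil_weights"] = w
    return out, w


# ---------------------------------------------------------------------------
# Frequency / phase alignment
# ---------------------------------------------------------------------------

DEFAULT_ALIGN_PPM = {"1H": (1.6, 3.6)}  # window bracketing NAA at 2.02 ppm


def _windowed_spectrum(fid: np.ndarray, mask: np.ndarray) -> np.ndarray:
    s = np.fft.fftshift(np.fft.fft(fid))[::-1]
    return s[mask]


def align_frequency_phase(ts: TransientSet, ppm_range: tuple | None = None,
                          max_shift_hz: float = 20.0):
    """Align transients to their median spectrum in a ppm window.

    For each transient, the frequency offset ``Δf`` (bounded to
    ``±max_shift_hz``) and zero-order phase ``Δφ`` minimizing the
    windowed squared difference to the point-wise median spectrum (real
    and imaginary medians taken separately) are estimated — a coarse
    frequency scan with the analytically optimal phase at each
    candidate, refined by bounded nonlinear least squares — and applied
    as ``fid * exp(i(2π Δf t + Δφ))``.

    Returns ``(aligned TransientSet, AlignmentResult)`` with the applied
    shifts in Hz and degrees.
    """
    if ts.n_channels != 1:
        raise ValueError("combine coils before alignment")
    if ts.n_transients < 2:
        raise ValueError("alignment requires >= 2 transients")
    hz, ppm = ts.axes()
    if ppm_range is None:
        ppm_range = DEFAULT_ALIGN_PPM.get(
            ts.nucleus, (float(ppm.min()), float(ppm.max())))
    mask = ppm_window_mask(ppm, *ppm_range)

    spectra = spectra_matrix(ts)[:, mask]
    median = np.median(spectra.real, axis=0) + \
        1j * np.median(spectra.imag, axis=0)

    t = ts.time_axis
    freq_shifts = np.zeros(ts.n_transients)
    phase_shifts = np.zeros(ts.n_transients)
    out = ts.data.copy()

    coarse = np.linspace(-max_shift_hz, max_shift_hz,
                         int(4 * max_shift_hz) + 1)  # 0.5 Hz steps

    for i in range(ts.n_transients):
        fid = ts.data[i, 0]

        def spec_of(df):
            return _windowed_spectrum(fid * np.exp(2j * np.pi * df * t), mask)

        def best_phase(a):
            # phase minimizing || e^{i phi} a - median ||^2
            return np.angle(np.vdot(a, median))

        costs = []
        for df in coarse:
            a = spec_of(df)
            phi = best_phase(a)
            costs.append(np.sum(np.abs(a * np.exp(1j * phi) - median) ** 2))
        j = int(np.argmin(costs))
        df0, phi0 = coarse[j], best_phase(spec_of(coarse[j]))

        def residuals(p):
            a = spec_of(p[0]) * np.exp(1j * p[1])
            d = a - median
            return np.concatenate([d.real, d.imag])

        try:
            res = optimize.least_squares(
                residuals, x0=[df0, phi0],
                bounds=([-max_shift_hz, -2 * np.pi],
                        [max_shift_hz, 2 * np.pi]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            df, phi = res.x
            if not res.success:
                raise RuntimeError(res.message)
        except Exception as exc:  # keep transient uncorrected
            warnings.warn(f"alignment failed for transient {i}: {exc}")
            df, phi = 0.0, 0.0
        phi = (phi + np.pi) % (2 * np.pi) - np.pi
        out[i, 0] = fid * np.exp(1j * (2 * np.pi * df * t + phi))
        freq_shifts[i] = df
        phase_shifts[i] = np.rad2deg(phi)

    return ts.replace(data=out), AlignmentResult(freq_shifts, phase_shifts)


# ---------------------------------------------------------------------------
# Eddy-current correction (Klose)
# ---------------------------------------------------------------------------

def eddy_current_correct(ts: TransientSet,
                         water_ts: TransientSet) -> TransientSet:
    """Klose correction: remove the water-reference phase point-wise.

    ``s_corr(n) = s(n) * exp(-i arg(w̄(n)))`` with ``w̄`` the mean water
    FID.  Where the water magnitude falls below machine precision the
    phase is held from the last valid point.
    """
    if ts.n_channels != 1 or water_ts.n_channels != 1:
        raise ValueError("eddy-current correction requires single-channel data")
    if ts.n_points != water_ts.n_points or not np.isclose(
            ts.dwell_time, water_ts.dwell_time):
        raise ValueError("metabolite and water sets must share n_points/dwell")
    wbar = water_ts.data[:, 0, :].mean(axis=0)
    mag = np.abs(wbar)
    valid = mag > np.finfo(float).eps * max(mag.max(), 1.0)
    phase = np.angle(wbar)
    if not valid.all():
        if not valid.any():
            raise ValueError("water reference is identically zero")
        # hold phase from the last valid sample
        idx = np.where(valid, np.arange(len(phase)), -1)
        idx = np.maximum.accumulate(idx)
        first_valid = int(np.argmax(valid))
        idx[idx < 0] = first_valid
        phase = phase[idx]
    corr = np.exp(-1j * phase)
    return ts.replace(data=ts.data * corr[None, None, :])


# ---------------------------------------------------------------------------
# Bad-average removal
# ---------------------------------------------------------------------------

def remove_bad_averages(ts: TransientSet, k_sd: float = 3.0):
    """Drop outlier transients scored by RMS deviation from the mean.

    ``score_t = RMS(s_t - mean)`` over all channels/points (complex
    difference); transients with ``score > mean(score) + k_sd*SD(score)``
    are removed in a single pass, order preserved.  If the rule would
    remove everything the input is returned unchanged with a warning.
    Returns ``(kept TransientSet, kept_indices)``.
    """
    if ts.n_transients < 3:
        raise ValueError("bad-average removal requires >= 3 transients")
    mean = ts.data.mean(axis=0, keepdims=True)
    diff = ts.data - mean
    score = np.sqrt(np.mean(np.abs(diff) ** 2, axis=(1, 2)))
    thr = score.mean() + k_sd * score.std(ddof=0)
    keep = score <= thr
    if not keep.any():
        warnings.warn("bad-average removal would drop every transient; "
                      "returning input unchanged")
        return ts.replace(), np.arange(ts.n_transients)
    kept_indices = np.nonzero(keep)[0]
    return ts.replace(data=ts.data[keep]), kept_indices


# ---------------------------------------------------------------------------
# Apodization / zero filling / averaging
# ---------------------------------------------------------------------------

def apodize(ts: TransientSet, shape: str = "lorentzian",
            width_hz: float = 1.0) -> TransientSet:
    """Multiply FIDs by a decaying envelope, broadening lines by ``width_hz``.

    Lorentzian: ``exp(-pi w t)``; Gaussian: ``exp(-(pi w t)^2 / (4 ln 2))``
    — for matching lineshapes the spectral FWHM grows by exactly ``w``.
    """
    if width_hz < 0:
        raise ValueError("width_hz must be >= 0")
    if shape not in ("lorentzian", "gaussian"):
        raise ValueError(f"unknown apodization shape {shape!r}")
    t = ts.time_axis
    if shape == "lorentzian":
        env = np.exp(-np.pi * width_hz * t)
    else:
        env = np.exp(-((np.pi * width_hz * t) ** 2) / (4.0 * _LN2))
    return ts.replace(data=ts.data * env[None, None, :])


def apodize_csi(csi: CsiGrid, shape: str = "gaussian",
                width_hz: float = 5.0) -> CsiGrid:
    """Spectral apodization of every voxel FID of a CSI grid."""
    import dataclasses as _dc
    if width_hz < 0:
        raise ValueError("width_hz must be >= 0")
    t = np.arange(csi.n_points) * csi.dwell_time
    if shape == "lorentzian":
        env = np.exp(-np.pi * width_hz * t)
    elif shape == "gaussian":
        env = np.exp(-((np.pi * width_hz * t) ** 2) / (4.0 * _LN2))
    else:
        raise ValueError(f"unknown apodization shape {shape!r}")
    return _dc.replace(csi, data=csi.data * env[None, None, None, :])


def zero_fill(ts: TransientSet, factor: int = 2) -> TransientSet:
    """Append zeros so n_points grows by an integer factor."""
    if not float(factor).is_integer() or factor < 1:
        raise ValueError(f"zero-fill factor must be an integer >= 1, "
                         f"got {factor}")
    factor = int(factor)
    if factor == 1:
        return ts.replace()
    pad = np.zeros(ts.data.shape[:2] + ((factor - 1) * ts.n_points,),
                   dtype=complex)
    return ts.replace(data=np.concatenate([ts.data, pad], axis=-1))


def average_all(ts: TransientSet) -> TransientSet:
    """Arithmetic mean over transients (one output transient)."""
    return ts.replace(data=ts.data.mean(axis=0, keepdims=True))


def blocked_average(ts: TransientSet, meas_per_block: int,
                    avgs_per_block: int, n_block_types: int = 1):
    """Average within experimental blocks, grouped by block type.

    The acquisition is split into consecutive blocks of
    ``meas_per_block`` transients; within each block, consecutive groups
    of ``meas_per_block // avgs_per_block`` transients are averaged,
    producing ``avgs_per_block`` spectra per block.  Blocks are assigned
    to ``n_block_types`` experimental conditions cyclically
    (``type = block_index % n_block_types``) and each type is treated
    independently: outputs are returned grouped by type, each a
    single-transient TransientSet tagged with ``block_type``,
    ``block_index`` and ``avg_index`` in ``acq_meta``.
    """
    n = ts.n_transients
    if meas_per_block < 1 or n % meas_per_block != 0:
        raise ValueError(
            f"n_transients ({n}) not divisible by measurements per block "
            f"({meas_per_block})")
    if avgs_per_block < 1 or meas_per_block % avgs_per_block != 0:
        raise ValueError(
            f"measurements per block ({meas_per_block}) not divisible by "
            f"averages per block ({avgs_per_block})")
    if n_block_types < 1:
        raise ValueError("n_block_types must be >= 1")
    group = meas_per_block // avgs_per_block
    n_blocks = n // meas_per_block
    outputs = []
    for btype in range(n_block_types):
        for b in range(n_blocks):
            if b % n_block_types != btype:
                continue
            start = b * meas_per_block
            for a in range(avgs_per_block):
                sl = ts.data[start + a * group:start + (a + 1) * group]
                out = ts.replace(data=sl.mean(axis=0, keepdims=True))
                out.acq_meta.update(block_type=btype, block_index=b,
                                    avg_index=a)
                outputs.append(out)
    return outputs


def moving_average(ts: TransientSet, window_length: int):
    """Sliding-window averaging with stride 1.

    Output ``k`` is the mean of transients ``[k, k + window)``; exactly
    ``n_transients - window_length + 1`` single-transient sets are
    produced, tagged with ``window_start``.
    """
    n = ts.n_transients
    if not (1 <= window_length <= n):
        raise ValueError(
            f"window_length must be in [1, {n}], got {window_length}")
    outputs = []
    for k in range(n - window_length + 1):
        out = ts.replace(
            data=ts.data[k:k + window_length].mean(axis=0, keepdims=True))
        out.acq_meta.update(window_start=k, window_length=window_length)
        outputs.append(out)
    return outputs


# ---------------------------------------------------------------------------
# Quality metrics
# ---------------------------------------------------------------------------

DEFAULT_SIGNAL_PPM = {"1H": (1.8, 2.2)}   # NAA CH3 at 2.02 ppm
DEFAULT_NOISE_PPM = {"1H": (0.2, 0.5)}    # signal-free upfield region


def _fwhm_interpolated(axis: np.ndarray, profile: np.ndarray) -> float:
    """Full width of the main peak at half maximum, linearly interpolated.

    ``axis`` may be descending; the result is the absolute width in the
    axis units.
    """
    peak = int(np.argmax(profile))
    half = profile[peak] / 2.0
    if profile[peak] <= 0:
        raise ValueError("peak not found above zero")

    def cross(idx_range):
        prev = peak
        for j in idx_range:
            if profile[j] <= half:
                # interpolate between j (below) and prev (above)
                f1, f2 = profile[prev], profile[j]
                x1, x2 = axis[prev], axis[j]
                return x1 + (half - f1) * (x2 - x1) / (f2 - f1)
            prev = j
        raise ValueError("half-maximum crossing not found inside axis")

    left = cross(range(peak - 1, -1, -1))
    right = cross(range(peak + 1, len(profile)))
    return abs(right - left)


def quality_metrics(metab_spec: Spectrum, water_spec: Spectrum,
                    nucleus: str = "1H",
                    signal_ppm: tuple | None = None,
                    noise_ppm: tuple | None = None) -> QualityMetrics:
    """SNR of the metabolite spectrum and FWHM of the water peak.

    SNR is the maximum real peak height in the signal window — after a
    local zero-order phase rotation that maximizes it — divided by the
    RMS of the linearly detrended real part in the noise window.  The
    water linewidth is the full width at half maximum of the
    absorption-mode (real, locally phased) water peak with linear
    interpolation between bins, reported in Hz and ppm.  Absorption
    mode is used because the magnitude of a Lorentzian line is sqrt(3)
    times wider than the linewidth it is meant to report.
    """
    if signal_ppm is None:
        signal_ppm = DEFAULT_SIGNAL_PPM.get(nucleus, (1.8, 2.2))
    if noise_ppm is None:
        noise_ppm = DEFAULT_NOISE_PPM.get(nucleus, (0.2, 0.5))
    sig_mask = ppm_window_mask(metab_spec.ppm_axis, *signal_ppm)
    noise_mask = ppm_window_mask(metab_spec.ppm_axis, *noise_ppm)

    window = metab_spec.values[sig_mask]
    peak_idx = int(np.argmax(np.abs(window)))
    phi0 = -np.angle(window[peak_idx])
    height = float(np.max((window * np.exp(1j * phi0)).real))

    noise = signal.detrend(metab_spec.values[noise_mask].real)
    rms = float(np.sqrt(np.mean(noise ** 2)))
    if rms == 0:
        raise ValueError("noise window has zero RMS; cannot form SNR")

    mag = np.abs(water_spec.values)
    if mag.max() <= 0:
        raise ValueError("water peak not found above noise floor")
    w_idx = int(np.argmax(mag))
    absorption = (water_spec.values
                  * np.exp(-1j * np.angle(water_spec.values[w_idx]))).real
    fwhm_hz = _fwhm_interpolated(water_spec.hz_axis, absorption)
    return QualityMetrics(snr=height / rms, fwhm_hz=fwhm_hz,
                          fwhm_ppm=fwhm_hz / water_spec.f0)


# ---------------------------------------------------------------------------
# CSI k-space Hanning filter
# ---------------------------------------------------------------------------

def _hann_centered(w: int) -> np.ndarray:
    """Symmetric Hann weights with exact weight 1 at index ``w // 2``."""
    if w < 1:
        raise ValueError("window size must be >= 1")
    if w == 1:
        return np.ones(1)
    d = np.arange(w) - w // 2
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * d / (w - 1)))


def hanning_filter_3d(csi: CsiGrid, window_size: tuple | None = None) -> CsiGrid:
    """Separable 3D Hann weighting of CSI k-space.

    The window dimensions must equal the matrix dimensions; the k-space
    centre sample keeps weight 1 and all weights lie in [0, 1].  The
    grid stays in k-space state.
    """
    import dataclasses as _dc
    if csi.space != "k":
        raise ValueError("Hanning filter operates on k-space data; "
                         "call to_kspace() first")
    if window_size is None:
        window_size = csi.matrix
    if tuple(window_size) != tuple(csi.matrix):
        raise ValueError(f"window size {tuple(window_size)} must equal the "
                         f"matrix size {tuple(csi.matrix)}")
    wx, wy, wz = (_hann_centered(w) for w in window_size)
    weights = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
    return _dc.replace(csi, data=csi.data * weights[..., None])


# ---------------------------------------------------------------------------
# Entropy-minimization phasing
# ---------------------------------------------------------------------------

def _entropy_cost(phases: np.ndarray, values: np.ndarray, ppm: np.ndarray,
                  pivot: float, gamma: float) -> float:
    phi0, phi1 = phases  # degrees, degrees/ppm
    rot = np.exp(1j * np.deg2rad(phi0 + phi1 * (ppm - pivot)))
    re = (values * rot).real
    h = np.abs(np.diff(re))
    total = h.sum()
    if total == 0:
        return np.inf
    hn = h / total
    ent = -np.sum(hn * np.log(hn + 1e-300))
    neg = np.minimum(re, 0.0)
    return ent + gamma * np.sum(neg ** 2)


def entropy_min_phase(spec: Spectrum, gamma: float = 1000.0,
                      pivot_ppm: float | None = None):
    """Automatic zero/first-order phasing by spectral entropy minimization.

    Minimizes ``E = -Σ h ln h + γ P`` where ``h`` is the normalized
    magnitude of the first derivative of the real part and ``P``
    penalizes negative real intensity, over the phase correction
    ``S · exp(i(φ0 + φ1·(ppm − pivot)))``.  A derivative-free simplex
    search is multi-started at φ0 ∈ {0°, 90°, 180°, 270°} to escape the
    180° ambiguity.  Returns ``(phi0_deg, phi1_deg_per_ppm, corrected)``.
    """
    if np.max(np.abs(spec.values)) == 0:
        raise ValueError("all-zero spectrum cannot be phased")
    if pivot_ppm is None:
        pivot_ppm = spec.ref_ppm
    values = spec.values / np.max(np.abs(spec.values))
    best = None
    for start in (0.0, 90.0, 180.0, 270.0):
        res = optimize.minimize(
            _entropy_cost, x0=[start, 0.0],
            args=(values, spec.ppm_axis, pivot_ppm, gamma),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    phi0, phi1 = best.x
    phi0 = (phi0 + 180.0) % 360.0 - 180.0
    rot = np.exp(1j * np.deg2rad(phi0 + phi1 * (spec.ppm_axis - pivot_ppm)))
    corrected = Spectrum(values=spec.values * rot,
                         ppm_axis=spec.ppm_axis.copy(),
                         hz_axis=spec.hz_axis.copy(),
                         f0=spec.f0, ref_ppm=spec.ref_ppm)
    return float(phi0), float(phi1), corrected


# ---------------------------------------------------------------------------
# Manual frequency / phase adjustment
# ---------------------------------------------------------------------------

class AdjustmentLog:
    """Append-only log of manual adjustments, optionally mirrored to disk."""

    def __init__(self, path=None):
        self.path = path
        self.entries: list[str] = []

    def append(self, freq_offset_hz, phi0_deg, phi1_deg_per_ppm):
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        line = (f"{stamp}\tfreq_offset_hz={freq_offset_hz:+.6g}\t"
                f"phi0_deg={phi0_deg:+.6g}\t"
                f"phi1_deg_per_ppm={phi1_deg_per_ppm:+.6g}")
        self.entries.append(line)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(line + "\n")
        return line


def _phase_rotation(ppm: np.ndarray, ref_ppm: float, phi0_deg: float,
                    phi1_deg_per_ppm: float) -> np.ndarray:
    return np.exp(1j * np.deg2rad(phi0_deg
                                  + phi1_deg_per_ppm * (ppm - ref_ppm)))


def manual_adjust(obj, freq_offset_hz: float = 0.0, phi0_deg: float = 0.0,
                  phi1_deg_per_ppm: float = 0.0,
                  log: AdjustmentLog | None = None):
    """Apply a user-chosen frequency offset and zero/first-order phase.

    Works on a :class:`TransientSet` (returned as a set) or a
    :class:`Spectrum`.  The frequency offset is applied in the time
    domain (``exp(i 2π f t)``), the phase terms about the carrier ppm in
    the frequency domain.  Every call appends one line to ``log``.
    """
    for v in (freq_offset_hz, phi0_deg, phi1_deg_per_ppm):
        if not np.isfinite(v):
            raise ValueError("manual adjustments must be finite")
    if log is not None:
        log.append(freq_offset_hz, phi0_deg, phi1_deg_per_ppm)

    if isinstance(obj, TransientSet):
        t = obj.time_axis
        data = obj.data * np.exp(2j * np.pi * freq_offset_hz * t)[None, None, :]
        if phi0_deg != 0.0 or phi1_deg_per_ppm != 0.0:
            hz, ppm = obj.axes()
            rot = _phase_rotation(ppm, obj.ref_ppm, phi0_deg,
                                  phi1_deg_per_ppm)
            spec = np.fft.fftshift(np.fft.fft(data, axis=-1), axes=-1)[..., ::-1]
            spec = spec * rot
            data = np.fft.ifft(np.fft.ifftshift(spec[..., ::-1], axes=-1),
                               axis=-1)
        return obj.replace(data=data)

    if isinstance(obj, Spectrum):
        fid = spectrum_to_fid(obj)
        # reconstruct dwell from the axis span: span = (n-1)/(n*dwell)
        n = len(fid)
        span = abs(obj.hz_axis[0] - obj.hz_axis[-1])
        dwell = (n - 1) / (n * span)
        t = np.arange(n) * dwell
        fid = fid * np.exp(2j * np.pi * freq_offset_hz * t)
        values = np.fft.fftshift(np.fft.fft(fid))[::-1]
        values = values * _phase_rotation(obj.ppm_axis, obj.ref_ppm,
                                          phi0_deg, phi1_deg_per_ppm)
        return Spectrum(values=values, ppm_axis=obj.ppm_axis.copy(),
                        hz_axis=obj.hz_axis.copy(), f0=obj.f0,
                        ref_ppm=obj.ref_ppm)

    raise TypeError(f"manual_adjust cannot handle {type(obj).__name__}")


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def estimate_peak_frequency(ts: TransientSet, transient: int,
                            ppm_range: tuple) -> float:
    """Peak frequency (Hz) of one transient via parabolic interpolation
    of the magnitude spectrum inside a ppm window — used to verify
    alignment independently of the aligner's own estimates."""
    spec = fid_to_spectrum(ts, transient)
    mask = ppm_window_mask(spec.ppm_axis, *ppm_range)
    idx = np.nonzero(mask)[0]
    mag = np.abs(spec.values[mask])
    j = int(np.argmax(mag))
    k = idx[j]
    if 0 < k < len(spec.values) - 1:
        y0, y1, y2 = (np.abs(spec.values[k - 1]), np.abs(spec.values[k]),
                      np.abs(spec.values[k + 1]))
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        step = spec.hz_axis[k + 1] - spec.hz_axis[k]
        return float(spec.hz_axis[k] + delta * step)
    return float(spec.hz_axis[k])
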