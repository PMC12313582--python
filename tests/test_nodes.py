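"""Processing-node library: each operation against its independent
oracle (grid searches, closed forms, direct recomputation)."""
import numpy as np
import pytest

from mrsflow.core import TransientSet, fid_to_spectrum, ppm_window_mask
from mrsflow.nodes import (AdjustmentLog, align_frequency_phase, apodize,
                           average_all, blocked_average, coil_combine,
                           eddy_current_correct, entropy_min_phase,
                           estimate_peak_frequency, hanning_filter_3d,
                           manual_adjust, moving_average, quality_metrics,
                           remove_bad_averages, zero_fill,
                           _fwhm_interpolated)
from mrsflow.simulate import Peak, SimConfig, simulate_csi, \
    simulate_transients, simulate_water_reference

from conftest import DWELL, F0, N_POINTS, single_peak_set


def measure_fwhm_hz(ts):
    """Independent linewidth read-out: absorption-mode half-max width."""
    spec = fid_to_spectrum(average_all(ts))
    k = int(np.argmax(np.abs(spec.values)))
    absorption = (spec.values * np.exp(-1j * np.angle(spec.values[k]))).real
    return _fwhm_interpolated(spec.hz_axis, absorption)


# ---------------------------------------------------------------------------
# Coil combination
# ---------------------------------------------------------------------------

class TestCoilCombine:
    @pytest.mark.parametrize("method", ["adaptive", "snr2", "svd"])
    def test_single_channel_is_identity(self, method):
        ts = single_peak_set(n_transients=2, n_points=256)
        out, w = coil_combine(ts, method=method)
        assert np.allclose(out.data, ts.data)
        assert np.isclose(abs(w[0]), 1.0)

    def test_two_identical_channels_svd_scales_sqrt2(self):
        cfg = SimConfig(peaks=[Peak(2.02, 100.0, 5.0)], n_transients=2,
                        n_channels=2, channel_sensitivities=(1.0, 1.0))
        ts = simulate_transients(cfg, n_points=256, dwell=DWELL, f0=F0)
        out, w = coil_combine(ts, method="svd")
        assert out.n_channels == 1
        assert np.allclose(out.data[:, 0, :],
                           np.sqrt(2.0) * ts.data[:, 0, :], rtol=1e-9)

    def test_snr2_reaches_matched_filter_snr(self):
        # oracle: direct matched-filter combination w = conj(s)/sigma^2
        sens = (1.0, 2.0, 2.0, 1.0)
        sigma = 0.5
        cfg = SimConfig(peaks=[Peak(2.02, 100.0, 5.0)], n_transients=16,
                        n_channels=4, channel_sensitivities=sens,
                        noise_sigma=sigma, seed=17)
        ts = simulate_transients(cfg, n_points=N_POINTS, dwell=DWELL, f0=F0)
        water = simulate_water_reference(cfg, n_points=N_POINTS, dwell=DWELL,
                                         f0=F0, water_amplitude=1000.0)
        out, w = coil_combine(ts, method="snr2", water_ref=water)

        def spectral_snr(ts1):
            spec = fid_to_spectrum(average_all(ts1))
            sig = ppm_window_mask(spec.ppm_axis, 1.8, 2.2)
            noi = ppm_window_mask(spec.ppm_axis, 0.2, 0.5)
            return (np.abs(spec.values[sig]).max()
                    / np.std(spec.values[noi].real))

        s = np.array(sens, dtype=complex)
        w_opt = np.conj(s) / sigma ** 2
        w_opt /= np.linalg.norm(w_opt)
        oracle = TransientSet(
            data=np.einsum("c,tcp->tp", w_opt, ts.data)[:, None, :],
            dwell_time=DWELL, f0=F0)
        assert abs(spectral_snr(out) - spectral_snr(oracle)) \
            / spectral_snr(oracle) < 0.03

    def test_adaptive_beats_naive_sum_on_unequal_channels(self):
        cfg = SimConfig(peaks=[Peak(2.02, 100.0, 5.0)], n_transients=8,
                        n_channels=3, channel_sensitivities=(1.0, 3.0, 0.5),
                        noise_sigma=0.5, seed=23)
        ts = simulate_transients(cfg, n_points=N_POINTS, dwell=DWELL, f0=F0)
        water = simulate_water_reference(cfg, n_points=N_POINTS, dwell=DWELL,
                                         f0=F0, water_amplitude=1000.0)
        out, _ = coil_combine(ts, method="adaptive", water_ref=water)
        naive = TransientSet(
            data=ts.data.sum(axis=1, keepdims=True) / np.sqrt(3),
            dwell_time=DWELL, f0=F0)

        def snr(ts1):
            spec = fid_to_spectrum(average_all(ts1))
            sig = ppm_window_mask(spec.ppm_axis, 1.8, 2.2)
            noi = ppm_window_mask(spec.ppm_axis, 0.2, 0.5)
            return (np.abs(spec.values[sig]).max()
                    / np.std(spec.values[noi].real))

        assert snr(out) > snr(naive)

    def test_combined_reference_first_point_real_positive(self):
        cfg = SimConfig(peaks=[Peak(2.02, 100.0, 5.0)], n_transients=2,
                        n_channels=2,
                        channel_sensitivities=(1j, -1.0))
        ts = simulate_transients(cfg, n_points=256, dwell=DWELL, f0=F0)
        out, w = coil_combine(ts, method="svd")
        first = (w @ ts.data.mean(axis=0))[0]
        assert first.real > 0 and abs(first.imag) < 1e-9 * abs(first)


# ---------------------------------------------------------------------------
# Frequency / phase alignment
# ---------------------------------------------------------------------------

def grid_search_alignment(fid, median_win, mask, t, df_grid):
    """Oracle: exhaustive frequency grid with the exact optimal phase at
    each candidate (the continuous minimizer over phase)."""
    best = (np.inf, 0.0, 0.0)
    for df in df_grid:
        a = np.fft.fftshift(np.fft.fft(
            fid * np.exp(2j * np.pi * df * t)))[::-1][mask]
        phi = np.angle(np.vdot(a, median_win))
        cost = np.sum(np.abs(a * np.exp(1j * phi) - median_win) ** 2)
        if cost < best[0]:
            best = (cost, df, phi)
    return best[1], np.rad2deg(best[2])


class TestAlignment:
    def test_identical_transients_need_no_correction(self):
        ts = single_peak_set(n_transients=4)
        aligned, res = align_frequency_phase(ts)
        assert np.all(np.abs(res.freq_shifts) < 0.05)
        assert np.all(np.abs(res.phase_shifts) < 0.5)

    def test_recovers_known_shifts_matching_grid_oracle(self):
        # majority of clean copies pins the median to the template, so the
        # injected offsets on the remaining transients must come back
        # negated
        base = single_peak_set(n_transients=1).data[0, 0]
        t = np.arange(N_POINTS) * DWELL
        true = [(0.0, 0.0)] * 5 + [(5.0, 30.0), (-5.0, -30.0), (3.0, -15.0),
                                   (-2.0, 20.0)]
        data = np.stack([
            base * np.exp(1j * (2 * np.pi * df * t + np.deg2rad(dp)))
            for df, dp in true])[:, None, :]
        ts = TransientSet(data=data, dwell_time=DWELL, f0=F0)
        aligned, res = align_frequency_phase(ts, ppm_range=(1.6, 3.6))

        hz, ppm = ts.axes()
        mask = ppm_window_mask(ppm, 1.6, 3.6)
        spectra = np.fft.fftshift(np.fft.fft(data[:, 0], axis=-1),
                                  axes=-1)[:, ::-1][:, mask]
        median = np.median(spectra.real, axis=0) + \
            1j * np.median(spectra.imag, axis=0)
        df_grid = np.arange(-20.0, 20.0 + 1e-9, 0.05)
        for i, (df_true, dp_true) in enumerate(true):
            df_o, dp_o = grid_search_alignment(data[i, 0], median, mask, t,
                                               df_grid)
            assert abs(res.freq_shifts[i] - df_o) < 0.1
            assert abs(res.freq_shifts[i] + df_true) < 0.1
            assert abs((res.phase_shifts[i] - dp_o + 180) % 360 - 180) < 1.0
            assert abs((res.phase_shifts[i] + dp_true + 180) % 360
                       - 180) < 1.0

    def test_objective_never_increases(self):
        cfg = SimConfig(peaks=[Peak(2.02, 100.0, 5.0)], n_transients=8,
                        noise_sigma=0.3, phase_jitter_deg_sd=15.0,
                        freq_drift_hz_per_transient=0.5, seed=31)
        ts = simulate_transients(cfg, n_points=N_POINTS, dwell=DWELL, f0=F0)
        aligned, _ = align_frequency_phase(ts)

        def spread(ts1):
            hz, ppm = ts1.axes()
            mask = ppm_window_mask(ppm, 1.6, 3.6)
            s = np.fft.fftshift(np.fft.fft(ts1.data[:, 0], axis=-1),
                                axes=-1)[:, ::-1][:, mask]
            med = np.median(s.real, axis=0) + 1j * np.median(s.imag, axis=0)
            return np.sum(np.abs(s - med) ** 2)

        assert spread(aligned) <= spread(ts) + 1e-9


# ---------------------------------------------------------------------------
# Eddy-current correction
# ---------------------------------------------------------------------------

class TestEddyCurrentCorrection:
    def test_zero_phase_water_is_identity(self):
        ts = single_peak_set(n_transients=2, n_points=256)
        water = TransientSet(
            data=np.abs(np.random.default_rng(0).standard_normal(
                (1, 1, 256))) + 0.5 + 0j,
            dwell_time=DWELL, f0=F0, role="water_reference")
        out = eddy_current_correct(ts, water)
        assert np.allclose(out.data, ts.data)

    def test_self_correction_yields_magnitude(self):
        cfg = SimConfig(peaks=[Peak(4.7, 100.0, 8.0)], n_transients=1,
                        eddy_amp_rad=0.5, seed=0)
        water = simulate_transients(cfg, n_points=256, dwell=DWELL, f0=F0,
                                    role="water_reference")
        out = eddy_current_correct(water, water)
        assert np.allclose(out.data.imag, 0.0, atol=1e-10)
        assert np.all(out.data.real >= -1e-12)

    def test_injected_eddy_phase_cancels_exactly(self):
        # algebraic oracle: identical phase term in metab and water cancels
        cfg_clean = SimConfig(peaks=[Peak(2.02, 100.0, 5.0)], n_transients=4,
                              seed=2)
        clean = simulate_transients(cfg_clean, n_points=N_POINTS,
                                    dwell=DWELL, f0=F0)
        t = np.arange(N_POINTS) * DWELL
        phase = 0.8 * np.exp(-t / 0.1)
        corrupted = clean.replace(data=clean.data * np.exp(1j * phase))
        water_clean = simulate_water_reference(cfg_clean, n_points=N_POINTS,
                                               dwell=DWELL, f0=F0)
        water = water_clean.replace(
            data=water_clean.data * np.exp(1j * phase))
        out = eddy_current_correct(corrupted, water)
        scale = np.abs(clean.data).max()
        assert np.max(np.abs(out.data - clean.data)) / scale < 1e-8

    def test_low_magnitude_water_holds_phase(self):
        ts = single_peak_set(n_transients=1, n_points=64)
        w = np.exp(1j * 0.3) * np.ones(64)
        w[40:] = 0.0  # dead tail
        water = TransientSet(data=w[None, None, :], dwell_time=DWELL, f0=F0,
                             role="water_reference")
        out = eddy_current_correct(ts, water)
        expected = ts.data * np.exp(-1j * 0.3)
        assert np.allclose(out.data, expected)


# ---------------------------------------------------------------------------
# Bad-average removal
# ---------------------------------------------------------------------------

class TestRemoveBadAverages:
    def test_identical_transients_all_kept(self):
        base = single_peak_set(n_transients=1).data[0]
        ts = TransientSet(data=np.repeat(base[None], 8, axis=0),
                          dwell_time=DWELL, f0=F0)
        kept, idx = remove_bad_averages(ts)
        assert kept.n_transients == 8
        assert list(idx) == list(range(8))

    def test_single_planted_artifact_removed(self):
        cfg = SimConfig(peaks=[Peak(2.02, 100.0, 5.0)], n_transients=32,
                        noise_sigma=0.2, outlier_indices=(13,),
                        outlier_gain=20.0, seed=13)
        ts = simulate_transients(cfg, n_points=N_POINTS, dwell=DWELL, f0=F0)
        # direct score oracle
        diff = ts.data - ts.data.mean(axis=0, keepdims=True)
        score = np.sqrt(np.mean(np.abs(diff) ** 2, axis=(1, 2)))
        thr = score.mean() + 3.0 * score.std()
        assert set(np.nonzero(score > thr)[0]) == {13}
        kept, idx = remove_bad_averages(ts, k_sd=3.0)
        assert 13 not in idx and kept.n_transients == 31

    def test_unreachable_threshold_removes_none(self):
        cfg = SimConfig(peaks=[Peak(2.02, 100.0, 5.0)], n_transients=8,
                        noise_sigma=0.5, seed=1)
        ts = simulate_transients(cfg, n_points=512, dwell=DWELL, f0=F0)
        kept, idx = remove_bad_averages(ts, k_sd=1e6)
        assert kept.n_transients == 8

    def test_kept_transients_order_and_content_preserved(self):
        cfg = SimConfig(peaks=[Peak(2.02, 100.0, 5.0)], n_transients=16,
                        noise_sigma=0.2, outlier_indices=(3, 9),
                        outlier_gain=15.0, seed=5)
        ts = simulate_transients(cfg, n_points=512, dwell=DWELL, f0=F0)
        kept, idx = remove_bad_averages(ts)
        assert np.all(np.diff(idx) > 0)
        for out_row, src in enumerate(idx):
            assert np.array_equal(kept.data[out_row], ts.data[src])


# ---------------------------------------------------------------------------
# Apodization / zero filling
# ---------------------------------------------------------------------------

class TestApodize:
    def test_zero_width_is_identity(self):
        ts = single_peak_set(n_points=256)
        for shape in ("lorentzian", "gaussian"):
            assert np.allclose(apodize(ts, shape, 0.0).data, ts.data)

    def test_lorentzian_widths_add(self):
        ts = single_peak_set(lorentz=6.0, n_points=8192)
        out = apodize(ts, "lorentzian", 4.0)
        grid_hz = 1.0 / (8192 * DWELL)
        assert abs(measure_fwhm_hz(out) - 10.0) <= 2 * grid_hz

    def test_gaussian_on_constant_envelope_gives_exact_width(self):
        fid = np.ones(8192, dtype=complex)  # delta line at carrier
        ts = TransientSet(data=fid[None, None, :], dwell_time=DWELL, f0=F0)
        out = apodize(ts, "gaussian", 12.0)
        grid_hz = 1.0 / (8192 * DWELL)
        assert abs(measure_fwhm_hz(out) - 12.0) <= 2 * grid_hz

    def test_negative_width_rejected(self):
        ts = single_peak_set(n_points=64)
        with pytest.raises(ValueError):
            apodize(ts, "lorentzian", -1.0)


class TestZeroFill:
    def test_factor_one_is_identity(self):
        ts = single_peak_set(n_points=128)
        assert np.array_equal(zero_fill(ts, 1).data, ts.data)

    def test_padding_is_exact_zeros(self):
        ts = single_peak_set(n_points=1024)
        out = zero_fill(ts, 2)
        assert out.n_points == 2048
        assert np.array_equal(out.data[..., :1024], ts.data)
        assert np.all(out.data[..., 1024:] == 0)

    def test_trigonometric_interpolation_at_original_grid(self):
        # oracle: direct DFT of the original FID at the original frequencies
        ts = single_peak_set(n_points=512)
        spec0 = fid_to_spectrum(ts)
        spec2 = fid_to_spectrum(zero_fill(ts, 2))
        # original bins sit at every other padded bin with matching hz
        sel = np.isin(np.round(spec2.hz_axis, 9), np.round(spec0.hz_axis, 9))
        sub = spec2.values[sel]
        assert len(sub) == len(spec0.values)
        scale = np.abs(spec0.values).max()
        assert np.max(np.abs(sub - spec0.values)) / scale < 1e-8

    def test_non_integer_factor_rejected(self):
        ts = single_peak_set(n_points=64)
        with pytest.raises(ValueError):
            zero_fill(ts, 1.5)


# ---------------------------------------------------------------------------
# Averaging modes
# ---------------------------------------------------------------------------

class TestAveraging:
    def test_average_all_of_copies_is_the_copy(self):
        base = single_peak_set(n_points=256).data[0]
        ts = TransientSet(data=np.repeat(base[None], 5, axis=0),
                          dwell_time=DWELL, f0=F0)
        out = average_all(ts)
        assert out.n_transients == 1
        assert np.allclose(out.data[0], base)

    def test_noise_reduces_by_sqrt_n(self):
        cfg = SimConfig(peaks=[], n_transients=64, noise_sigma=1.0, seed=8)
        ts = simulate_transients(cfg, n_points=4096, dwell=DWELL, f0=F0)
        spec_single = fid_to_spectrum(ts, 0)
        spec_avg = fid_to_spectrum(average_all(ts))
        r_single = np.sqrt(np.mean(spec_single.values.real ** 2))
        r_avg = np.sqrt(np.mean(spec_avg.values.real ** 2))
        assert abs(r_avg - r_single / 8.0) / (r_single / 8.0) < 0.10

    def test_blocked_16_transients_4_avgs_groups_of_4(self):
        cfg = SimConfig(peaks=[Peak(2.02, 100.0, 5.0)], n_transients=16,
                        noise_sigma=0.3, seed=4)
        ts = simulate_transients(cfg, n_points=256, dwell=DWELL, f0=F0)
        outs = blocked_average(ts, meas_per_block=16, avgs_per_block=4)
        assert len(outs) == 4
        for a, out in enumerate(outs):
            expected = ts.data[4 * a:4 * (a + 1)].mean(axis=0)
            assert np.allclose(out.data[0], expected)

    def test_blocked_fmrs_configuration_yields_8_spectra(self):
        cfg = SimConfig(peaks=[Peak(2.02, 100.0, 5.0)], n_transients=128,
                        noise_sigma=0.3, seed=6)
        ts = simulate_transients(cfg, n_points=128, dwell=DWELL, f0=F0)
        outs = blocked_average(ts, meas_per_block=16, avgs_per_block=1,
                               n_block_types=2)
        assert len(outs) == 8
        types = [o.acq_meta["block_type"] for o in outs]
        assert types == [0, 0, 0, 0, 1, 1, 1, 1]  # grouped by type
        blocks = [o.acq_meta["block_index"] for o in outs]
        assert blocks == [0, 2, 4, 6, 1, 3, 5, 7]  # cyclic assignment

    def test_blocked_degenerate_equals_average_all(self):
        ts = single_peak_set(n_transients=8, n_points=128, noise_sigma=0.2,
                             seed=3)
        outs = blocked_average(ts, meas_per_block=8, avgs_per_block=1)
        assert len(outs) == 1
        assert np.allclose(outs[0].data, average_all(ts).data)

    def test_blocked_indivisible_raises_naming_both(self):
        ts = single_peak_set(n_transients=10, n_points=64)
        with pytest.raises(ValueError, match="10.*3|3.*10"):
            blocked_average(ts, meas_per_block=3, avgs_per_block=1)
        with pytest.raises(ValueError, match="5.*2|2.*5"):
            blocked_average(ts, meas_per_block=5, avgs_per_block=2)

    def test_moving_window_equals_slice_means(self):
        cfg = SimConfig(peaks=[Peak(2.02, 100.0, 5.0)], n_transients=128,
                        noise_sigma=0.3, seed=7)
        ts = simulate_transients(cfg, n_points=64, dwell=DWELL, f0=F0)
        outs = moving_average(ts, window_length=5)
        assert len(outs) == 124
        for k in (0, 50, 123):
            assert np.allclose(outs[k].data[0],
                               ts.data[k:k + 5].mean(axis=0))

    def test_moving_degenerate_windows(self):
        ts = single_peak_set(n_transients=6, n_points=64, noise_sigma=0.1,
                             seed=9)
        full = moving_average(ts, window_length=6)
        assert len(full) == 1
        assert np.allclose(full[0].data, average_all(ts).data)
        identity = moving_average(ts, window_length=1)
        assert len(identity) == 6
        assert all(np.allclose(o.data[0], ts.data[k])
                   for k, o in enumerate(identity))


# ---------------------------------------------------------------------------
# Quality metrics
# ---------------------------------------------------------------------------

class TestQualityMetrics:
    def test_noiseless_lorentzian_water_fwhm(self):
        water = single_peak_set(ppm=4.7, amplitude=100.0, lorentz=10.0,
                                n_points=8192)
        metab = single_peak_set(ppm=2.02, amplitude=100.0, lorentz=5.0,
                                n_points=8192, noise_sigma=0.5, seed=2)
        qm = quality_metrics(fid_to_spectrum(metab), fid_to_spectrum(water))
        assert abs(qm.fwhm_hz - 10.0) <= 0.2
        assert np.isclose(qm.fwhm_ppm, qm.fwhm_hz / F0)

    def test_snr_matches_direct_ratio_oracle(self):
        cfg = SimConfig(peaks=[Peak(2.02, 100.0, 5.0)], n_transients=1,
                        noise_sigma=0.5, seed=12)
        metab = simulate_transients(cfg, n_points=4096, dwell=DWELL, f0=F0)
        water = single_peak_set(ppm=4.7, amplitude=100.0, lorentz=10.0,
                                n_points=4096)
        spec = fid_to_spectrum(metab)
        qm = quality_metrics(spec, fid_to_spectrum(water))
        # oracle: same realized draw, direct height / rms computation
        from scipy.signal import detrend
        sig = ppm_window_mask(spec.ppm_axis, 1.8, 2.2)
        noi = ppm_window_mask(spec.ppm_axis, 0.2, 0.5)
        win = spec.values[sig]
        phi = -np.angle(win[np.argmax(np.abs(win))])
        height = (win * np.exp(1j * phi)).real.max()
        rms = np.sqrt(np.mean(detrend(spec.values[noi].real) ** 2))
        assert abs(qm.snr - height / rms) / (height / rms) < 1e-9

    def test_snr_halves_when_noise_doubles(self):
        water = single_peak_set(ppm=4.7, amplitude=100.0, lorentz=10.0,
                                n_points=4096)
        snrs = []
        for sigma in (0.5, 1.0):
            cfg = SimConfig(peaks=[Peak(2.02, 100.0, 5.0)], n_transients=1,
                            noise_sigma=sigma, seed=12)
            metab = simulate_transients(cfg, n_points=4096, dwell=DWELL,
                                        f0=F0)
            snrs.append(quality_metrics(fid_to_spectrum(metab),
                                        fid_to_spectrum(water)).snr)
        assert abs(snrs[1] - snrs[0] / 2) / (snrs[0] / 2) < 0.10

    def test_window_outside_axis_raises(self):
        metab = single_peak_set(n_points=512)
        water = single_peak_set(ppm=4.7, n_points=512)
        with pytest.raises(Exception, match="outside"):
            quality_metrics(fid_to_spectrum(metab), fid_to_spectrum(water),
                            signal_ppm=(90.0, 95.0))


# ---------------------------------------------------------------------------
# 3D Hanning k-space filter
# ---------------------------------------------------------------------------

def psf_fwhm(grid_shape, weights=None):
    """Direct PSF oracle: image of a full-grid k-space impulse response."""
    k = np.ones(grid_shape, dtype=complex)
    if weights is not None:
        k = k * weights
    img = np.abs(np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(k))))
    profile = img[:, grid_shape[1] // 2, grid_shape[2] // 2]
    return _fwhm_interpolated(np.arange(grid_shape[0]).astype(float),
                              profile)


class TestHanningFilter:
    def _kgrid(self, matrix=(16, 16, 8)):
        cfg = SimConfig(peaks=[Peak(0.0, 10.0, 8.0)], seed=3)
        return simulate_csi(cfg, matrix=matrix, n_points=16,
                            to_kspace=True)

    def test_center_weight_is_one_and_bounded(self):
        grid = self._kgrid()
        flat = grid.to_image()
        flat.data[:] = 0
        flat.data[..., 0] = 1.0
        k = flat.to_kspace()
        k.data[:] = 1.0  # constant k-space
        out = hanning_filter_3d(k)
        weights = out.data[..., 0].real
        cx, cy, cz = 16 // 2, 16 // 2, 8 // 2
        assert np.isclose(weights[cx, cy, cz], 1.0)
        assert weights.min() >= -1e-12 and weights.max() <= 1.0 + 1e-12

    def test_constant_kspace_becomes_the_window(self):
        grid = self._kgrid((8, 8, 4))
        grid.data[:] = 2.0
        out = hanning_filter_3d(grid)
        w = out.data[..., 0] / 2.0
        # separability: w(x,y,z) = w(x,c,c)*w(c,y,c)*w(c,c,z)
        cx, cy, cz = 4, 4, 2
        recon = (w[:, cy, cz][:, None, None] * w[cx, :, cz][None, :, None]
                 * w[cx, cy, :][None, None, :])
        assert np.allclose(w, recon)

    def test_psf_strictly_broadened(self):
        matrix = (16, 16, 8)
        grid = self._kgrid(matrix)
        ones = grid
        ones.data[:] = 1.0
        filtered = hanning_filter_3d(ones)
        w3 = filtered.data[..., 0].real
        before = psf_fwhm(matrix)
        after = psf_fwhm(matrix, w3)
        assert after > before

    def test_image_space_input_rejected(self):
        cfg = SimConfig(peaks=[Peak(0.0, 10.0, 8.0)], seed=3)
        img = simulate_csi(cfg, matrix=(4, 4, 2), n_points=8)
        with pytest.raises(ValueError, match="k-space"):
            hanning_filter_3d(img)

    def test_window_must_match_matrix(self):
        grid = self._kgrid((8, 8, 4))
        with pytest.raises(ValueError, match="matrix"):
            hanning_filter_3d(grid, window_size=(16, 16, 8))


# ---------------------------------------------------------------------------
# Entropy-minimization phasing
# ---------------------------------------------------------------------------

def p31_spectrum(phi0=0.0, phi1=0.0):
    """Multi-peak phosphorus-like absorption spectrum, optionally dephased."""
    cfg = SimConfig(peaks=[Peak(0.0, 100.0, 8.0), Peak(-7.5, 40.0, 10.0),
                           Peak(5.0, 30.0, 10.0), Peak(-16.0, 25.0, 12.0)],
                    n_transients=1, seed=0)
    ts = simulate_transients(cfg, n_points=2048, dwell=1 / 6000.0, f0=120.7,
                             nucleus="31P")
    spec = fid_to_spectrum(ts)
    rot = np.exp(1j * np.deg2rad(phi0 + phi1 * (spec.ppm_axis
                                                - spec.ref_ppm)))
    spec.values = spec.values * rot
    return spec


def entropy_grid_oracle(spec, phi0_grid, phi1_grid, gamma=1000.0):
    from mrsflow.nodes import _entropy_cost
    values = spec.values / np.max(np.abs(spec.values))
    best = (np.inf, 0.0, 0.0)
    for p0 in phi0_grid:
        for p1 in phi1_grid:
            c = _entropy_cost((p0, p1), values, spec.ppm_axis, spec.ref_ppm,
                              gamma)
            if c < best[0]:
                best = (c, p0, p1)
    return best[1], best[2]


class TestEntropyPhasing:
    def test_already_phased_spectrum_untouched(self):
        spec = p31_spectrum()
        phi0, phi1, _ = entropy_min_phase(spec)
        assert abs(phi0) < 2.0
        assert abs(phi1) < 0.5

    def test_zero_order_dephasing_recovered_vs_grid_oracle(self):
        spec = p31_spectrum(phi0=40.0)
        phi0, phi1, corrected = entropy_min_phase(spec)
        o0, o1 = entropy_grid_oracle(spec, np.arange(-180, 180, 1.0), [0.0])
        assert abs((phi0 - o0 + 180) % 360 - 180) <= 2.0
        assert abs((phi0 + 40.0 + 180) % 360 - 180) <= 2.0
        # corrected spectrum has no large negative absorption lobes
        assert corrected.values.real.min() > -0.05 * \
            corrected.values.real.max()

    def test_first_order_dephasing_recovered(self):
        spec = p31_spectrum(phi0=20.0, phi1=3.0)
        phi0, phi1, _ = entropy_min_phase(spec)
        assert abs((phi0 + 20.0 + 180) % 360 - 180) <= 2.0
        assert abs(phi1 + 3.0) <= 0.5

    def test_all_zero_spectrum_rejected(self):
        spec = p31_spectrum()
        spec.values = np.zeros_like(spec.values)
        with pytest.raises(ValueError, match="zero"):
            entropy_min_phase(spec)


# ---------------------------------------------------------------------------
# Manual adjustment
# ---------------------------------------------------------------------------

class TestManualAdjust:
    def test_identity_adjustment_logs_one_line(self):
        ts = single_peak_set(n_points=256)
        log = AdjustmentLog()
        out = manual_adjust(ts, 0.0, 0.0, 0.0, log=log)
        assert np.allclose(out.data, ts.data)
        assert len(log.entries) == 1

    def test_180_degree_phase_negates_spectrum(self):
        ts = single_peak_set(n_points=256)
        spec = fid_to_spectrum(ts)
        out = manual_adjust(spec, 0.0, 180.0, 0.0)
        assert np.allclose(out.values, -spec.values, atol=1e-9)

    def test_frequency_offset_moves_peak(self):
        ts = single_peak_set(n_points=N_POINTS)
        out = manual_adjust(ts, freq_offset_hz=12.0)
        f_before = estimate_peak_frequency(ts, 0, (1.6, 3.6))
        f_after = estimate_peak_frequency(out, 0, (1.6, 3.6))
        bin_hz = 1.0 / (N_POINTS * DWELL)
        assert abs((f_after - f_before) - 12.0) <= bin_hz

    def test_spectrum_frequency_offset_consistent_with_time_domain(self):
        ts = single_peak_set(n_points=1024)
        via_ts = fid_to_spectrum(manual_adjust(ts, 7.0, 30.0, 0.0))
        via_spec = manual_adjust(fid_to_spectrum(ts), 7.0, 30.0, 0.0)
        scale = np.abs(via_ts.values).max()
        assert np.max(np.abs(via_ts.values - via_spec.values)) / scale < 1e-8

    def test_non_finite_rejected(self):
        ts = single_peak_set(n_points=64)
        with pytest.raises(ValueError):
            manual_adjust(ts, float("nan"), 0.0, 0.0)


# ---------------------------------------------------------------------------
# Cross-cutting properties
# ---------------------------------------------------------------------------

class TestNodeProperties:
    def test_linear_nodes_commute_with_scaling(self):
        ts = single_peak_set(n_transients=4, n_points=256, noise_sigma=0.2,
                             seed=14)
        scaled = ts.replace(data=3.0 * ts.data)
        for op in (lambda x: apodize(x, "gaussian", 5.0),
                   lambda x: zero_fill(x, 2),
                   average_all):
            assert np.allclose(op(scaled).data, 3.0 * op(ts).data)

    def test_zero_fill_apodize_commute_on_original_support(self):
        ts = single_peak_set(n_transients=2, n_points=256)
        a = zero_fill(apodize(ts, "lorentzian", 4.0), 2)
        b = apodize(zero_fill(ts, 2), "lorentzian", 4.0)
        # identical on the original support; the padded region is zero in
        # both orders (envelope times zero)
        assert np.allclose(a.data, b.data)

    def test_nodes_do_not_mutate_inputs(self):
        ts = single_peak_set(n_transients=4, n_points=256, noise_sigma=0.2,
                             seed=15)
        snapshot = ts.data.copy()
        apodize(ts, "lorentzian", 3.0)
        zero_fill(ts, 2)
        average_all(ts)
        remove_bad_averages(ts)
        align_frequency_phase(ts)
        assert np.array_equal(ts.data, snapshot)
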