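# mrsflow

Headless, scriptable node-graph pipelines for in-vivo magnetic resonance
spectroscopy (MRS) and spectroscopic imaging (MRSI) data.

Reliable metabolite quantification from MRS requires a chain of
preprocessing steps — coil combination, frequency/phase alignment,
eddy-current correction, outlier rejection, apodization, zero filling
and averaging — before the spectrum ever reaches a fitting program.
`mrsflow` implements that chain as a library of composable processing
nodes plus a pipeline engine, for researchers who want reproducible,
batch-capable spectral preprocessing of ¹H and X-nuclei (³¹P, ¹³C, ²H)
single-voxel and CSI data without a GUI. Processed data are exchanged
as NIfTI-MRS and LCModel ASCII formats; the fitting itself is delegated
to an external LCModel binary when one is configured.

## What it computes

The central object is a set of complex free-induction decays (FIDs)
`s_t,c(n)` indexed by transient *t*, receiver channel *c* and time point
*n*, with spectra obtained by a centre-shifted DFT on a descending ppm
axis (`ppm = Hz / f0 + ref_ppm`). The core operations:

* **Coil combination** — weights `w_c ∝ conj(S_c)/σ_c²` (signal/noise²),
  the leading left singular vector of the water channel×time matrix
  (SVD), or the generalized-eigenvector weights maximizing
  `w†R_s w / w†R_n w` (adaptive combine).
* **Frequency/phase alignment** — per transient, `(Δf, Δφ)` minimizing
  `Σ_window |S_t·e^{i(2πΔf τ + Δφ)} − S_median|²` against the point-wise
  median spectrum, windowed on the NAA resonance at 2.02 ppm for ¹H.
* **Eddy-current correction (Klose)** —
  `s_corr(n) = s(n)·e^{−i·arg(w̄(n))}` with `w̄` the mean unsuppressed
  water FID.
* **Bad-average removal** — drop transients whose RMS deviation from the
  mean exceeds `mean + k·SD` of the per-transient scores (default k=3).
* **Averaging** — overall, blocked (per experimental condition, for
  functional MRS) and moving-window modes.
* **Quality metrics** — SNR as the 2.02 ppm peak height over the RMS
  noise in 0.2–0.5 ppm; water linewidth as the absorption-mode FWHM in
  Hz.
* **CSI** — separable 3D Hann k-space weighting and per-voxel line
  broadening; per-voxel LCModel outputs feed CRLB-thresholded 2D
  metabolite maps, optionally as ratios to a reference metabolite and
  interpolated to an anatomical slice.
* **Entropy-minimization phasing** — automatic zero/first-order phase
  for X-nuclei spectra by minimizing `−Σ h ln h + γ·P` over the
  derivative-magnitude distribution `h` with a negativity penalty `P`.
* **Water scaling** — voxel water concentration
  `WCONC = 55510·(0.78 f_GM + 0.65 f_WM + 0.97 f_CSF)/(Σf)` mM from
  tissue-probability volumes, substituted into the LCModel control
  file.

A deterministic synthetic-acquisition generator (resonances at known
ppm, Voigt lineshapes, multi-channel sensitivities, drift, phase
jitter, eddy phase, outliers, fMRS block designs, 3D CSI grids) makes
every pipeline testable end to end with no external data.

## Worked example

Simulate a corrupted 32-transient, two-channel proton acquisition
(1 Hz/transient drift, 10° phase jitter, eddy-current phase, two
motion-corrupted transients) and run the single-voxel preset —
adaptive coil combination → alignment → eddy-current correction →
bad-average removal → averaging:

```python
from mrsflow import SimConfig, Peak, simulate_transients, \
    simulate_water_reference, run_pipeline
from mrsflow.presets import get_preset
from mrsflow.core import fid_to_spectrum
from mrsflow.nodes import quality_metrics, average_all

cfg = SimConfig(
    peaks=[Peak(2.02, 100.0, 5.0), Peak(3.03, 70.0, 5.0)],
    n_transients=32, n_channels=2, channel_sensitivities=(1.0, 1.5),
    noise_sigma=0.2, freq_drift_hz_per_transient=1.0,
    phase_jitter_deg_sd=10.0, eddy_amp_rad=0.8,
    outlier_indices=(5, 21), outlier_gain=8.0, seed=42)
metab = simulate_transients(cfg, n_points=4096, dwell=1/4000, f0=297.2)
water = simulate_water_reference(cfg, n_points=4096, dwell=1/4000,
                                 f0=297.2, water_amplitude=500.0)

run = run_pipeline(metab, get_preset("svs_1h"), water_ref=water)
kept = run.context.kept_indices[0]
print("kept transients:", len(kept), "of", metab.n_transients)
align = run.context.alignments[0]
print(f"alignment shifts: {align.freq_shifts.min():.1f} "
      f"to {align.freq_shifts.max():.1f} Hz")
qm = quality_metrics(fid_to_spectrum(run.final[0]),
                     fid_to_spectrum(average_all(run.context.water)))
print(f"SNR = {qm.snr:.1f}, water FWHM = {qm.fwhm_hz:.2f} Hz "
      f"({qm.fwhm_ppm:.4f} ppm)")
```

prints

```
kept transients: 30 of 32
alignment shifts: -14.8 to 16.2 Hz
SNR = 3125.5, water FWHM = 10.09 Hz (0.0339 ppm)
```

Both planted outliers were rejected; the alignment undid the ±16 Hz of
accumulated drift relative to the median transient; the water linewidth
matches the simulated 10 Hz Lorentzian. (SNR is high because the
example uses a strong noiseless-signal configuration with σ = 0.2.)

The same pipelines run from a shell:

```sh
mrsflow simulate --out demo.nii --seed 3
mrsflow run --input demo.nii --preset svs_1h --out results/ --save-intermediate
mrsflow batch make --root studies --study PILOT --participants 5
mrsflow map --quant-dir voxels/ --metabolite NAD+ --reference PCr \
            --crlb 30 --slice ax:4 --out nad_map.csv
```

Pipelines are saved and shared as canonical-JSON `.pipe` files; custom
nodes are Python classes dropped into a designated plugin folder and
registered via `api.RegisterNode` (see `mrsflow.engine.Node`).

## Scope notes

Vendor raw formats (Siemens .dat/.ima/.rda, Philips .sdat) are not
parsed — convert externally (e.g. with spec2nii) to NIfTI-MRS. The
LCModel fitting algorithm is never re-implemented: when no binary is
configured, runs degrade gracefully, leaving the prepared .RAW and
control files in place. See `docs/methods.md` for the models,
conventions, parameter defaults and known limitations.
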