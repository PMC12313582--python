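# Methods

This note documents the models, conventions, numerical choices and
limitations behind `mrsflow`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and spectral conventions

The canonical in-memory object is the time-domain `TransientSet`:
complex FIDs indexed `[transient, channel, point]` with a sampling
interval (`dwell_time`, s), transmitter frequency (`f0`, MHz), nucleus
label and the chemical shift assigned to the carrier (`ref_ppm`).
Time-domain is canonical between processing nodes; the frequency-domain
view is computed on demand. The forward transform is a plain
(non-unitary) centre-shifted DFT; only internal consistency matters and
Parseval's identity (`Σ|fid|² = Σ|spec|²/n`) is enforced by a property
test on every grid size.

Axes follow the NMR plotting convention: frequencies
`(k − ⌊n/2⌋)/(n·dwell)` Hz are reversed so the ppm axis
(`ppm = Hz/f0 + ref_ppm`) decreases left-to-right. For even `n` the
carrier sits on bin `n/2` before reversal (half-open convention).
Default `ref_ppm` is 4.7 for ¹H (water-centred acquisitions) and 0.0
for ³¹P/¹³C; there is no chemical-shift referencing to external
standards.

## Synthetic acquisitions

The generator produces every input shape the pipelines consume; its
defaults mirror a short-TE 7 T proton protocol (4 kHz bandwidth, 4096
points, f0 = 297.2 MHz, 32 transients) and a 6 kHz / 2048-point ³¹P
protocol at 120.7 MHz. The signal model per transient and channel is

```
FID_t,c(n) = sens_c · Σ_p A_p·g_p(t_n)·exp(i(2π(f_p + t·drift)t_n + φ_p + jitter_t)) · exp(i·eddy(t_n)) + noise
```

with lineshape `g_p(t) = exp(−π·Δν_L·t)·exp(−(π·Δν_G·t)²/(4 ln 2))`,
chosen so the spectral FWHM of the Lorentzian and Gaussian components
equal the configured values exactly — quality-metric and apodization
tests rely on these closed forms. Corruptions: linear frequency drift
per transient index, Gaussian zero-order phase jitter, a shared
exponentially decaying eddy-current phase `a·e^{−t/τ}` (default decay
0.1 s), and outliers modelled as an amplitude gain times a large
(120°) phase excursion, emulating motion-corrupted transients.
`noise_sigma` is the per-component (real and imaginary) standard
deviation of each complex time sample, so a signal-free spectrum has
real-part RMS `σ√n`.

One global seed expands into independent substreams (noise, jitter) via
`SeedSequence.spawn`, so enabling one corruption never changes the
draws of another; identical configurations are bit-identical. fMRS
block designs scale per-peak amplitudes by per-block multipliers cycled
over blocks of fixed length. CSI grids scale a shared voxel FID by a
3D amplitude map (default: a centred ellipsoid "brain", so corner
voxels are empty) and use a centre-shifted spatial DFT whose
k-space/image round trip is exact to ~1e−15.

What the generator does **not** emulate: J-coupled multiplets and
realistic metabolite basis spectra (no density-matrix simulation),
macromolecule baselines, residual water tails, B₀ inhomogeneity
lineshape distortion, or frequency-dependent coil phase. Passing tests
therefore demonstrate correctness of the processing algebra and the
estimators under controlled corruption, not quantification accuracy on
in-vivo spectra.

## Processing nodes

**Coil combination.** The reference is the water acquisition when
supplied, else the input itself. `snr2` uses the first point of the
mean reference FID per channel and a per-channel noise σ estimated from
the last 10 % of FID samples; `svd` uses the first left singular vector
of the mean-reference channel×time matrix; `adaptive` solves the
generalized eigenproblem `R_s w = λ R_n w` with the signal covariance
from the leading 5 % of samples and the noise covariance from the tail
(Tikhonov-regularized at 1e−12·tr(R_s) so noiseless fixtures stay
solvable). The 10 %/5 % block sizes are implementation defaults; the
methods literature does not fix them. Weights are unit-norm and
globally phased so the combined reference FID starts real-positive;
channels with vanishing first-point signal get weight 0 with a warning.

**Frequency/phase alignment.** The reference is the point-wise median
spectrum (median of real and imaginary parts separately — robust to a
minority of outlier transients). For each transient the windowed
least-squares objective is minimized by a coarse 0.5 Hz frequency scan,
using at each candidate the analytically optimal zero-order phase
`φ* = arg⟨S_t, S_med⟩`, followed by bounded nonlinear least squares
(`Δf ∈ [−20, 20] Hz` by default, φ wrapped to (−180°, 180°]). Alignment
is one-shot against the median of the *input* spectra (not iterated).
Default windows: 1.6–3.6 ppm for ¹H (bracketing NAA at 2.02 ppm), full
axis otherwise. Non-convergent transients are left uncorrected with a
warning — in practice these are gross outliers that the bad-average
node removes next.

**Eddy-current correction** divides out the phase of the mean water
FID point-wise (Klose method). Where the water magnitude is below
machine precision the phase is held from the last valid point, so a
truncated water tail cannot inject noise phase.

**Bad-average removal** scores each transient by the RMS of its complex
difference from the mean over all transients, in the time domain, and
removes scores above `mean + k_sd·SD` in a single pass (k_sd = 3 by
default; the scoring is not iterated to convergence). Order and content
of kept transients are untouched; if the rule would remove everything
the input is returned with a warning.

**Apodization / zero filling.** Envelopes match the generator's
lineshape definitions so widths add exactly for matching shapes.
Zero filling appends exact zeros and rebuilds axes; by the
trigonometric-interpolation property the padded spectrum agrees with
the original on the original frequency grid, and apodization and zero
filling commute (the padded region is zero either way).

**Averaging.** Overall (arithmetic mean), blocked (consecutive blocks
of `meas_per_block` transients, `avgs_per_block` outputs per block from
consecutive groups, block types assigned cyclically and treated
independently — outputs grouped by type), and moving (stride-1 window,
`n − w + 1` outputs). Indivisible configurations raise errors naming
both numbers.

**Quality metrics.** SNR is the maximum real peak height in the signal
window (default 1.8–2.2 ppm) after a local zero-order phase rotation
maximizing it, divided by the RMS of the linearly detrended real part
of the noise window (default 0.2–0.5 ppm). Detrending guards against
baseline tilt leaking into the noise estimate. The water linewidth is
the full width at half maximum of the **absorption-mode** (locally
phased real) water peak with linear interpolation between bins,
reported in Hz and ppm. Absorption mode rather than magnitude is a
deliberate choice: the magnitude of a Lorentzian line is √3 wider than
the linewidth it is meant to report, so a magnitude measurement would
systematically overstate a 10 Hz line as 17.3 Hz.

**3D Hann filter.** Separable weights
`H(d) = 0.5·(1 + cos(2πd/(w−1)))`, `d = index − ⌊w/2⌋`, so the k-space
centre keeps weight exactly 1 and all weights lie in [0, 1]; for even
sizes the window is integer-aligned to the centre bin. Window
dimensions must equal the matrix dimensions (the CSI use case applies
exactly matrix-sized windows); the grid must be in k-space state. The
filter trades spatial resolution (strictly broadened point-spread
function, verified directly on 16×16×8) for SNR.

**Entropy-minimization phasing.** Cost
`E = −Σ h_j ln h_j + γ·Σ min(Re S, 0)²` with `h` the normalized
magnitude of the first derivative of the real part, evaluated on the
spectrum scaled to unit maximum magnitude; γ = 1000 keeps the
negativity penalty dominant whenever dispersion lobes exist while the
entropy term resolves the remainder. The phase model is
`exp(i(φ0 + φ1·(ppm − pivot)))` with the pivot at the carrier ppm.
Nelder-Mead is multi-started at φ0 ∈ {0°, 90°, 180°, 270°} to escape
the 180° ambiguity of entropy-based criteria. Recovery accuracy is
checked against an exhaustive 2-D grid search.

**Manual adjustment** applies a time-domain frequency shift and
zero/first-order phase; every call appends a timestamped line to the
run's adjustment log, which is written next to the executed pipeline
copy for traceability.

## Pipeline engine

Nodes declare a label, author/description, a typed parameter schema
with ranges and defaults, and a `process` hook; registration validates
the contract and rejects duplicate labels. Plugin files in one
designated folder are imported on rescan with the registry API injected
as `api` — no arbitrary-path imports. The state between nodes is a
list of `TransientSet`s: averaging nodes may expand it (one entry per
output spectrum, tagged with block/window metadata), all other nodes
map entries independently. The engine accepts DAGs (upstream lists)
but every shipped preset is a linear chain. Step and full execution
modes produce identical results; inputs are never mutated. The water
reference travels in the run context: the coil-combination node applies
the metabolite weights to it, eddy-current correction and quality
metrics consume it, and both skip with a logged notice when it is
absent.

`.pipe` files are canonical JSON (sorted keys, schema-versioned) so
save → load → save is byte-identical; loading validates node types and
parameter ranges. Batch mode creates/validates/processes the
study/participant folder convention; per-participant failures are
recorded as JSON lines (participant, node id, message) and never stop
the remaining participants. Batch results are bit-identical to a
single run on the same participant's files (note: *files* — NIfTI
stores the dwell time in a float32 header field, so a run on an
in-memory set can differ in the last bits from a run on its serialized
copy).

The five presets mirror the standard applications: (1) single-voxel ¹H
(adaptive combine → align → ECC → bad-average removal → average),
(2) fMRS (…→ blocked averaging), (3) single-voxel ³¹P (average →
entropy phasing; surface-coil data need no combination — the entropy
step is placed after averaging because it operates on a single
spectrum), (4) ³¹P CSI (Hann k-space weighting → 5 Hz Gaussian
broadening, via `presets.process_csi` since the CSI state is a spatial
grid rather than a transient list), and (5) GABA-edited MEGA data,
processed as direct averaging of sub-spectra with an optional manual
adjustment step; no ON−OFF subtraction node is shipped (it is a
natural custom node).

## I/O formats

NIfTI-MRS: single-voxel layout `(1,1,1,points,channels,transients)`
with `dim_5 = DIM_COIL`, `dim_6 = DIM_DYN`, dwell in `pixdim[4]`,
spectrometer frequency and nucleus in the JSON header extension
(ecode 44); data are written complex128 so round trips are exact well
inside the 1e−7 tolerance. Frequency-domain-tagged files are rejected.
LCModel RAW uses a minimal `$NMID` namelist (ID, FMTDAT, VOLUME,
TRAMP) and fixed `(2E16.6)` formatting, making writers byte-
deterministic. Control files are key=value namelist templates with
acquisition-derived keys (DELTAT, HZPPPM, NUNFIL) filled from the data
and overrides (e.g. WCONC) substituted in place, all other lines
preserved verbatim. COORD parsing targets the LCModel 6.3 text layout
(concentration table, FWHM/S-N line, ppm/data/fit/baseline curve
blocks), tolerant of column spacing; truncated files raise an error
listing the sections recovered. The COORD fixture writer used in tests
and fitter stubs is synthetic and exists only to exercise the parser.
Per-voxel CSI outputs live in 0-based `x_y_z` folders. A parameter CSV
(acquisition + pipeline provenance) is written with every output tree.

## Quantification

Voxel tissue fractions are the mean GM/WM/CSF probabilities over the
axis-aligned MRS voxel box (scanner-mm geometry through the volume
affine), renormalized to sum ≤ 1. Water concentration uses the
tissue-composition convention `WCONC = 55510·(0.78 f_GM + 0.65 f_WM +
0.97 f_CSF)/Σf` mM; T1/T2 relaxation attenuation factors are omitted,
and all four constants are arguments so field-strength-specific values
can be substituted. The external fitter is invoked as a subprocess when
a binary is configured (argument, `LCMODEL_BIN`, or PATH); otherwise
the run completes with the RAW and control files left in place and a
logged notice.

Metabolite maps include a voxel only when the CRLB of the selected
metabolite — and of the reference, when one is chosen — is *strictly*
below the threshold; raising the threshold can only grow the mask.
Ratio maps divide by the reference concentration on the mask.
Projection to an anatomical slice is bilinear with masked-out voxels
excluded from the interpolation support (normalized convolution:
masked values and mask are interpolated separately and divided), i.e.
mask-then-interpolate; an optional brain mask is applied afterwards.
Without an anatomical image the raw concentration matrix is returned
unchanged.

## Problem sizes and reproducibility

Tests and the acceptance script use 256–8192-point FIDs, 8–128
transients and 16×16×8 CSI grids — sizes at which every oracle
(exhaustive grid searches, direct PSF computation, closed forms) is
exact and the whole suite runs in well under a minute on one CPU. All
randomness flows from explicit seeds; `scripts/acceptance.py --seed N`
regenerates every synthetic input from N and recomputes all reported
quantities at run time.

## Known limitations

* No vendor raw readers (convert externally to NIfTI-MRS), no DICOM
  export, no B₀-map handling, no HSVD water removal, no time-domain
  model-based registration.
* The LCModel fitting algorithm is external by design; without a binary
  only the interchange files are produced.
* Alignment assumes the median spectrum is a faithful template; it
  degrades when more than half the transients share a common offset.
* Synthetic validation does not certify quantification accuracy on
  in-vivo data (see the generator's non-goals above).
* Map interpolation order (mask-then-interpolate) is a documented
  choice; tools that interpolate before masking will differ near mask
  edges.
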