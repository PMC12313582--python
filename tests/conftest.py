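import numpy as np
import pytest

from mrsflow.core import TransientSet
from mrsflow.simulate import Peak, SimConfig, simulate_transients, \
    simulate_water_reference

# Default single-voxel proton acquisition: 4 kHz bandwidth, 4096 points,
# 7 T proton frequency, short-TE style metabolite pattern.
N_POINTS = 2048
DWELL = 1.0 / 4000.0
F0 = 297.2

PROTON_PEAKS = [
    Peak(ppm=2.02, amplitude=100.0, lorentz_fwhm_hz=5.0),   # NAA CH3
    Peak(ppm=3.03, amplitude=70.0, lorentz_fwhm_hz=5.0),    # Cr CH3
    Peak(ppm=3.22, amplitude=50.0, lorentz_fwhm_hz=6.0),    # Cho
]


@pytest.fixture
def clean_config():
    return SimConfig(peaks=[Peak(2.02, 100.0, 5.0)], n_transients=8, seed=11)


@pytest.fixture
def proton_set():
    cfg = SimConfig(peaks=PROTON_PEAKS, n_transients=8, noise_sigma=0.2,
                    seed=3)
    return simulate_transients(cfg, n_points=N_POINTS, dwell=DWELL, f0=F0)


@pytest.fixture
def paired_water():
    """Metabolite + water sets sharing eddy phase and sensitivities."""
    cfg = SimConfig(peaks=PROTON_PEAKS, n_transients=8, noise_sigma=0.0,
                    eddy_amp_rad=0.8, eddy_decay_s=0.1, seed=7)
    metab = simulate_transients(cfg, n_points=N_POINTS, dwell=DWELL, f0=F0)
    water = simulate_water_reference(cfg, n_points=N_POINTS, dwell=DWELL,
                                     f0=F0)
    return metab, water


def single_peak_set(ppm=2.02, amplitude=100.0, lorentz=5.0, gauss=0.0,
                    n_transients=1, n_points=N_POINTS, dwell=DWELL, f0=F0,
                    **cfg_kw) -> TransientSet:
    cfg = SimConfig(peaks=[Peak(ppm, amplitude, lorentz, gauss)],
                    n_transients=n_transients, **cfg_kw)
    return simulate_transients(cfg, n_points=n_points, dwell=dwell, f0=f0)


def rms(x):
    return float(np.sqrt(np.mean(np.abs(np.asarray(x)) ** 2)))
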