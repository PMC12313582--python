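"""The five shipped pipeline presets.

1. Single-voxel 1H MRS: adaptive coil combination, frequency/phase
   alignment, eddy-current correction, bad-average removal, averaging.
2. Functional MRS: coil combination, alignment, eddy-current
   correction, blocked averaging (quantification per averaged set).
3. Single-voxel 31P MRS: averaging followed by entropy-minimization
   phasing (surface-coil acquisitions need no coil combination).
4. 31P MRSI: 3D Hanning k-space weighting and 5 Hz Gaussian line
   broadening (CSI path, see :func:`process_csi`).
5. GABA-edited (MEGA) MRS: treated as direct averaging of sub-spectra —
   the single-voxel chain plus an optional manual adjustment step.
"""
from __future__ import annotations

from .engine import PipelineSpec

__all__ = ["svs_1h", "fmrs", "p31_svs", "p31_csi", "gaba_mega",
           "PRESETS", "get_preset", "process_csi"]


def svs_1h() -> PipelineSpec:
    return PipelineSpec.chain([
        ("coil_combination", {"method": "adaptive"}),
        ("frequency_phase_alignment", {}),
        ("eddy_current_correction", {}),
        ("bad_average_removal", {"k_sd": 3.0}),
        ("averaging", {}),
    ], name="svs_1h")


def fmrs(meas_per_block: int = 16, avgs_per_block: int = 1,
         n_block_types: int = 2) -> PipelineSpec:
    return PipelineSpec.chain([
        ("coil_combination", {"method": "adaptive"}),
        ("frequency_phase_alignment", {}),
        ("eddy_current_correction", {}),
        ("blocked_averaging", {"meas_per_block": meas_per_block,
                               "avgs_per_block": avgs_per_block,
                               "n_block_types": n_block_types}),
    ], name="fmrs")


def p31_svs() -> PipelineSpec:
    return PipelineSpec.chain([
        ("averaging", {}),
        ("entropy_phasing", {}),
    ], name="p31_svs")


def p31_csi() -> PipelineSpec:
    # Chain mirror of the CSI path; executed via process_csi.
    return PipelineSpec.chain([
        ("apodization", {"shape": "gaussian", "width_hz": 5.0}),
    ], name="p31_csi")


def gaba_mega() -> PipelineSpec:
    return PipelineSpec.chain([
        ("coil_combination", {"method": "adaptive"}),
        ("frequency_phase_alignment", {}),
        ("eddy_current_correction", {}),
        ("bad_average_removal", {"k_sd": 3.0}),
        ("averaging", {}),
        ("manual_adjustment", {"freq_offset_hz": 0.0, "phi0_deg": 0.0,
                               "phi1_deg_per_ppm": 0.0}),
    ], name="gaba_mega")


PRESETS = {
    "svs_1h": svs_1h,
    "fmrs": fmrs,
    "p31_svs": p31_svs,
    "p31_csi": p31_csi,
    "gaba_mega": gaba_mega,
}


def get_preset(name: str) -> PipelineSpec:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{sorted(PRESETS)}")
    return PRESETS[name]()


def process_csi(csi, hanning: bool = True, apodize_width_hz: float = 5.0,
                apodize_shape: str = "gaussian"):
    """The 31P MRSI preset on a CsiGrid: Hanning k-space weighting then
    Gaussian line broadening, returning the image-space grid."""
    from .nodes import apodize_csi, hanning_filter_3d
    grid = csi.to_kspace()
    if hanning:
        grid = hanning_filter_3d(grid)
    grid = grid.to_image()
    if apodize_width_hz > 0:
        grid = apodize_csi(grid, shape=apodize_shape,
                           width_hz=apodize_width_hz)
    return grid
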