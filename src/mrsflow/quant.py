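"""Tissue-fraction water scaling, external-fitter invocation and
CRLB-thresholded metabolite maps.

The water concentration passed to the fitter (WCONC, mM) follows the
standard tissue-composition convention: pure water is 55,510 mM and the
apparent water content of gray matter, white matter and CSF is 0.78,
0.65 and 0.97 respectively.  Relaxation attenuation terms are omitted;
all four constants are overridable for users who need field-strength-
specific corrections.
"""
from __future__ import annotations

import os
import shutil
import subprocess
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import QuantResult, parse_coord

__all__ = [
    "TissueFractions", "MetaboliteMap", "CsiQuantGrid",
    "voxel_tissue_fractions", "water_concentration", "run_fitter",
    "metabolite_map", "project_to_anatomy",
    "PURE_WATER_MM", "WATER_CONTENT",
]

PURE_WATER_MM = 55510.0
WATER_CONTENT = {"gm": 0.78, "wm": 0.65, "csf": 0.97}


@dataclass
class TissueFractions:
    """Gray matter / white matter / CSF fractions of an MRS voxel."""

    f_gm: float
    f_wm: float
    f_csf: float

    def __post_init__(self):
        for name in ("f_gm", "f_wm", "f_csf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = self.f_gm + self.f_wm + self.f_csf
        if not (0.0 < total <= 1.0001):
            raise ValueError(f"fractions must sum into (0, 1.0001], "
                             f"got {total}")

    @property
    def total(self) -> float:
        return self.f_gm + self.f_wm + self.f_csf


def _volume_and_affine(vol):
    """Accept a nibabel image or a (ndarray, affine) pair or bare array."""
    if hasattr(vol, "get_fdata"):
        return np.asarray(vol.get_fdata()), np.asarray(vol.affine)
    if isinstance(vol, tuple):
        data, affine = vol
        return np.asarray(data, dtype=float), np.asarray(affine)
    return np.asarray(vol, dtype=float), np.eye(4)


def voxel_tissue_fractions(gm_vol, wm_vol, csf_vol, center_mm,
                           size_mm) -> TissueFractions:
    """Mean tissue probability of each class over the MRS voxel box.

    ``gm_vol``/``wm_vol``/``csf_vol`` are co-registered probability
    volumes (nibabel images, ``(array, affine)`` pairs, or bare arrays
    with an identity affine).  The voxel is an axis-aligned box of
    ``size_mm`` centred at ``center_mm`` in scanner coordinates.  The
    three means are renormalized to sum to at most 1.
    """
    gm, affine = _volume_and_affine(gm_vol)
    wm, affine_w = _volume_and_affine(wm_vol)
    csf, affine_c = _volume_and_affine(csf_vol)
    if not (gm.shape == wm.shape == csf.shape):
        raise ValueError(f"tissue volume shapes differ: "
                         f"{gm.shape}, {wm.shape}, {csf.shape}")
    if not (np.allclose(affine, affine_w) and np.allclose(affine, affine_c)):
        raise ValueError("tissue volumes are not co-registered "
                         "(affines differ)")
    center_mm = np.asarray(center_mm, dtype=float)
    half = np.asarray(size_mm, dtype=float) / 2.0
    inv = np.linalg.inv(affine)

    corners = np.array([center_mm + half * s for s in
                        np.array(np.meshgrid([-1, 1], [-1, 1], [-1, 1])
                                 ).T.reshape(-1, 3)])
    idx = (inv @ np.c_[corners, np.ones(len(corners))].T)[:3].T
    lo = np.floor(idx.min(axis=0) + 0.5).astype(int)
    hi = np.ceil(idx.max(axis=0) - 0.5).astype(int) + 1
    if np.any(lo < 0) or np.any(hi > np.array(gm.shape)):
        raise ValueError(f"MRS voxel box {lo}..{hi} extends outside the "
                         f"volume {gm.shape}")
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    f = np.array([gm[box].mean(), wm[box].mean(), csf[box].mean()])
    total = f.sum()
    if total > 1.0:
        f = f / total
    return TissueFractions(*np.clip(f, 0.0, 1.0))


def water_concentration(tf: TissueFractions,
                        pure_water_mm: float = PURE_WATER_MM,
                        content: dict | None = None) -> float:
    """Voxel water concentration in mM for the fitter's WCONC key.

    ``WCONC = 55510 * (0.78 f_gm + 0.65 f_wm + 0.97 f_csf) / (f_gm +
    f_wm + f_csf)``.
    """
    c = dict(WATER_CONTENT)
    if content:
        c.update(content)
    total = tf.total
    if total <= 0:
        raise ValueError("zero total tissue fraction")
    return pure_water_mm * (c["gm"] * tf.f_gm + c["wm"] * tf.f_wm
                            + c["csf"] * tf.f_csf) / total


# ---------------------------------------------------------------------------
# External fitter
# ---------------------------------------------------------------------------

def run_fitter(raw_path, control_path, basis_path=None, binary=None,
               out_dir=None, notices=None):
    """Invoke the external LCModel binary on prepared RAW/control files.

    The binary is looked up from ``binary``, the ``LCMODEL_BIN``
    environment variable, or ``lcmodel`` on PATH.  If absent the run
    degrades gracefully: a notice is logged, the RAW and control files
    stay in place, and ``None`` is returned.  On success the produced
    ``.COORD`` file is parsed to a :class:`QuantResult`.
    """
    from pathlib import Path
    raw_path = Path(raw_path)
    control_path = Path(control_path)
    out_dir = Path(out_dir) if out_dir is not None else raw_path.parent
    binary = binary or os.environ.get("LCMODEL_BIN") or shutil.which("lcmodel")
    if binary is None or not (os.path.isfile(binary)
                              and os.access(binary, os.X_OK)):
        msg = ("external fitter binary not configured; leaving RAW and "
               "control files in place for offline fitting")
        (notices.append(msg) if notices is not None
         else warnings.warn(msg))
        return None
    coord_path = out_dir / (raw_path.stem + ".COORD")
    with open(control_path) as fh:
        proc = subprocess.run([binary], stdin=fh, cwd=out_dir,
                              capture_output=True, text=True)
    if proc.returncode != 0:
        msg = (f"fitter exited with code {proc.returncode}: "
               f"{proc.stderr.strip()[:500]}")
        (notices.append(msg) if notices is not None
         else warnings.warn(msg))
        return None
    candidates = [coord_path] + sorted(out_dir.glob("*.COORD")) + \
        sorted(out_dir.glob("*.coord"))
    for c in candidates:
        if c.exists():
            return parse_coord(c)
    msg = "fitter produced no .COORD output"
    (notices.append(msg) if notices is not None else warnings.warn(msg))
    return None


# ---------------------------------------------------------------------------
# Metabolite maps
# ---------------------------------------------------------------------------

@dataclass
class CsiQuantGrid:
    """Per-voxel quantification results on a CSI matrix, 0-based image-
    space indexing matching the voxel output folders."""

    shape: tuple
    results: dict = field(default_factory=dict)  # (x, y, z) -> QuantResult

    def set(self, xyz, result: QuantResult):
        x, y, z = xyz
        if not (0 <= x < self.shape[0] and 0 <= y < self.shape[1]
                and 0 <= z < self.shape[2]):
            raise IndexError(f"voxel {xyz} outside grid {self.shape}")
        self.results[(x, y, z)] = result

    def get(self, xyz):
        return self.results.get(tuple(xyz))


@dataclass
class MetaboliteMap:
    """2D concentration (or ratio) slice with its reliability mask."""

    values: np.ndarray
    mask: np.ndarray
    orientation: str = "ax"
    slice_idx: int = 0
    scale: tuple | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values inside the mask")
        if self.scale is None:
            inside = self.values[self.mask]
            self.scale = ((float(inside.min()), float(inside.max()))
                          if inside.size else (0.0, 1.0))


_ORIENT_AXIS = {"ax": 2, "cor": 1, "sag": 0}


def metabolite_map(quant_grid: CsiQuantGrid, metabolite: str,
                   reference: str | None = None,
                   crlb_threshold_pct: float = 30.0,
                   orientation: str = "ax", slice_idx: int = 0,
                   as_ratio: bool = False) -> MetaboliteMap:
    """Build a 2D metabolite map from per-voxel fit results.

    A voxel is displayed only if the CRLB of the selected metabolite is
    strictly below the threshold — and, when a reference is chosen, the
    reference CRLB as well.  With ``as_ratio`` the values are
    metabolite / reference concentrations.
    """
    if as_ratio and reference is None:
        raise ValueError("as_ratio requires a reference metabolite")
    if orientation not in _ORIENT_AXIS:
        raise ValueError(f"orientation must be one of {list(_ORIENT_AXIS)}")
    axis = _ORIENT_AXIS[orientation]
    if not (0 <= slice_idx < quant_grid.shape[axis]):
        raise IndexError(f"slice {slice_idx} outside axis of length "
                         f"{quant_grid.shape[axis]}")
    plane_dims = [d for i, d in enumerate(quant_grid.shape) if i != axis]
    values = np.zeros(plane_dims)
    mask = np.zeros(plane_dims, dtype=bool)

    seen_metab = False
    for (x, y, z), res in quant_grid.results.items():
        coords = (x, y, z)
        if coords[axis] != slice_idx:
            try:
                res[metabolite]
                seen_metab = True
            except KeyError:
                pass
            continue
        ij = tuple(c for i, c in enumerate(coords) if i != axis)
        try:
            rec = res[metabolite]
            seen_metab = True
        except KeyError:
            continue
        ok = rec.concentration_sd_pct < crlb_threshold_pct
        if reference is not None:
            try:
                ref_rec = res[reference]
            except KeyError:
                continue
            ok = ok and ref_rec.concentration_sd_pct < crlb_threshold_pct
        if not ok:
            continue
        v = rec.concentration
        if as_ratio:
            if ref_rec.concentration == 0:
                continue
            v = rec.concentration / ref_rec.concentration
        values[ij] = v
        mask[ij] = True
    if not seen_metab:
        raise KeyError(f"metabolite {metabolite!r} not present in any voxel")
    return MetaboliteMap(values=values, mask=mask, orientation=orientation,
                         slice_idx=slice_idx)


def project_to_anatomy(mmap: MetaboliteMap, anat_slice=None,
                       brain_mask=None) -> MetaboliteMap:
    """Interpolate a metabolite map to the anatomical slice resolution.

    Bilinear interpolation with the masked-out voxels excluded from the
    interpolation support (normalized convolution: values and mask are
    interpolated separately and divided).  Without an anatomical slice
    the raw matrix is returned unchanged.
    """
    if anat_slice is None:
        return mmap
    anat_slice = np.asarray(anat_slice)
    if any(a < m for a, m in zip(anat_slice.shape, mmap.values.shape)):
        raise ValueError(f"anatomical slice {anat_slice.shape} smaller than "
                         f"map {mmap.values.shape}")
    if brain_mask is not None:
        brain_mask = np.asarray(brain_mask, dtype=bool)
        if brain_mask.shape != anat_slice.shape:
            raise ValueError("brain mask shape must match the anatomical "
                             "slice")
    from scipy.interpolate import RegularGridInterpolator
    ny, nx = mmap.values.shape
    ty, tx = anat_slice.shape
    # map each target pixel to source coordinates (edge-aligned)
    ys = np.linspace(0, ny - 1, ty)
    xs = np.linspace(0, nx - 1, tx)
    grid_y, grid_x = np.meshgrid(ys, xs, indexing="ij")
    pts = np.stack([grid_y.ravel(), grid_x.ravel()], axis=-1)

    interp_vals = RegularGridInterpolator(
        (np.arange(ny), np.arange(nx)),
        np.where(mmap.mask, mmap.values, 0.0), method="linear")
    interp_mask = RegularGridInterpolator(
        (np.arange(ny), np.arange(nx)),
        mmap.mask.astype(float), method="linear")
    num = interp_vals(pts).reshape(ty, tx)
    den = interp_mask(pts).reshape(ty, tx)
    out_mask = den > 0.5
    values = np.zeros((ty, tx))
    values[out_mask] = num[out_mask] / den[out_mask]
    if brain_mask is not None:
        out_mask &= brain_mask
        values = np.where(out_mask, values, 0.0)
    return MetaboliteMap(values=values, mask=out_mask,
                         orientation=mmap.orientation,
                         slice_idx=mmap.slice_idx, scale=mmap.scale)
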