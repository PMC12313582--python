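"""Readers and writers for on-disk formats.

* NIfTI-MRS (.nii/.nii.gz) with the JSON header extension (ecode 44):
  complex time-domain data in dims 4-6, dwell in ``pixdim[4]``,
  spectrometer frequency and nucleus in the extension.
* LCModel text dialects: .RAW data files, namelist control files, and
  .COORD result files (version 6.3 layout).
* The structured output tree written after a pipeline run.

All writers use fixed float formatting so identical inputs produce
byte-identical files.
"""
from __future__ import annotations

import io as _io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import TransientSet

__all__ = [
    "FormatError", "CoordRecord", "QuantResult",
    "read_nifti_mrs", "write_nifti_mrs",
    "write_lcmodel_raw", "read_lcmodel_raw",
    "generate_control_file", "parse_coord", "write_coord_fixture",
    "write_output_tree", "voxel_folder_name",
]

MRS_EXT_CODE = 44  # NIfTI-MRS header extension


class FormatError(ValueError):
    """Raised when a file does not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# NIfTI-MRS
# ---------------------------------------------------------------------------

def write_nifti_mrs(ts: TransientSet, path) -> Path:
    """Serialize a TransientSet as single-voxel NIfTI-MRS.

    Layout: shape ``(1, 1, 1, n_points, n_channels, n_transients)`` with
    ``dim_5 = DIM_COIL`` and ``dim_6 = DIM_DYN``; dwell time in
    ``pixdim[4]``; spectrometer frequency, nucleus and auxiliary fields
    in the JSON header extension.
    """
    import nibabel as nib
    path = Path(path)
    arr = ts.data.transpose(2, 1, 0)[None, None, None, ...].astype(
        np.complex128)
    img = nib.Nifti1Image(arr, affine=np.eye(4))
    img.header.set_data_dtype(np.complex128)
    img.header["pixdim"][4] = ts.dwell_time
    header = {
        "SpectrometerFrequency": [float(ts.f0)],
        "ResonantNucleus": [ts.nucleus],
        "dim_5": "DIM_COIL",
        "dim_6": "DIM_DYN",
        "RefPpm": float(ts.ref_ppm),
        "Role": ts.role,
        "AcqMeta": _jsonable(ts.acq_meta),
    }
    ext = nib.nifti1.Nifti1Extension(
        MRS_EXT_CODE, json.dumps(header, sort_keys=True).encode())
    img.header.extensions.append(ext)
    nib.save(img, str(path))
    return path


def read_nifti_mrs(path) -> TransientSet:
    """Load a NIfTI-MRS file written by :func:`write_nifti_mrs` (or any
    single-voxel file using the same dimension tags)."""
    import nibabel as nib
    path = Path(path)
    img = nib.load(str(path))
    header = None
    for ext in img.header.extensions:
        if ext.get_code() == MRS_EXT_CODE:
            content = ext.get_content()
            if isinstance(content, bytes):
                content = content.decode(errors="replace").rstrip("\x00")
            try:
                header = json.loads(content)
            except (TypeError, json.JSONDecodeError):
                header = content if isinstance(content, dict) else None
            break
    if header is None:
        raise FormatError(
            f"{path.name}: missing NIfTI-MRS header extension "
            f"(ecode {MRS_EXT_CODE}) with SpectrometerFrequency/"
            f"ResonantNucleus")
    if str(header.get("SpectralDomain", "time")).lower().startswith("freq"):
        raise FormatError(f"{path.name}: frequency-domain NIfTI-MRS data is "
                          "not supported; supply time-domain FIDs")
    for key in ("SpectrometerFrequency", "ResonantNucleus"):
        if key not in header:
            raise FormatError(f"{path.name}: header extension lacks {key}")
    arr = np.asanyarray(img.dataobj)
    if not np.iscomplexobj(arr):
        raise FormatError(f"{path.name}: expected complex time-domain data")
    while arr.ndim < 6:
        arr = arr[..., None]
    if arr.shape[:3] != (1, 1, 1):
        raise FormatError(f"{path.name}: expected single-voxel data, got "
                          f"spatial shape {arr.shape[:3]}")
    data = arr[0, 0, 0].transpose(2, 1, 0)  # -> [transient, channel, point]
    dwell = float(img.header["pixdim"][4])
    return TransientSet(
        data=np.ascontiguousarray(data.astype(np.complex128)),
        dwell_time=dwell,
        f0=float(header["SpectrometerFrequency"][0]),
        nucleus=str(header["ResonantNucleus"][0]),
        ref_ppm=header.get("RefPpm"),
        role=header.get("Role", "metabolite"),
        acq_meta=dict(header.get("AcqMeta", {})),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        if np.iscomplexobj(obj):
            return {"__complex_array__": [obj.real.tolist(),
                                          obj.imag.tolist()]}
        return obj.tolist()
    if isinstance(obj, complex):
        return {"__complex__": [obj.real, obj.imag]}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


# ---------------------------------------------------------------------------
# LCModel RAW
# ---------------------------------------------------------------------------

_RAW_FMT = "(2E16.6)"


def write_lcmodel_raw(ts: TransientSet, path, id_str: str | None = None,
                      volume: float = 1.0, tramp: float = 1.0) -> Path:
    """Write a single averaged FID in the LCModel RAW ASCII dialect.

    A ``$NMID`` namelist (ID, FMTDAT, VOLUME, TRAMP) is followed by one
    ``real imag`` pair per line in scientific notation with 6
    significant digits.
    """
    if ts.n_transients != 1 or ts.n_channels != 1:
        raise FormatError("RAW export requires a single averaged transient "
                          f"(got {ts.n_transients} transients, "
                          f"{ts.n_channels} channels)")
    path = Path(path)
    if id_str is None:
        id_str = ts.acq_meta.get("sequence", "mrsflow")
    fid = ts.data[0, 0]
    buf = _io.StringIO()
    buf.write(" $NMID\n")
    buf.write(f" ID='{id_str}'\n")
    buf.write(f" FMTDAT='{_RAW_FMT}'\n")
    buf.write(f" VOLUME={volume:.6g}\n")
    buf.write(f" TRAMP={tramp:.6g}\n")
    buf.write(" $END\n")
    for v in fid:
        buf.write(f"{v.real:16.6E}{v.imag:16.6E}\n")
    path.write_text(buf.getvalue())
    return path


def read_lcmodel_raw(path):
    """Parse a RAW file back to ``(complex FID, header dict)``."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header = {}
    data_start = None
    in_nmid = False
    for i, line in enumerate(lines):
        s = line.strip()
        if s.startswith("$NMID"):
            in_nmid = True
            continue
        if in_nmid:
            if s.startswith("$END"):
                data_start = i + 1
                break
            m = re.match(r"(\w+)\s*=\s*(.*)", s)
            if m:
                key, val = m.group(1), m.group(2).strip().rstrip(",")
                header[key] = val.strip("'\"")
    if data_start is None:
        raise FormatError(f"{path.name}: no $NMID...$END header found")
    values = []
    for line in lines[data_start:]:
        parts = line.split()
        if len(parts) < 2:
            continue
        values.append(complex(float(parts[0]), float(parts[1])))
    if not values:
        raise FormatError(f"{path.name}: no data points after header")
    return np.array(values, dtype=complex), header


# ---------------------------------------------------------------------------
# LCModel control files
# ---------------------------------------------------------------------------

_CONTROL_KEYMAP = {
    "basis": "FILBAS",
    "ppmst": "PPMST",
    "ppmend": "PPMEND",
    "deltat": "DELTAT",
    "hzpppm": "HZPPPM",
    "nunfil": "NUNFIL",
    "water_conc": "WCONC",
    "echot": "ECHOT",
}


def _control_value(key: str, value) -> str:
    if isinstance(value, str):
        return f"'{value}'"
    if isinstance(value, bool):
        return ".TRUE." if value else ".FALSE."
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return np.format_float_scientific(float(value), precision=6, trim="-")


def generate_control_file(template: str, overrides: dict | None = None,
                          ts: TransientSet | None = None) -> str:
    """Substitute fitting parameters into an LCModel namelist template.

    ``overrides`` uses friendly keys (``basis``, ``ppmst``, ``ppmend``,
    ``deltat``, ``hzpppm``, ``nunfil``, ``water_conc``, ``echot``) or
    raw namelist keys.  When ``ts`` is given, the acquisition-derived
    keys DELTAT (dwell s), HZPPPM (f0 MHz) and NUNFIL (points) are
    filled from it.  Existing template lines are preserved verbatim
    unless their key is overridden; new keys are inserted before $END.
    """
    lines = template.splitlines()
    start = end = None
    for i, line in enumerate(lines):
        s = line.strip().upper()
        if s.startswith("$LCMODL"):
            start = i
        elif s.startswith("$END") and start is not None:
            end = i
            break
    if start is None or end is None:
        raise FormatError("malformed control template: no $LCMODL...$END "
                          "namelist found")

    subs: dict[str, str] = {}
    if ts is not None:
        subs["DELTAT"] = _control_value("DELTAT", ts.dwell_time)
        subs["HZPPPM"] = _control_value("HZPPPM", ts.f0)
        subs["NUNFIL"] = _control_value("NUNFIL", ts.n_points)
    for key, value in (overrides or {}).items():
        name = _CONTROL_KEYMAP.get(key.lower(), key.upper())
        subs[name] = _control_value(name, value)
    if not subs:
        return template

    out = list(lines)
    seen = set()
    for i in range(start + 1, end):
        m = re.match(r"\s*(\w+)\s*=", lines[i])
        if m and m.group(1).upper() in subs:
            name = m.group(1).upper()
            out[i] = f" {name} = {subs[name]}"
            seen.add(name)
    insert = [f" {name} = {val}" for name, val in subs.items()
              if name not in seen]
    out[end:end] = insert
    text = "\n".join(out)
    if template.endswith("\n"):
        text += "\n"
    return text


# ---------------------------------------------------------------------------
# LCModel COORD
# ---------------------------------------------------------------------------

@dataclass
class CoordRecord:
    """One metabolite row of a COORD concentration table."""

    metabolite: str
    concentration: float
    concentration_sd_pct: float  # CRLB %
    ratio_to_reference: float

    def __post_init__(self):
        if self.concentration_sd_pct < 0:
            raise ValueError("CRLB must be >= 0")


@dataclass
class QuantResult:
    """Quantification result parsed from one COORD file."""

    records: list = field(default_factory=list)
    snr: float = float("nan")
    fwhm_ppm: float = float("nan")
    ppm: np.ndarray | None = None
    data_curve: np.ndarray | None = None
    fit_curve: np.ndarray | None = None
    baseline_curve: np.ndarray | None = None

    def __post_init__(self):
        for name in ("data_curve", "fit_curve", "baseline_curve"):
            arr = getattr(self, name)
            if arr is not None and self.ppm is not None and \
                    len(arr) != len(self.ppm):
                raise ValueError("curve arrays must share the ppm length")

    def concentration(self, metabolite: str) -> float:
        return self[metabolite].concentration

    def crlb(self, metabolite: str) -> float:
        return self[metabolite].concentration_sd_pct

    def __getitem__(self, metabolite: str) -> CoordRecord:
        for rec in self.records:
            if rec.metabolite == metabolite:
                return rec
        raise KeyError(metabolite)

    @property
    def metabolites(self):
        return [r.metabolite for r in self.records]


def write_coord_fixture(result: QuantResult, path,
                        version: str = "6.3-1L") -> Path:
    """Emit a synthetic COORD file in the LCModel 6.3 text layout.

    Used to build test fixtures and fitter stubs; :func:`parse_coord`
    inverts it exactly.
    """
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f" LCModel (Version {version})  Copyright ...\n\n")
    n = len(result.records)
    buf.write(f"  {n + 1} lines in following concentration table = NCONC+1\n")
    buf.write("  Conc.  %SD   /Cr+PCr   Metabolite\n")
    for rec in result.records:
        buf.write(f"  {rec.concentration:10.3E} {rec.concentration_sd_pct:3.0f}%"
                  f" {rec.ratio_to_reference:9.3E}  {rec.metabolite}\n")
    buf.write(f" FWHM = {result.fwhm_ppm:6.3f} ppm    S/N = {result.snr:6.1f}\n")
    if result.ppm is not None:
        ny = len(result.ppm)
        buf.write(f" {ny} points on ppm-axis = NY\n")
        _write_curve(buf, result.ppm)
        for label, arr in (("NY phased data points follow", result.data_curve),
                           ("NY points of the fit to the data follow",
                            result.fit_curve),
                           ("NY background values follow",
                            result.baseline_curve)):
            if arr is not None:
                buf.write(f" {label}\n")
                _write_curve(buf, arr)
    path.write_text(buf.getvalue())
    return path


def _write_curve(buf, arr, per_line: int = 10):
    arr = np.asarray(arr, dtype=float)
    for i in range(0, len(arr), per_line):
        buf.write("".join(f"{v:13.5E}" for v in arr[i:i + per_line]) + "\n")


_FLOAT_RE = re.compile(r"[-+]?\d*\.?\d+(?:[EeDd][-+]?\d+)?")


def parse_coord(path) -> QuantResult:
    """Parse an LCModel .COORD file (6.3 layout, tolerant of spacing).

    Extracts the concentration table, the S/N and FWHM line, and the
    ppm/data/fit/baseline curve blocks when present.  A truncated file
    raises :class:`FormatError` listing the sections recovered so far.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    recovered = []
    result = QuantResult()

    i = 0
    # concentration table
    while i < len(lines) and "Metabolite" not in lines[i]:
        i += 1
    if i == len(lines):
        raise FormatError(f"{path.name}: truncated COORD file; recovered "
                          f"sections: {recovered or ['none']}")
    i += 1
    while i < len(lines):
        line = lines[i]
        if "FWHM" in line:
            break
        m = re.match(
            r"\s*([-+0-9.EeDd]+)\s+([0-9.]+)%\s+([-+0-9.EeDd]+)\s+(\S+)",
            line)
        if m:
            result.records.append(CoordRecord(
                metabolite=m.group(4),
                concentration=float(m.group(1).replace("D", "E")),
                concentration_sd_pct=float(m.group(2)),
                ratio_to_reference=float(m.group(3).replace("D", "E"))))
        i += 1
    recovered.append("concentrations")

    if i == len(lines):
        raise FormatError(f"{path.name}: truncated COORD file; recovered "
                          f"sections: {recovered}")
    m = re.search(r"FWHM\s*=\s*([-\d.]+)\s*ppm", lines[i])
    if m:
        result.fwhm_ppm = float(m.group(1))
    m = re.search(r"S/N\s*=\s*([-\d.]+)", lines[i])
    if m:
        result.snr = float(m.group(1))
    recovered.append("quality")
    i += 1

    # curve blocks
    def read_block(start, count):
        vals = []
        j = start
        while j < len(lines) and len(vals) < count:
            vals.extend(float(v) for v in _FLOAT_RE.findall(lines[j]))
            j += 1
        if len(vals) < count:
            raise FormatError(
                f"{path.name}: truncated COORD file; recovered sections: "
                f"{recovered}")
        return np.array(vals[:count]), j

    while i < len(lines):
        line = lines[i]
        m = re.search(r"(\d+)\s+points on ppm-axis", line)
        if m:
            ny = int(m.group(1))
            result.ppm, i = read_block(i + 1, ny)
            recovered.append("ppm-axis")
            continue
        if "phased data points follow" in line:
            result.data_curve, i = read_block(i + 1, len(result.ppm))
            recovered.append("data")
            continue
        if "fit to the data follow" in line:
            result.fit_curve, i = read_block(i + 1, len(result.ppm))
            recovered.append("fit")
            continue
        if "background values follow" in line:
            result.baseline_curve, i = read_block(i + 1, len(result.ppm))
            recovered.append("baseline")
            continue
        i += 1
    return result


# ---------------------------------------------------------------------------
# Output tree
# ---------------------------------------------------------------------------

def voxel_folder_name(x: int, y: int, z: int) -> str:
    """0-based, underscore-separated CSI voxel folder name."""
    return f"{x}_{y}_{z}"


def _step_plot(ts: TransientSet, path: Path, title: str):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from .core import spectra_matrix
    fig, ax = plt.subplots(figsize=(6, 3.2))
    if ts.n_channels == 1:
        spec = spectra_matrix(ts).mean(axis=0)
    else:
        spec = np.fft.fftshift(
            np.fft.fft(ts.data.mean(axis=(0, 1))))[::-1]
    ax.plot(ts.ppm_axis, spec.real, lw=0.7)
    ax.invert_xaxis()
    ax.set_xlabel("ppm")
    ax.set_ylabel("real")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def write_step_artifacts(ts_list, step_dir: Path, save_plots: bool = True):
    """Per-step outputs: averaged RAW + NIfTI-MRS (+ diagnostic PDF)."""
    step_dir = Path(step_dir)
    step_dir.mkdir(parents=True, exist_ok=True)
    from .nodes import average_all
    for j, ts in enumerate(ts_list):
        stem = f"data_{j}" if len(ts_list) > 1 else "data"
        write_nifti_mrs(ts, step_dir / f"{stem}.nii")
        if ts.n_channels == 1:
            write_lcmodel_raw(average_all(ts), step_dir / f"{stem}.RAW")
        if save_plots:
            _step_plot(ts, step_dir / f"{stem}.pdf", step_dir.name)
    return step_dir


def write_parameter_csv(run, path: Path):
    """Acquisition + pipeline provenance fields as a one-row CSV."""
    import pandas as pd
    ts = run.final[0] if run.final else None
    row = {
        "pipeline_name": run.pipeline.name,
        "pipeline_version": run.pipeline.version,
        "n_steps": len(run.pipeline.nodes),
        "node_types": ";".join(n.node_type for n in run.pipeline.nodes),
    }
    if ts is not None:
        row.update({
            "nucleus": ts.nucleus,
            "f0_mhz": ts.f0,
            "dwell_s": ts.dwell_time,
            "n_points": ts.n_points,
            "ref_ppm": ts.ref_ppm,
            "te_ms": ts.acq_meta.get("te_ms"),
            "tr_ms": ts.acq_meta.get("tr_ms"),
            "sequence": ts.acq_meta.get("sequence"),
        })
    pd.DataFrame([row]).to_csv(path, index=False)
    return path


def write_output_tree(run, out_dir, save_intermediate: bool = False) -> Path:
    """Write the structured result tree of a completed pipeline run.

    Always contains the executed pipeline copy (``pipeline.pipe``), the
    manual-adjustment log, the parameter CSV, the final outputs and an
    ``LCModel/`` folder with RAW files ready for fitting; per-step
    subfolders with spectra and diagnostic plots are added when
    ``save_intermediate`` is on.
    """
    from .engine import save_pipe
    from .nodes import average_all
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    save_pipe(run.pipeline, out_dir / "pipeline.pipe")
    log_path = out_dir / "manual_adjustments.log"
    log_path.write_text("\n".join(run.adjustments) + "\n"
                        if run.adjustments else "")
    write_parameter_csv(run, out_dir / "parameters.csv")

    if save_intermediate:
        for k, (node_id, node_type, state) in enumerate(run.steps, start=1):
            write_step_artifacts(state, out_dir / f"{k}_{node_type}")

    lcm_dir = out_dir / "LCModel"
    lcm_dir.mkdir(exist_ok=True)
    for j, ts in enumerate(run.final):
        stem = f"final_{j}" if len(run.final) > 1 else "final"
        write_nifti_mrs(ts, out_dir / f"{stem}.nii")
        if ts.n_channels == 1:
            write_lcmodel_raw(average_all(ts), lcm_dir / f"{stem}.RAW")
    return out_dir
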