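"""Node registry, pipeline graph execution, .pipe serialization,
custom-node plugin contract and batch-mode orchestration.

A pipeline is an ordered list of :class:`NodeSpec` entries forming a
DAG (the shipped presets are simple chains).  The state flowing between
nodes is a list of :class:`TransientSet` objects — averaging nodes may
expand the list (blocked / moving averaging produce one set per output
spectrum) and every other node maps each element independently.

The ``.pipe`` on-disk dialect is canonical JSON (sorted keys, schema
versioned) so save -> load -> save is byte-identical.
"""
from __future__ import annotations

import importlib.util
import json
import sys
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nodes as _ops
from .core import TransientSet, fid_to_spectrum

__all__ = [
    "ParamSpec", "Node", "PluginNode", "NodeSpec", "PipelineSpec",
    "register_node", "unregister_node", "list_nodes", "get_node",
    "scan_plugin_dir", "RegisterNode",
    "save_pipe", "load_pipe", "run_pipeline", "RunResult",
    "make_batch_folder", "validate_batch_folder", "run_batch",
    "PIPE_SCHEMA_VERSION",
]

PIPE_SCHEMA_VERSION = 1


class PipelineError(ValueError):
    """Invalid pipeline definition or node registration."""


# ---------------------------------------------------------------------------
# Parameter schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamSpec:
    """Declared node parameter: type, default and admissible range."""

    type: type
    default: object = None
    min: float | None = None
    max: float | None = None
    choices: tuple | None = None

    def validate(self, name: str, value):
        if value is None:
            return self.default
        if self.type in (int, float) and isinstance(value, (int, float)) \
                and not isinstance(value, bool):
            value = self.type(value)
        if not isinstance(value, self.type):
            raise PipelineError(
                f"parameter {name!r}: expected {self.type.__name__}, "
                f"got {type(value).__name__}")
        if self.choices is not None and value not in self.choices:
            raise PipelineError(
                f"parameter {name!r}: {value!r} not in {self.choices}")
        if self.min is not None and value < self.min:
            raise PipelineError(
                f"parameter {name!r}: {value} below minimum {self.min}")
        if self.max is not None and value > self.max:
            raise PipelineError(
                f"parameter {name!r}: {value} above maximum {self.max}")
        return value


class Node:
    """Base class for processing nodes.

    Subclasses declare ``label`` (unique registry name), ``author`` and
    ``description``, a ``PARAMS`` schema mapping parameter names to
    :class:`ParamSpec`, and implement
    ``process(state: list[TransientSet], params, ctx) -> list[TransientSet]``.
    An optional ``plot(state, params, ctx)`` hook may return matplotlib
    figure data for diagnostics.
    """

    label: str = ""
    author: str = ""
    description: str = ""
    PARAMS: dict = {}

    def resolve_params(self, params: dict | None) -> dict:
        params = dict(params or {})
        unknown = set(params) - set(self.PARAMS)
        if unknown:
            raise PipelineError(
                f"node {self.label!r}: undeclared parameters {sorted(unknown)}")
        return {name: spec.validate(name, params.get(name))
                for name, spec in self.PARAMS.items()}

    def process(self, state, params, ctx):  # pragma: no cover - abstract
        raise NotImplementedError


#: Alias matching the documented plugin contract (api.RegisterNode).
PluginNode = Node


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, type] = {}


def register_node(node_cls: type) -> type:
    """Register a node class under its label.

    The class must satisfy the plugin contract: identifying information
    (label; author/description may be empty strings but must exist), a
    parameter schema of :class:`ParamSpec`, and a ``process`` hook.  A
    duplicate label is rejected.
    """
    if not isinstance(node_cls, type) or not issubclass(node_cls, Node):
        raise PipelineError("register_node expects a Node subclass")
    label = getattr(node_cls, "label", "")
    if not label:
        raise PipelineError("node must declare a non-empty label")
    if label in _REGISTRY:
        raise PipelineError(f"node label {label!r} already registered")
    if node_cls.process is Node.process:
        raise PipelineError(f"node {label!r} must implement a process hook")
    for pname, pspec in node_cls.PARAMS.items():
        if not isinstance(pspec, ParamSpec):
            raise PipelineError(
                f"node {label!r}: parameter {pname!r} must be a ParamSpec")
    _REGISTRY[label] = node_cls
    return node_cls


#: Plugin-facing alias per the custom-node contract.
RegisterNode = register_node


def unregister_node(label: str):
    _REGISTRY.pop(label, None)


def list_nodes() -> list[str]:
    return sorted(_REGISTRY)


def get_node(label: str) -> Node:
    if label not in _REGISTRY:
        raise PipelineError(f"unknown node type {label!r}; registered: "
                            f"{list_nodes()}")
    return _REGISTRY[label]()


def scan_plugin_dir(directory) -> list[str]:
    """Import every ``*.py`` file in the designated plugin folder.

    Plugin modules register their nodes at import time via
    ``mrsflow.engine.RegisterNode`` (exposed to them as the attribute
    ``api`` injected into the module namespace).  Returns the labels
    newly registered.  Only the one designated directory is scanned; no
    arbitrary-path imports.
    """
    directory = Path(directory)
    before = set(_REGISTRY)
    for py in sorted(directory.glob("*.py")):
        name = f"mrsflow_plugin_{py.stem}"
        spec = importlib.util.spec_from_file_location(name, py)
        module = importlib.util.module_from_spec(spec)
        module.api = sys.modules[__name__]
        sys.modules[name] = module
        spec.loader.exec_module(module)
    return sorted(set(_REGISTRY) - before)


# ---------------------------------------------------------------------------
# Built-in nodes
# ---------------------------------------------------------------------------

@register_node
class CoilCombinationNode(Node):
    label = "coil_combination"
    description = "Combine receiver channels (adaptive / snr2 / svd)"
    PARAMS = {"method": ParamSpec(str, "adaptive",
                                  choices=("adaptive", "snr2", "svd"))}

    def process(self, state, params, ctx):
        out = []
        for ts in state:
            combined, w = _ops.coil_combine(ts, method=params["method"],
                                            water_ref=ctx.water)
            out.append(combined)
        if ctx.water is not None and ctx.water.n_channels > 1:
            combined_water = np.einsum("c,tcp->tp", w,
                                       ctx.water.data)[:, None, :]
            ctx.water = ctx.water.replace(data=combined_water)
        return out


@register_node
class FrequencyPhaseAlignmentNode(Node):
    label = "frequency_phase_alignment"
    description = ("Align transients to the median spectrum in a ppm window "
                   "(NAA at 2.02 ppm by default for 1H)")
    PARAMS = {
        "ppm_min": ParamSpec(float, None),
        "ppm_max": ParamSpec(float, None),
        "max_shift_hz": ParamSpec(float, 20.0, min=0.1, max=500.0),
    }

    def process(self, state, params, ctx):
        rng = None
        if params["ppm_min"] is not None and params["ppm_max"] is not None:
            rng = (params["ppm_min"], params["ppm_max"])
        out = []
        for ts in state:
            if ts.n_transients < 2:
                out.append(ts)
                continue
            aligned, result = _ops.align_frequency_phase(
                ts, ppm_range=rng, max_shift_hz=params["max_shift_hz"])
            ctx.alignments.append(result)
            out.append(aligned)
        return out


@register_node
class EddyCurrentCorrectionNode(Node):
    label = "eddy_current_correction"
    description = "Klose eddy-current correction using the water reference"
    PARAMS = {}

    def process(self, state, params, ctx):
        if ctx.water is None:
            ctx.log("eddy_current_correction skipped: no water reference")
            return state
        return [_ops.eddy_current_correct(ts, ctx.water) for ts in state]


@register_node
class BadAverageRemovalNode(Node):
    label = "bad_average_removal"
    description = "Remove outlier transients scored by RMS deviation"
    PARAMS = {"k_sd": ParamSpec(float, 3.0, min=0.0)}

    def process(self, state, params, ctx):
        out = []
        for ts in state:
            if ts.n_transients < 3:
                out.append(ts)
                continue
            kept, idx = _ops.remove_bad_averages(ts, k_sd=params["k_sd"])
            ctx.kept_indices.append(idx)
            out.append(kept)
        return out


@register_node
class ApodizationNode(Node):
    label = "apodization"
    description = "Lorentzian or Gaussian line broadening"
    PARAMS = {
        "shape": ParamSpec(str, "lorentzian",
                           choices=("lorentzian", "gaussian")),
        "width_hz": ParamSpec(float, 1.0, min=0.0),
    }

    def process(self, state, params, ctx):
        return [_ops.apodize(ts, shape=params["shape"],
                             width_hz=params["width_hz"]) for ts in state]


@register_node
class ZeroFillingNode(Node):
    label = "zero_filling"
    description = "Extend FIDs with zeros for finer spectral sampling"
    PARAMS = {"factor": ParamSpec(int, 2, min=1, max=16)}

    def process(self, state, params, ctx):
        return [_ops.zero_fill(ts, factor=params["factor"]) for ts in state]


@register_node
class AveragingNode(Node):
    label = "averaging"
    description = "Average all transients into one spectrum"
    PARAMS = {}

    def process(self, state, params, ctx):
        return [_ops.average_all(ts) for ts in state]


@register_node
class BlockedAveragingNode(Node):
    label = "blocked_averaging"
    description = "Average within experimental blocks, grouped by block type"
    PARAMS = {
        "meas_per_block": ParamSpec(int, 16, min=1),
        "avgs_per_block": ParamSpec(int, 1, min=1),
        "n_block_types": ParamSpec(int, 1, min=1),
    }

    def process(self, state, params, ctx):
        out = []
        for ts in state:
            out.extend(_ops.blocked_average(
                ts, meas_per_block=params["meas_per_block"],
                avgs_per_block=params["avgs_per_block"],
                n_block_types=params["n_block_types"]))
        return out


@register_node
class MovingAveragingNode(Node):
    label = "moving_averaging"
    description = "Sliding-window averaging with stride 1"
    PARAMS = {"window_length": ParamSpec(int, 5, min=1)}

    def process(self, state, params, ctx):
        out = []
        for ts in state:
            out.extend(_ops.moving_average(
                ts, window_length=params["window_length"]))
        return out


@register_node
class QualityMetricsNode(Node):
    label = "quality_metrics"
    description = "SNR of the metabolite spectrum and water-peak FWHM"
    PARAMS = {
        "signal_ppm_min": ParamSpec(float, None),
        "signal_ppm_max": ParamSpec(float, None),
        "noise_ppm_min": ParamSpec(float, None),
        "noise_ppm_max": ParamSpec(float, None),
    }

    def process(self, state, params, ctx):
        if ctx.water is None:
            ctx.log("quality_metrics skipped: no water reference")
            return state
        sig = None
        if params["signal_ppm_min"] is not None:
            sig = (params["signal_ppm_min"], params["signal_ppm_max"])
        noi = None
        if params["noise_ppm_min"] is not None:
            noi = (params["noise_ppm_min"], params["noise_ppm_max"])
        from .nodes import average_all
        water_spec = fid_to_spectrum(average_all(ctx.water))
        for ts in state:
            metab_spec = fid_to_spectrum(average_all(ts))
            ctx.metrics.append(_ops.quality_metrics(
                metab_spec, water_spec, nucleus=ts.nucleus,
                signal_ppm=sig, noise_ppm=noi))
        return state


@register_node
class EntropyPhasingNode(Node):
    label = "entropy_phasing"
    description = ("Automatic zero/first-order phasing by entropy "
                   "minimization (X-nuclei spectra)")
    PARAMS = {"gamma": ParamSpec(float, 1000.0, min=0.0)}

    def process(self, state, params, ctx):
        out = []
        for ts in state:
            if ts.n_transients != 1:
                raise PipelineError("entropy_phasing expects averaged data "
                                    "(one transient); average first")
            spec = fid_to_spectrum(ts)
            phi0, phi1, corrected = _ops.entropy_min_phase(
                spec, gamma=params["gamma"])
            ctx.log(f"entropy_phasing: phi0={phi0:.2f} deg, "
                    f"phi1={phi1:.3f} deg/ppm")
            from .core import spectrum_to_fid
            out.append(ts.replace(
                data=spectrum_to_fid(corrected)[None, None, :]))
        return out


@register_node
class ManualAdjustmentNode(Node):
    label = "manual_adjustment"
    description = "User-specified frequency offset and zero/first-order phase"
    PARAMS = {
        "freq_offset_hz": ParamSpec(float, 0.0),
        "phi0_deg": ParamSpec(float, 0.0),
        "phi1_deg_per_ppm": ParamSpec(float, 0.0),
    }

    def process(self, state, params, ctx):
        return [_ops.manual_adjust(ts, params["freq_offset_hz"],
                                   params["phi0_deg"],
                                   params["phi1_deg_per_ppm"],
                                   log=ctx.adjustment_log) for ts in state]


# ---------------------------------------------------------------------------
# Pipeline definition and .pipe serialization
# ---------------------------------------------------------------------------

@dataclass
class NodeSpec:
    node_id: str
    node_type: str
    params: dict = field(default_factory=dict)
    upstream: list = field(default_factory=list)


@dataclass
class PipelineSpec:
    nodes: list
    name: str = "pipeline"
    version: int = PIPE_SCHEMA_VERSION

    def validate(self):
        seen = set()
        for spec in self.nodes:
            if spec.node_id in seen:
                raise PipelineError(f"duplicate node id {spec.node_id!r}")
            node = get_node(spec.node_type)  # raises on unknown type
            node.resolve_params(spec.params)
            for up in spec.upstream:
                if up not in seen:
                    raise PipelineError(
                        f"node {spec.node_id!r}: upstream {up!r} not defined "
                        "earlier (cycle or missing node)")
            seen.add(spec.node_id)
        return self

    @classmethod
    def chain(cls, steps, name="pipeline"):
        """Build a linear pipeline from (node_type, params) pairs."""
        nodes = []
        prev = None
        for i, (node_type, params) in enumerate(steps):
            node_id = f"{i}_{node_type}"
            nodes.append(NodeSpec(node_id=node_id, node_type=node_type,
                                  params=dict(params),
                                  upstream=[prev] if prev else []))
            prev = node_id
        return cls(nodes=nodes, name=name).validate()


def pipe_to_json(pipeline: PipelineSpec) -> str:
    doc = {
        "format": "pipe",
        "schema_version": pipeline.version,
        "name": pipeline.name,
        "nodes": [
            {"node_id": n.node_id, "node_type": n.node_type,
             "params": n.params, "upstream": list(n.upstream)}
            for n in pipeline.nodes
        ],
    }
    return json.dumps(doc, sort_keys=True, indent=2) + "\n"


def save_pipe(pipeline: PipelineSpec, path) -> Path:
    path = Path(path)
    path.write_text(pipe_to_json(pipeline))
    return path


def load_pipe(path) -> PipelineSpec:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise PipelineError(f"{path.name}: not a valid .pipe file: {exc}")
    if doc.get("format") != "pipe":
        raise PipelineError(f"{path.name}: missing 'format: pipe' marker")
    nodes = [NodeSpec(node_id=n["node_id"], node_type=n["node_type"],
                      params=dict(n.get("params", {})),
                      upstream=list(n.get("upstream", [])))
             for n in doc.get("nodes", [])]
    pipeline = PipelineSpec(nodes=nodes, name=doc.get("name", "pipeline"),
                            version=doc.get("schema_version",
                                            PIPE_SCHEMA_VERSION))
    return pipeline.validate()


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

class RunContext:
    """Mutable context shared by nodes during one run."""

    def __init__(self, water=None, adjustment_log=None):
        self.water = water
        self.adjustment_log = adjustment_log or _ops.AdjustmentLog()
        self.metrics = []
        self.alignments = []
        self.kept_indices = []
        self.messages = []

    def log(self, message: str):
        self.messages.append(message)


@dataclass
class RunResult:
    pipeline: PipelineSpec
    final: list
    steps: list            # (node_id, node_type, state-after) per node
    context: RunContext

    @property
    def adjustments(self):
        return self.context.adjustment_log.entries

    @property
    def metrics(self):
        return self.context.metrics


def run_pipeline(ts, pipeline: PipelineSpec, mode: str = "full",
                 water_ref=None, out_dir=None, save_intermediate: bool = False,
                 step_callback=None) -> RunResult:
    """Execute a pipeline on a TransientSet (or list of them).

    ``mode='step'`` fires ``step_callback(node_id, state)`` after each
    node; both modes produce identical final data.  When ``out_dir`` is
    given, a copy of the executed pipeline is always written there and,
    with ``save_intermediate``, per-step artifact folders as well.
    Inputs are never mutated.
    """
    if mode not in ("step", "full"):
        raise PipelineError(f"mode must be 'step' or 'full', got {mode!r}")
    pipeline.validate()
    initial = list(ts) if isinstance(ts, (list, tuple)) else [ts]
    ctx = RunContext(water=water_ref.replace() if water_ref is not None
                     else None)

    outputs: dict[str, list] = {}
    steps = []
    downstream_used = set()
    for spec in pipeline.nodes:
        for up in spec.upstream:
            downstream_used.add(up)

    for spec in pipeline.nodes:
        if spec.upstream:
            state = []
            for up in spec.upstream:
                state.extend(outputs[up])
        else:
            state = initial
        node = get_node(spec.node_type)
        params = node.resolve_params(spec.params)
        try:
            result = node.process(state, params, ctx)
        except Exception as exc:
            raise PipelineError(
                f"node {spec.node_id!r} ({spec.node_type}) failed: {exc}"
            ) from exc
        outputs[spec.node_id] = result
        steps.append((spec.node_id, spec.node_type, result))
        if mode == "step" and step_callback is not None:
            step_callback(spec.node_id, result)

    if pipeline.nodes:
        final = []
        for spec in pipeline.nodes:
            if spec.node_id not in downstream_used:
                final.extend(outputs[spec.node_id])
    else:
        final = initial
    run = RunResult(pipeline=pipeline, final=final, steps=steps, context=ctx)

    if out_dir is not None:
        from .io import write_output_tree
        write_output_tree(run, out_dir, save_intermediate=save_intermediate)
    return run


# ---------------------------------------------------------------------------
# Batch mode
# ---------------------------------------------------------------------------

SUPPORTED_METABOLITE_SUFFIXES = (".nii", ".nii.gz")


def _is_supported(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in SUPPORTED_METABOLITE_SUFFIXES)


def make_batch_folder(root, study_name: str, n_participants: int) -> Path:
    """Create the structured batch tree for a study.

    ``STUDY_NAME/`` with placeholder ``STUDY_NAME.control`` and
    ``STUDY_NAME.basis`` files plus ``PARTICIPANT_k/`` directories the
    user fills with ``<FILENAME>_metabolite`` (required),
    ``<FILENAME>_water_reference`` (optional) and an optional
    ``tissue_segmentation_files/`` folder.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if any(sep in study_name for sep in ("/", "\\", "\0")) or \
            study_name in ("", ".", ".."):
        raise ValueError(f"invalid study name {study_name!r}")
    root = Path(root)
    study = root / study_name
    if study.exists() and any(study.iterdir()):
        raise FileExistsError(f"{study} exists and is not empty")
    study.mkdir(parents=True, exist_ok=True)
    (study / f"{study_name}.control").write_text(
        "; placeholder - replace with the LCModel control file\n")
    (study / f"{study_name}.basis").write_text(
        "; placeholder - replace with the LCModel basis set\n")
    for k in range(1, n_participants + 1):
        (study / f"PARTICIPANT_{k}").mkdir()
    return study


@dataclass
class ParticipantReport:
    name: str
    metabolite: Path | None = None
    water_reference: Path | None = None
    tissue_dir: Path | None = None
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def runnable(self) -> bool:
        return self.metabolite is not None and not self.errors


@dataclass
class BatchReport:
    root: Path
    control: Path | None
    basis: Path | None
    participants: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (self.control is not None and self.basis is not None
                and all(p.runnable for p in self.participants))


def validate_batch_folder(root) -> BatchReport:
    """Check a batch tree for required files; report-only, never raises
    for content problems."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(root)
    control = next(iter(sorted(root.glob("*.control"))), None)
    basis = next(iter(sorted(root.glob("*.basis"))), None)
    report = BatchReport(root=root, control=control, basis=basis)
    if control is None:
        report.warnings.append("missing study .control file")
    if basis is None:
        report.warnings.append("missing study .basis file")
    for pdir in sorted(root.glob("PARTICIPANT_*")):
        if not pdir.is_dir():
            continue
        p = ParticipantReport(name=pdir.name)
        metab = sorted(f for f in pdir.iterdir()
                       if f.is_file() and "_metabolite" in f.name)
        water = sorted(f for f in pdir.iterdir()
                       if f.is_file() and "_water_reference" in f.name)
        if not metab:
            p.errors.append("missing required *_metabolite file")
        else:
            p.metabolite = metab[0]
            if not _is_supported(metab[0]):
                p.warnings.append(
                    f"unsupported metabolite format {metab[0].suffix!r}; "
                    f"supported: {SUPPORTED_METABOLITE_SUFFIXES} "
                    "(convert vendor data externally, e.g. with spec2nii)")
        if water:
            p.water_reference = water[0]
        tdir = pdir / "tissue_segmentation_files"
        if tdir.is_dir():
            p.tissue_dir = tdir
            for fname in ("WM_prob.nii", "GM_prob.nii", "CSF_prob.nii"):
                if not (tdir / fname).exists():
                    p.warnings.append(f"tissue segmentation missing {fname}")
        report.participants.append(p)
    return report


def run_batch(root, pipeline: PipelineSpec, out_root=None,
              save_intermediate: bool = False):
    """Apply one pipeline to every runnable participant.

    Failures are recorded — one JSON line per failure in
    ``batch_errors.jsonl`` under ``out_root`` — and the remaining
    participants keep processing.  Returns
    ``(results: dict name -> RunResult, errors: list of dict)``.
    """
    from .io import read_nifti_mrs
    root = Path(root)
    report = validate_batch_folder(root)
    runnable = [p for p in report.participants if p.runnable
                and _is_supported(p.metabolite)]
    if not runnable:
        raise PipelineError("no runnable participants in batch folder")
    out_root = Path(out_root) if out_root is not None else root / "output"
    out_root.mkdir(parents=True, exist_ok=True)

    results = {}
    errors = []
    for p in report.participants:
        if not (p.runnable and _is_supported(p.metabolite)):
            errors.append({"participant": p.name, "node_id": None,
                           "message": "; ".join(p.errors + p.warnings)
                           or "not runnable"})
            continue
        try:
            ts = read_nifti_mrs(p.metabolite)
            water = (read_nifti_mrs(p.water_reference)
                     if p.water_reference is not None else None)
            run = run_pipeline(ts, pipeline, water_ref=water,
                               out_dir=out_root / p.name,
                               save_intermediate=save_intermediate)
            results[p.name] = run
        except Exception as exc:
            node_id = None
            if isinstance(exc, PipelineError):
                import re as _re
                m = _re.search(r"node '([^']+)'", str(exc))
                node_id = m.group(1) if m else None
            errors.append({"participant": p.name, "node_id": node_id,
                           "message": str(exc)})
    ledger = out_root / "batch_errors.jsonl"
    with open(ledger, "w") as fh:
        for entry in errors:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    return results, errors
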