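"""Configuration, trace I/O, synthetic fixtures and run manifests.

Configuration files are flat ``key = value`` text with dotted namespaces
(``exc.g_l``, ``synapses.gaba_e.g_max`` ...); an empty file yields the full
default parameter set, and unknown keys are rejected with their line number.
Traces round-trip through HDF5 or tab-separated text with a unit header.
The fixture generators synthesise voltage-clamp recordings, rate traces with
planted events, and GHK I-V samples with known ground truth for testing the
analysis operations without experimental data.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

from . import __version__
from .analysis import (ClampRecordingSet, IVTemplates, ghk_current,
                       model_templates)
from .ion_channels import ExcitatoryParams, InterneuronParams
from .network import (NetworkConfig, OUParams, StimulusTrain, TRACE_CHANNELS,
                      TraceSet)
from .synapses import (DepressionParams, GapJunctionDef, PROJECTION_ORDER,
                       ProjectionDef)

__all__ = [
    "RunManifest",
    "FixtureSpec",
    "load_config",
    "save_config",
    "config_to_flat",
    "write_traces",
    "read_traces",
    "generate_fixture",
]

TRACE_FORMAT_VERSION = 1

_SIMPLE_FIELDS = {f.name for f in dataclasses.fields(NetworkConfig)
                  if f.name not in ("exc", "inh", "synapses", "depression",
                                    "gap", "ou", "stimulus")}
_NESTED = {
    "exc": ExcitatoryParams,
    "inh": InterneuronParams,
    "depression": DepressionParams,
    "gap": GapJunctionDef,
    "ou": OUParams,
    "stimulus": StimulusTrain,
}
_PROJ_FIELDS = ("g_max", "tau_rise", "tau_decay")


def config_to_flat(config: NetworkConfig) -> dict:
    """Flatten a NetworkConfig into dotted ``key -> value`` pairs."""
    flat = {}
    for name in sorted(_SIMPLE_FIELDS):
        flat[name] = getattr(config, name)
    for ns, _ in _NESTED.items():
        obj = getattr(config, ns)
        if obj is None:
            continue
        for f in dataclasses.fields(obj):
            flat[f"{ns}.{f.name}"] = getattr(obj, f.name)
    for pname in PROJECTION_ORDER:
        proj = config.synapses[pname]
        for f in _PROJ_FIELDS:
            flat[f"synapses.{pname.lower()}.{f}"] = getattr(proj, f)
    return flat


def _parse_value(text: str, current):
    text = text.strip()
    if isinstance(current, bool):
        if text.lower() in ("true", "1", "yes", "on"):
            return True
        if text.lower() in ("false", "0", "no", "off"):
            return False
        raise ValueError(f"expected boolean, got {text!r}")
    if isinstance(current, int) and not isinstance(current, bool):
        return int(float(text))
    return float(text)


def load_config(path) -> NetworkConfig:
    """Read a flat key-value configuration file.

    Missing keys keep their defaults; unknown or malformed entries raise
    with the offending line number and key name.
    """
    cfg = NetworkConfig()
    overrides: dict[str, object] = {}
    nested: dict[str, dict] = {}
    proj: dict[str, dict] = {}
    defaults = config_to_flat(replace(cfg, stimulus=StimulusTrain()))
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in defaults:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            try:
                parsed = _parse_value(value, defaults[key])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad value for {key!r}: {exc}") from exc
            parts = key.split(".")
            if len(parts) == 1:
                overrides[key] = parsed
            elif parts[0] == "synapses":
                proj.setdefault(parts[1], {})[parts[2]] = parsed
            else:
                nested.setdefault(parts[0], {})[parts[1]] = parsed
    for ns, kv in nested.items():
        base = getattr(cfg, ns)
        if base is None:  # stimulus
            base = StimulusTrain()
        overrides[ns] = replace(base, **kv)
    if proj:
        synapses = dict(cfg.synapses)
        for pname, kv in proj.items():
            synapses[pname.upper()] = replace(synapses[pname.upper()], **kv)
        overrides["synapses"] = synapses
    return replace(cfg, **overrides)


def save_config(config: NetworkConfig, path) -> None:
    lines = [f"{k} = {v}" for k, v in config_to_flat(config).items()]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RunManifest:
    """Provenance record binding outputs to a configuration and seed."""

    protocol: str
    seed: int
    config_flat: dict
    outputs: list = field(default_factory=list)
    package_version: str = __version__
    wall_time_s: float = 0.0
    created: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str) + "\n")

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# trace I/O
# ---------------------------------------------------------------------------

def write_traces(trace: TraceSet, path, channels=None) -> None:
    """Write a TraceSet to HDF5 (``.h5``/``.hdf5``) or TSV (anything else).

    ``channels`` optionally restricts the output to a subset (time is always
    included).
    """
    path = Path(path)
    names = [n for n, _ in TRACE_CHANNELS]
    if channels is not None:
        keep = ["time"] + [c for c in channels if c != "time"]
    else:
        keep = names
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.attrs["format_version"] = TRACE_FORMAT_VERSION
            fh.attrs["meta"] = json.dumps(trace.meta, default=str)
            for name in keep:
                ds = fh.create_dataset(name, data=trace[name])
                ds.attrs["units"] = trace.units[name]
    else:
        header = "\t".join(f"{n}[{trace.units[n]}]" for n in keep)
        meta = json.dumps({"format_version": TRACE_FORMAT_VERSION, **trace.meta},
                          default=str)
        data = np.column_stack([trace[n] for n in keep])
        np.savetxt(path, data, delimiter="\t", header=f"{meta}\n{header}")


def read_traces(path) -> TraceSet:
    """Read a trace file written by :func:`write_traces` (lossless round trip).

    Channels absent from the file are filled with NaN.
    """
    path = Path(path)
    names = [n for n, _ in TRACE_CHANNELS]
    units = dict(TRACE_CHANNELS)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            version = int(fh.attrs.get("format_version", -1))
            meta = json.loads(fh.attrs.get("meta", "{}"))
            n = len(fh["time"])
            data = np.full((len(names), n), np.nan)
            for i, name in enumerate(names):
                if name in fh:
                    data[i] = fh[name][:]
                    units[name] = fh[name].attrs.get("units", units[name])
    else:
        with open(path) as fh:
            meta_line = fh.readline().lstrip("# ").strip()
            header = fh.readline().lstrip("# ").strip().split("\t")
        meta = json.loads(meta_line)
        version = int(meta.pop("format_version", -1))
        cols = [h.split("[")[0] for h in header]
        raw = np.loadtxt(path, skiprows=2, ndmin=2)
        data = np.full((len(names), raw.shape[0]), np.nan)
        for j, col in enumerate(cols):
            if col in names:
                data[names.index(col)] = raw[:, j]
    if version != TRACE_FORMAT_VERSION:
        import warnings
        warnings.warn(f"trace format version {version} != {TRACE_FORMAT_VERSION}")
    return TraceSet(data, units=units, meta=meta)


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic test fixture with stored ground truth."""

    kind: str                    # clamp_recording | rate_trace | iv_points
    seed: int = 0
    noise_sd: float = 0.0        # Gaussian noise SD (units of the signal)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("clamp_recording", "rate_trace", "iv_points"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def _alpha_kernel(t, onset, tau):
    s = np.clip(t - onset, 0.0, None) / tau
    return s * np.exp(1.0 - s)


def generate_fixture(spec: FixtureSpec):
    """Generate a synthetic fixture; the returned object carries its ground truth.

    - ``clamp_recording``: multi-potential current traces synthesised from
      prescribed conductance waveforms through the template forward model;
      returns a :class:`ClampRecordingSet`.
    - ``rate_trace``: a TraceSet-like dict with boxcar rate events planted at
      known times.
    - ``iv_points``: GHK forward-model samples with known internal chloride;
      returns ``(points, ground_truth)``.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    if spec.kind == "clamp_recording":
        duration = p.get("duration_ms", 300.0)
        dt = p.get("sample_interval_ms", 1.0)
        v_gaba = p.get("v_gaba", -50.0)
        mg = p.get("mg", 0.25)
        potentials = np.asarray(p.get("potentials", (-87.0, -57.0, -27.0, 3.0)), float)
        t = np.arange(0.0, duration, dt)
        g_true = {
            "g_ampa": p.get("peak_ampa", 2.0) * _alpha_kernel(t, 50.0, 10.0),
            "g_gaba": p.get("peak_gaba", 8.0) * _alpha_kernel(t, 40.0, 15.0),
            "g_nmda": p.get("peak_nmda", 1.5) * _alpha_kernel(t, 60.0, 40.0),
        }
        templates = model_templates(v_gaba, mg)
        currents = np.empty((len(t), len(potentials)))
        for j, v in enumerate(potentials):
            f = templates.at(v)
            currents[:, j] = (g_true["g_ampa"] * f[0] + g_true["g_gaba"] * f[1]
                              + g_true["g_nmda"] * f[2])
        if spec.noise_sd > 0:
            currents = currents + rng.normal(0.0, spec.noise_sd, currents.shape)
        return ClampRecordingSet(potentials, currents, dt,
                                 ground_truth={"time": t, **g_true,
                                               "templates": templates})
    if spec.kind == "rate_trace":
        duration = p.get("duration_ms", 60000.0)
        dt = p.get("sample_interval_ms", 1.0)
        onsets = np.asarray(p.get("onsets_ms", np.arange(2000.0, duration, 4000.0)), float)
        width = p.get("width_ms", 100.0)
        amp = p.get("amplitude_hz", 50.0)
        t = np.arange(0.0, duration, dt)
        nu_i = np.zeros_like(t)
        for onset in onsets:
            nu_i[(t >= onset) & (t < onset + width)] = amp
        if spec.noise_sd > 0:
            nu_i = np.clip(nu_i + rng.normal(0.0, spec.noise_sd, nu_i.shape), 0.0, None)
        return {"time": t, "nu_I": nu_i, "nu_E": np.zeros_like(t),
                "onsets": onsets, "width_ms": width}
    # iv_points
    cl_in = p.get("cl_in", 20.0)
    cl_out = p.get("cl_out", 132.5)
    temperature = p.get("temperature_c", 30.0)
    scale = p.get("p_scale", 0.5)
    voltages = np.asarray(p.get("voltages", np.arange(-90.0, 1.0, 10.0)), float)
    currents = ghk_current(voltages, scale, cl_in, cl_out, temperature)
    if spec.noise_sd > 0:
        currents = currents + rng.normal(0.0, spec.noise_sd, currents.shape)
    frt = 96485.332 / (8.314462 * (273.15 + temperature)) / 1000.0
    truth = {"cl_in": cl_in, "cl_out": cl_out, "p_scale": scale,
             "v_gaba": np.log(cl_in / cl_out) / frt}
    return np.column_stack([voltages, currents]), truth

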