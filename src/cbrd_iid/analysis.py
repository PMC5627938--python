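"""Trace analysis: discharge detection and statistics, conductance ratios,
voltage-clamp conductance decomposition and GHK reversal-potential fitting.

The detection/classification conventions follow the physiology of the two
discharge types: events are detected on the interneuron population rate with
a hysteresis threshold; an event during which the pyramidal population also
fires is classed IID2 (GABA-initiated, glutamate-maintained), otherwise IID1
(purely GABAergic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, nnls

from .synapses import nmda_block

__all__ = [
    "DetectionThresholds",
    "EventTable",
    "IVTemplates",
    "ClampRecordingSet",
    "detect_events",
    "event_statistics",
    "conductance_ratios",
    "model_templates",
    "decompose_conductances",
    "ghk_current",
    "fit_vgaba_ghk",
]

EVENT_COLUMNS = ["onset", "offset", "duration", "peak_nu_i", "peak_nu_e",
                 "peak_i_clamp", "peak_g_ampa", "peak_g_nmda", "peak_g_gaba",
                 "event_class"]

FARADAY_RT = {  # F/RT in 1/mV at common bath temperatures
    25.0: 1.0 / 25.69,
    30.0: 1.0 / 26.12,
    35.0: 1.0 / 26.55,
}


def _f_over_rt(temperature_c: float) -> float:
    return 96485.332 / (8.314462 * (273.15 + temperature_c)) / 1000.0  # 1/mV


@dataclass(frozen=True)
class DetectionThresholds:
    """Hysteresis detector settings on the interneuron rate trace (Hz)."""

    on: float = 10.0
    off: float = 2.0
    min_duration: float = 10.0   # ms
    merge_gap: float = 50.0      # ms
    class_nu_e: float = 2.0      # Hz; peak E rate separating IID2 from IID1


class EventTable(pd.DataFrame):
    """Detected discharge events (non-overlapping, ordered by onset)."""

    @property
    def _constructor(self):
        return EventTable


def detect_events(trace, thresholds: DetectionThresholds | None = None) -> EventTable:
    """Hysteresis detection of discharges on the interneuron rate.

    ``trace`` is a TraceSet (or any mapping with ``time``/``nu_I``/``nu_E``
    and optional conductance and clamp channels, uniformly sampled).
    """
    thr = thresholds or DetectionThresholds()
    t = np.asarray(trace["time"], dtype=float)
    if len(t) == 0:
        raise ValueError("empty trace")
    nu_i = np.asarray(trace["nu_I"], dtype=float)
    dt = t[1] - t[0] if len(t) > 1 else 1.0

    events = []
    inside = False
    onset = 0.0
    for i in range(len(t)):
        if not inside and nu_i[i] >= thr.on:
            inside = True
            onset = t[i]
        elif inside and nu_i[i] < thr.off:
            inside = False
            events.append([onset, t[i]])
    if inside:
        events.append([onset, t[-1]])

    # merge events separated by less than the merge gap
    merged = []
    for ev in events:
        if merged and ev[0] - merged[-1][1] < thr.merge_gap:
            merged[-1][1] = ev[1]
        else:
            merged.append(ev)
    merged = [ev for ev in merged if ev[1] - ev[0] >= thr.min_duration]

    def channel(name):
        try:
            return np.asarray(trace[name], dtype=float)
        except (KeyError, ValueError, IndexError):
            return None

    nu_e = channel("nu_E")
    i_clamp = channel("I_clamp")
    g_a, g_n, g_g = channel("g_AMPA_E"), channel("g_NMDA_E"), channel("g_GABA_E")

    rows = []
    for onset, offset in merged:
        idx = (t >= onset) & (t <= offset)
        peak_e = float(np.max(nu_e[idx])) if nu_e is not None else 0.0
        rows.append({
            "onset": onset,
            "offset": offset,
            "duration": offset - onset,
            "peak_nu_i": float(np.max(nu_i[idx])),
            "peak_nu_e": peak_e,
            "peak_i_clamp": float(np.max(np.abs(i_clamp[idx]))) if i_clamp is not None else np.nan,
            "peak_g_ampa": float(np.max(g_a[idx])) if g_a is not None else np.nan,
            "peak_g_nmda": float(np.max(g_n[idx])) if g_n is not None else np.nan,
            "peak_g_gaba": float(np.max(g_g[idx])) if g_g is not None else np.nan,
            "event_class": "IID2" if peak_e > thr.class_nu_e else "IID1",
        })
    return EventTable(rows, columns=EVENT_COLUMNS)


def event_statistics(events: pd.DataFrame, duration_ms: float) -> dict:
    """Frequency, inter-event-interval CV, mean duration and amplitude.

    Frequency is events per second over the full record; the CV is the
    SD/mean of inter-onset intervals (NaN if fewer than two events, flagged
    with ``cv_defined``).
    """
    n = len(events)
    freq = n / (duration_ms / 1000.0)
    if n >= 2:
        intervals = np.diff(np.asarray(events["onset"], dtype=float))
        cv = float(np.std(intervals) / np.mean(intervals))
        cv_defined = True
    else:
        cv, cv_defined = float("nan"), False
    return {
        "n_events": n,
        "frequency_hz": freq,
        "cv_intervals": cv,
        "cv_defined": cv_defined,
        "mean_duration_ms": float(events["duration"].mean()) if n else float("nan"),
        "mean_amplitude_pa": float(events["peak_i_clamp"].mean()) if n else float("nan"),
    }


def conductance_ratios(events: pd.DataFrame) -> pd.DataFrame:
    """Per-event ratios of within-event conductance maxima to the GABA peak.

    Events with zero GABA peak are skipped.  Adds the across-event mean and
    SD as summary attributes ``.attrs['summary']``.
    """
    ok = events[events["peak_g_gaba"] > 0].copy()
    ok["ampa_over_gaba"] = ok["peak_g_ampa"] / ok["peak_g_gaba"]
    ok["nmda_over_gaba"] = ok["peak_g_nmda"] / ok["peak_g_gaba"]
    out = pd.DataFrame(ok[["onset", "event_class", "ampa_over_gaba", "nmda_over_gaba"]])
    out.attrs["summary"] = {
        "ampa_over_gaba": (float(out["ampa_over_gaba"].mean()),
                           float(out["ampa_over_gaba"].std(ddof=1)) if len(out) > 1 else 0.0),
        "nmda_over_gaba": (float(out["nmda_over_gaba"].mean()),
                           float(out["nmda_over_gaba"].std(ddof=1)) if len(out) > 1 else 0.0),
    }
    return out


@dataclass(frozen=True)
class IVTemplates:
    """Tabulated unit-conductance I-V relationships of the three mediators."""

    voltages: np.ndarray
    f_ampa: np.ndarray
    f_gaba: np.ndarray
    f_nmda: np.ndarray

    def __post_init__(self):
        for a in (self.f_ampa, self.f_gaba, self.f_nmda):
            if not np.all(np.isfinite(a)):
                raise ValueError("templates must be finite")

    def at(self, v: float) -> np.ndarray:
        """Template column [f_AMPA, f_GABA, f_NMDA] at holding potential v."""
        return np.array([np.interp(v, self.voltages, self.f_ampa),
                         np.interp(v, self.voltages, self.f_gaba),
                         np.interp(v, self.voltages, self.f_nmda)])


def model_templates(v_gaba: float, mg: float = 0.25,
                    v_grid: np.ndarray | None = None) -> IVTemplates:
    """Templates implied by the model's reversal potentials and Mg block:
    f_AMPA(V) = V, f_GABA(V) = V - V_GABA, f_NMDA(V) = V * block(V)."""
    v = np.linspace(-100.0, 40.0, 281) if v_grid is None else np.asarray(v_grid, float)
    return IVTemplates(v, v.copy(), v - v_gaba, v * nmda_block(v, mg))


@dataclass
class ClampRecordingSet:
    """Time-aligned voltage-clamp current traces at several holding potentials."""

    potentials: np.ndarray       # mV
    currents: np.ndarray         # (n_samples, n_potentials), pA
    sample_interval: float       # ms
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if len(self.potentials) < 3:
            raise ValueError("need recordings at >= 3 holding potentials")
        if self.currents.shape[1] != len(self.potentials):
            raise ValueError("current array column count mismatch")


def decompose_conductances(recordings: ClampRecordingSet,
                           templates: IVTemplates,
                           bin_ms: float = 1.0):
    """Nonnegative least-squares decomposition of clamp currents into
    g_AMPA(t), g_GABA(t), g_NMDA(t).

    For each time bin the currents across holding potentials form an I-V
    curve that is fitted as a weighted sum of the mediator templates, the
    conductances being the weights.  Returns a DataFrame with the three
    conductance series and the per-bin residual norm.
    """
    A = np.column_stack([templates.at(v) for v in recordings.potentials]).T
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError(
            "template matrix is rank deficient at holding potentials "
            f"{recordings.potentials.tolist()}; choose more informative potentials")
    stride = max(1, int(round(bin_ms / recordings.sample_interval)))
    n_bins = recordings.currents.shape[0] // stride
    out = np.empty((n_bins, 5))
    for b in range(n_bins):
        i_v = recordings.currents[b * stride:(b + 1) * stride].mean(axis=0)
        g, res = nnls(A, i_v)
        out[b] = (b * stride * recordings.sample_interval, g[0], g[1], g[2], res)
    return pd.DataFrame(out, columns=["time", "g_ampa", "g_gaba", "g_nmda", "residual"])


def ghk_current(v, p_scale: float, cl_in: float, cl_out: float,
                temperature_c: float = 30.0):
    """GHK current of a monovalent anion (outward positive), arbitrary scale.

    ``p_scale`` lumps permeability, area and unit conversions; the zero
    crossing sits at the Nernst potential of the fitted concentrations.
    """
    v = np.asarray(v, dtype=float)
    frt = _f_over_rt(temperature_c)
    x = v * frt
    num = cl_in - cl_out * np.exp(x)
    den = -np.expm1(x)
    small = np.abs(x) < 1e-8
    body = np.divide(x * num, den, out=np.zeros_like(x), where=~small)
    # x -> 0 limit (second order): (cl_out - cl_in) + x (cl_in + cl_out) / 2
    body = np.where(small, (cl_out - cl_in) + 0.5 * x * (cl_in + cl_out), body)
    out = p_scale * body
    return float(out) if out.ndim == 0 else out


def fit_vgaba_ghk(iv_points, temperature_c: float = 30.0,
                  cl_out: float = 132.5):
    """Fit the GHK anion-current equation to I-V points and report V_GABA.

    ``iv_points`` is a sequence of (V mV, I pA) pairs spanning the reversal.
    Free parameters are the permeability scale and the internal chloride
    concentration; the reported reversal is the Nernst potential of the
    fitted concentrations.  Returns a dict with ``v_gaba``, ``cl_in``,
    ``p_scale`` and fit metadata.
    """
    pts = np.asarray(iv_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        raise ValueError("need >= 4 (V, I) points")
    v, i = pts[:, 0], pts[:, 1]
    if np.min(i) >= 0 or np.max(i) <= 0:
        raise ValueError("I-V points do not span the reversal (no sign change)")

    # linear zero crossing as initial guess for the reversal
    order = np.argsort(v)
    v_s, i_s = v[order], i[order]
    k = np.argmax(i_s > 0) if i_s[0] < 0 else np.argmax(i_s < 0)
    v0 = v_s[k - 1] - i_s[k - 1] * (v_s[k] - v_s[k - 1]) / (i_s[k] - i_s[k - 1])
    frt = _f_over_rt(temperature_c)
    cl0 = cl_out * math.exp(v0 * frt)
    slope = (i_s[-1] - i_s[0]) / (v_s[-1] - v_s[0])
    p0 = max(slope / max(cl_out, 1.0), 1e-6)

    def model(vv, p_scale, cl_in):
        return ghk_current(vv, p_scale, cl_in, cl_out, temperature_c)

    popt, _ = curve_fit(model, v, i, p0=[p0, cl0],
                        bounds=([0.0, 1e-3], [np.inf, 10.0 * cl_out]),
                        maxfev=20000)
    p_scale, cl_in = popt
    v_rev = math.log(cl_in / cl_out) / frt
    return {
        "v_gaba": v_rev,
        "cl_in": cl_in,
        "p_scale": p_scale,
        "cl_out": cl_out,
        "temperature_c": temperature_c,
        "parameterization": "GHK current equation, monovalent anion",
    }
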