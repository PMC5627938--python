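"""Synaptic conductance kinetics, NMDA magnesium block, short-term depression
and gap-junction coupling.

Each projection's dimensionless conductance m follows damped second-order
kinetics driven by the presynaptic population rate, with a saturation factor
(1 - m).  The drive time scale tau_s is normalised so that the peak response
to a brief presynaptic volley is independent of the rise/decay constants.
Short-term depression is a presynaptic resource per mediator class (one
glutamatergic, one GABAergic) that multiplies all conductances of that class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K

__all__ = [
    "ProjectionDef",
    "SynapseState",
    "DepressionParams",
    "GapJunctionDef",
    "PROJECTION_ORDER",
    "default_projections",
    "normalize_tau",
    "advance_m",
    "nmda_block",
    "advance_depression",
    "assemble_conductances",
    "gap_junction_current",
]

#: canonical projection order used throughout the package
PROJECTION_ORDER = ("AMPA_E", "NMDA_E", "GABA_E", "AMPA_I", "NMDA_I", "GABA_I")


def normalize_tau(tau_rise: float, tau_decay: float) -> float:
    """Drive time scale making the impulse-response peak of m equal to the
    presynaptic volley area, independent of (tau_rise, tau_decay)."""
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("time constants must be positive")
    if abs(tau_rise - tau_decay) < 1e-9 * max(tau_rise, tau_decay):
        return tau_rise * math.e
    r = tau_decay / tau_rise
    d = tau_rise - tau_decay
    return d / (r ** (tau_decay / d) - r ** (tau_rise / d))


@dataclass(frozen=True)
class ProjectionDef:
    """One synaptic projection (mediator onto a target population)."""

    mediator: str          # AMPA | NMDA | GABA
    target: str            # E | I
    g_max: float           # mS/cm^2
    tau_rise: float        # ms
    tau_decay: float       # ms

    def __post_init__(self):
        if self.mediator not in ("AMPA", "NMDA", "GABA"):
            raise ValueError("mediator must be AMPA, NMDA or GABA")
        if self.target not in ("E", "I"):
            raise ValueError("target must be E or I")
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("time constants must be positive")
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")

    @property
    def tau_s(self) -> float:
        return normalize_tau(self.tau_rise, self.tau_decay)

    @property
    def presynaptic(self) -> str:
        return "I" if self.mediator == "GABA" else "E"


def default_projections() -> dict:
    """The six projections with their default maximal conductances and kinetics."""
    return {
        "AMPA_E": ProjectionDef("AMPA", "E", 0.6, 1.7, 8.3),
        "NMDA_E": ProjectionDef("NMDA", "E", 0.6, 6.7, 100.0),
        "GABA_E": ProjectionDef("GABA", "E", 0.5, 0.5, 20.0),
        "AMPA_I": ProjectionDef("AMPA", "I", 0.2, 1.7, 8.3),
        "NMDA_I": ProjectionDef("NMDA", "I", 0.2, 6.7, 100.0),
        "GABA_I": ProjectionDef("GABA", "I", 0.5, 0.5, 20.0),
    }


@dataclass
class SynapseState:
    """Dimensionless conductances, their rates, and the depression resources."""

    m: np.ndarray = field(default_factory=lambda: np.zeros(len(PROJECTION_ORDER)))
    m_dot: np.ndarray = field(default_factory=lambda: np.zeros(len(PROJECTION_ORDER)))
    x_glu: float = 1.0
    x_gaba: float = 1.0


@dataclass(frozen=True)
class DepressionParams:
    """Short-term depression: recovery times and use fractions per mediator class."""

    tau_glu: float = 2000.0
    tau_gaba: float = 2000.0
    u_glu: float = 0.04
    u_gaba: float = 0.04

    def __post_init__(self):
        if min(self.tau_glu, self.tau_gaba, self.u_glu, self.u_gaba) <= 0:
            raise ValueError("depression parameters must be positive")


@dataclass(frozen=True)
class GapJunctionDef:
    g_gj: float = 0.2  # mS/cm^2

    def __post_init__(self):
        if self.g_gj < 0:
            raise ValueError("g_gj must be >= 0")


def advance_m(m: float, m_dot: float, projection: ProjectionDef,
              phi: float, dt: float):
    """One step of the second-order conductance kinetics (RK4, phi frozen).

    ``phi`` is the presynaptic population rate in 1/ms.  Returns (m, m_dot);
    m stays in [0, 1] thanks to the (1 - m) saturation of the drive.
    """
    if phi < 0:
        raise ValueError("presynaptic rate must be >= 0")
    return K.advance_m_scalar(float(m), float(m_dot), float(phi),
                              projection.tau_rise, projection.tau_decay,
                              projection.tau_s, dt)


def nmda_block(u, mg: float):
    """Voltage-dependent fraction of unblocked NMDA channels (Mg2+ block)."""
    if mg < 0:
        raise ValueError("Mg concentration must be >= 0")
    u = np.asarray(u, dtype=float)
    out = 1.0 / (1.0 + mg / 3.57 * np.exp(-0.062 * u))
    return float(out) if out.ndim == 0 else out


def advance_depression(state: SynapseState, params: DepressionParams,
                       phi_e: float, phi_i: float, dt: float) -> SynapseState:
    """Exponential-Euler update of both depression resources (exact for frozen rates)."""
    if phi_e < 0 or phi_i < 0:
        raise ValueError("presynaptic rates must be >= 0")
    state.x_glu = K.advance_depression_scalar(state.x_glu, params.tau_glu,
                                              params.u_glu, phi_e, dt)
    state.x_gaba = K.advance_depression_scalar(state.x_gaba, params.tau_gaba,
                                               params.u_gaba, phi_i, dt)
    return state


def assemble_conductances(state: SynapseState, projections: dict,
                          u_target: float, mg: float) -> dict:
    """Momentary conductances (mS/cm^2) per projection.

    AMPA/NMDA are multiplied by the glutamatergic resource, GABA by the
    GABAergic one; NMDA additionally by the magnesium block at the
    postsynaptic voltage ``u_target``.
    """
    out = {}
    for idx, name in enumerate(PROJECTION_ORDER):
        proj = projections[name]
        g = proj.g_max * state.m[idx]
        if proj.mediator == "GABA":
            g *= state.x_gaba
        else:
            g *= state.x_glu
            if proj.mediator == "NMDA":
                g *= nmda_block(u_target, mg)
        out[name] = g
    return out


def gap_junction_current(u, u_mean: float, g_gj: float):
    """Gap-junction current density toward the population mean voltage.

    The density-weighted total over the population vanishes by construction.
    """
    return g_gj * (u_mean - np.asarray(u, dtype=float))
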