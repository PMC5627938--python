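"""Channel kinetics, membrane equations and reset rules for both populations.

The excitatory population is a two-compartment adaptive pyramidal-cell model
(potassium currents I_DR, I_A, I_M, I_AHP; sodium spikes are replaced by the
hazard/reset mechanism of the refractory-density formalism).  The inhibitory
population is a single-compartment fast-spiking interneuron with one delayed
rectifier I_K.  All printed maximal conductances are stored in mS/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from . import _kernels as K

__all__ = [
    "ChannelDef",
    "MembraneParams",
    "ResetRule",
    "ExcitatoryParams",
    "InterneuronParams",
    "channel_current",
    "advance_gates",
    "advance_excitatory_membrane",
    "somatic_synaptic_current",
    "dendritic_synaptic_current",
    "apply_reset",
    "threshold_voltage",
    "steady_gates",
    "resting_state",
]

_RATE_FUNCS = {
    "DR": K.dr_rates,
    "A": K.a_rates,
    "M": K.m_rates,
    "AHP": K.ahp_rates,
    "K": K.kdr_rates,
}

# (activation exponent, inactivation exponent)
_GATE_EXPONENTS = {"DR": (1, 1), "A": (4, 3), "M": (2, 0), "AHP": (1, 0), "K": (4, 0)}


@dataclass(frozen=True)
class ChannelDef:
    """One voltage-gated potassium current."""

    name: str
    g_max: float
    reversal: float

    def __post_init__(self):
        if self.name not in _RATE_FUNCS:
            raise ValueError(f"unknown channel {self.name!r}")
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")

    @property
    def gate_exponents(self):
        return _GATE_EXPONENTS[self.name]

    def rates(self, u: float):
        """tau and steady state of the activation (and inactivation) gates at voltage u."""
        fn = _RATE_FUNCS[self.name]
        out = fn(u)
        if len(out) == 2:  # activation only
            return out
        return out


def channel_current(channel: ChannelDef, u, gates):
    """Ohmic current density g_max * prod(gates**exponents) * (U - reversal), uA/cm^2."""
    gates = np.atleast_1d(np.asarray(gates, dtype=float))
    px, py = channel.gate_exponents
    g = channel.g_max * gates[0] ** px
    if py:
        g = g * gates[1] ** py
    return g * (np.asarray(u, dtype=float) - channel.reversal)


def advance_gates(channel: ChannelDef, u, gates, dt: float):
    """Exponential-Euler relaxation of the channel gates toward their steady state."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    gates = np.atleast_1d(np.asarray(gates, dtype=float)).copy()
    out = _RATE_FUNCS[channel.name](float(u))
    tau_x, x_inf = out[0], out[1]
    gates[0] = x_inf + (gates[0] - x_inf) * np.exp(-dt / tau_x)
    if len(out) == 4 and len(gates) > 1:
        tau_y, y_inf = out[2], out[3]
        gates[1] = y_inf + (gates[1] - y_inf) * np.exp(-dt / tau_y)
    return gates


@dataclass(frozen=True)
class MembraneParams:
    """Passive membrane and geometry parameters shared by both populations."""

    c: float           # uF/cm^2
    g_l: float         # mS/cm^2
    v_rest: float      # mV
    v_reset: float     # mV
    dt_ap: float       # ms
    gamma: float       # dendritic/somatic conductance ratio
    ell: float         # squared dendritic length ratio
    tau_m0: float      # resting membrane time constant, ms
    area: float        # cm^2
    v_k: float         # mV
    v_m: float         # mV

    def __post_init__(self):
        if self.c <= 0 or self.dt_ap <= 0 or self.gamma <= 0:
            raise ValueError("c, dt_ap and gamma must be positive")

    @property
    def g_tot0(self) -> float:
        """Resting total conductance implied by tau_m0 (mS/cm^2)."""
        return self.c / self.tau_m0


@dataclass(frozen=True)
class ResetRule:
    """Gate values applied when a probe re-enters the spike state.

    Fast gates are hard-set; slow gates are incremented from their value at
    the peak of the spike-release distribution t*_p.
    """

    hard_resets: dict
    incremental_resets: dict

    def __post_init__(self):
        for v in self.hard_resets.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("hard reset values must lie in [0, 1]")
        for v in self.incremental_resets.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("increments must lie in [0, 1]")


EXC_RESET = ResetRule(
    hard_resets={"DR.x": K.RESET_XDR, "DR.y": K.RESET_YDR,
                 "A.x": K.RESET_XA, "A.y": K.RESET_YA},
    incremental_resets={"M.x": K.INC_XM, "AHP.w": K.INC_W},
)
INH_RESET = ResetRule(hard_resets={"K.n": K.RESET_N}, incremental_resets={})


@dataclass(frozen=True)
class ExcitatoryParams:
    """Parameter block of the adaptive pyramidal-cell population."""

    c: float = 0.7
    g_l: float = 0.034
    v_rest: float = -65.0
    v_reset: float = -40.0
    dt_ap: float = 1.5
    gamma: float = 2.85
    ell: float = 1.0
    tau_m0: float = 14.4
    area: float = 1.0e-4
    v_k: float = -70.0
    v_m: float = -80.0
    g_dr: float = 0.76
    g_a: float = 4.36
    g_m: float = 0.4
    g_ahp: float = 0.3
    v_th_base: float = -40.0
    v_th_amp: float = 50.0
    v_th_tau: float = 10.0
    sigma_v0: float = 2.0
    tau_noise: float = 4.0
    grid_b: float = 100.0
    grid_n: int = 100

    @property
    def membrane(self) -> MembraneParams:
        return MembraneParams(self.c, self.g_l, self.v_rest, self.v_reset,
                              self.dt_ap, self.gamma, self.ell, self.tau_m0,
                              self.area, self.v_k, self.v_m)

    @property
    def g_tot0(self) -> float:
        return self.c / self.tau_m0

    @property
    def channels(self):
        return {
            "DR": ChannelDef("DR", self.g_dr, self.v_k),
            "A": ChannelDef("A", self.g_a, self.v_k),
            "M": ChannelDef("M", self.g_m, self.v_m),
            "AHP": ChannelDef("AHP", self.g_ahp, self.v_k),
        }

    def to_vector(self) -> np.ndarray:
        p = np.zeros(K.NPOP_PARAMS)
        p[K.P_C] = self.c
        p[K.P_GL] = self.g_l
        p[K.P_VREST] = self.v_rest
        p[K.P_VRESET] = self.v_reset
        p[K.P_DTAP] = self.dt_ap
        p[K.P_VK] = self.v_k
        p[K.P_VM] = self.v_m
        p[K.P_GAMMA] = self.gamma
        p[K.P_ELL] = self.ell
        p[K.P_TAUM0] = self.tau_m0
        p[K.P_GDR] = self.g_dr
        p[K.P_GA] = self.g_a
        p[K.P_GM] = self.g_m
        p[K.P_GAHP] = self.g_ahp
        p[K.P_VTHB] = self.v_th_base
        p[K.P_VTHA] = self.v_th_amp
        p[K.P_VTHT] = self.v_th_tau
        p[K.P_SIG0] = self.sigma_v0
        p[K.P_TAUN] = self.tau_noise
        p[K.P_GTOT0] = self.g_tot0
        p[K.P_B] = self.grid_b
        p[K.P_AREA] = self.area
        return p


@dataclass(frozen=True)
class InterneuronParams:
    """Parameter block of the fast-spiking interneuron population."""

    c: float = 1.0
    g_l: float = 0.1
    v_rest: float = -60.0
    v_reset: float = -40.0
    dt_ap: float = 1.4
    tau_m0: float = 9.7
    area: float = 1.0e-4
    v_k: float = -80.0
    g_k: float = 40.0
    v_th_base: float = -50.0
    v_th_amp: float = 20.0
    v_th_tau: float = 10.0
    sigma_v0: float = 3.0
    tau_noise: float = 4.0
    grid_b: float = 40.0
    grid_n: int = 50

    @property
    def g_tot0(self) -> float:
        return self.c / self.tau_m0

    @property
    def channels(self):
        return {"K": ChannelDef("K", self.g_k, self.v_k)}

    def to_vector(self) -> np.ndarray:
        p = np.zeros(K.NPOP_PARAMS)
        p[K.P_C] = self.c
        p[K.P_GL] = self.g_l
        p[K.P_VREST] = self.v_rest
        p[K.P_VRESET] = self.v_reset
        p[K.P_DTAP] = self.dt_ap
        p[K.P_VK] = self.v_k
        p[K.P_GK] = self.g_k
        p[K.P_VTHB] = self.v_th_base
        p[K.P_VTHA] = self.v_th_amp
        p[K.P_VTHT] = self.v_th_tau
        p[K.P_SIG0] = self.sigma_v0
        p[K.P_TAUN] = self.tau_noise
        p[K.P_GTOT0] = self.g_tot0
        p[K.P_B] = self.grid_b
        p[K.P_AREA] = self.area
        return p


def threshold_voltage(t_star, pop: str = "E"):
    """Post-spike relaxing firing threshold V_th(t*) in mV."""
    t_star = np.asarray(t_star, dtype=float)
    if pop == "E":
        out = -40.0 + 50.0 * np.exp(-t_star / 10.0)
    elif pop == "I":
        out = -50.0 + 20.0 * np.exp(-t_star / 10.0)
    else:
        raise ValueError("pop must be 'E' or 'I'")
    return float(out) if out.ndim == 0 else out


def somatic_synaptic_current(g_gaba, u, v_gaba):
    """GABAergic somatic current density g * (V_GABA - U), uA/cm^2."""
    return np.asarray(g_gaba, dtype=float) * (v_gaba - np.asarray(u, dtype=float))


def dendritic_synaptic_current(drive, drive_prev, params: MembraneParams, dt: float):
    """Transient-sharpened dendritic drive.

    Applies the operator ``(l*tau_m0/2 * d/dt + 1 + l/2)`` to the summed
    glutamatergic drive, with a one-step backward difference for the
    derivative.  The operator reconstructs the dendritic current that a
    somatically registered conductance response implies.
    """
    drive = np.asarray(drive, dtype=float)
    drive_prev = np.asarray(drive_prev, dtype=float)
    return (1.0 + params.ell / 2.0) * drive \
        + (params.ell * params.tau_m0 / 2.0) * (drive - drive_prev) / dt


def advance_excitatory_membrane(u, u_d, gates, drive_prev, t_star,
                                g_ampa, g_nmda, g_gaba, v_gaba, mg, i_ext,
                                params: ExcitatoryParams, dt: float,
                                pinned=None):
    """One semi-implicit step of the two-compartment membrane pair.

    Mutates ``u``, ``u_d``, ``gates`` (6 x N array) and ``drive_prev`` in
    place and returns ``(du_dt, g_tot)`` per probe (the pre-update somatic
    right-hand side and the somatic total conductance).
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("non-finite somatic voltage")
    if pinned is None:
        pinned = np.ones(len(u))
    dudt = np.empty(len(u))
    gtot = np.empty(len(u))
    K.step_exc_membrane(u, u_d, gates, drive_prev, t_star, pinned,
                        float(g_ampa), float(g_nmda), float(g_gaba),
                        float(v_gaba), float(mg), float(i_ext),
                        params.to_vector(), dt, dudt, gtot)
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("membrane update diverged")
    return dudt, gtot


def apply_reset(pop: str, gates: np.ndarray, recycled: int, peak_idx: int | None):
    """Apply the boundary-condition gate resets to a recycled probe.

    Fast gates are hard-set; slow gates (I_M activation, I_AHP gate) are
    incremented from their values at the peak-flux probe ``peak_idx``.  If
    the population released no spikes this step (``peak_idx is None``) the
    recycled probe keeps its carried slow-gate values unchanged, so silent
    recycling does not inject adaptation conductance.
    """
    silent = peak_idx is None
    p = recycled if silent else peak_idx
    if pop == "E":
        xm_p = gates[K.GE_XM, p]
        w_p = gates[K.GE_W, p]
        gates[K.GE_XDR, recycled] = K.RESET_XDR
        gates[K.GE_YDR, recycled] = K.RESET_YDR
        gates[K.GE_XA, recycled] = K.RESET_XA
        gates[K.GE_YA, recycled] = K.RESET_YA
        if not silent:
            gates[K.GE_XM, recycled] = xm_p + K.INC_XM * (1.0 - xm_p)
            gates[K.GE_W, recycled] = w_p + K.INC_W * (1.0 - w_p)
    elif pop == "I":
        gates[0, recycled] = K.RESET_N
    else:
        raise ValueError("pop must be 'E' or 'I'")
    return gates


def steady_gates(u: float, pop: str = "E") -> np.ndarray:
    """Steady-state gate values at a fixed voltage."""
    if pop == "E":
        _, xdr, _, ydr = K.dr_rates(u)
        _, xa, _, ya = K.a_rates(u)
        _, xm = K.m_rates(u)
        _, w = K.ahp_rates(u)
        return np.array([xdr, ydr, xa, ya, xm, w])
    _, n = K.kdr_rates(u)
    return np.array([n])


def _exc_channel_conductances(u: float, gates: np.ndarray, p: ExcitatoryParams):
    g_dr = p.g_dr * gates[0] * gates[1]
    g_a = p.g_a * gates[2] ** 4 * gates[3] ** 3
    g_m = p.g_m * gates[4] ** 2
    g_ahp = p.g_ahp * gates[5]
    return g_dr, g_a, g_m, g_ahp


def resting_state(params, pop: str = "E"):
    """Self-consistent resting potential(s) with gates at steady state.

    The resting potassium conductances pull the equilibrium slightly below
    the nominal leak reversal; populations are initialised here so that a
    zero-input simulation is stationary.  Returns ``(u, u_d)`` for the
    excitatory population or a scalar ``u`` for the interneurons.
    """
    if pop == "E":
        p: ExcitatoryParams = params
        g_cd = 2.0 / p.ell * p.g_l
        g_cs = 2.0 * p.gamma / p.ell * p.g_l

        def ud_of(u):
            return (p.g_l * p.v_rest + g_cd * u) / (p.g_l + g_cd)

        def f(u):
            g = steady_gates(u, "E")
            g_dr, g_a, g_m, g_ahp = _exc_channel_conductances(u, g, p)
            return (-p.g_l * (u - p.v_rest) + g_cs * (ud_of(u) - u)
                    - (g_dr + g_a + g_ahp) * (u - p.v_k) - g_m * (u - p.v_m))

        u_eq = brentq(f, -90.0, -45.0, xtol=1e-10)
        return u_eq, ud_of(u_eq)
    p: InterneuronParams = params

    def f(u):
        n = steady_gates(u, "I")[0]
        return -p.g_l * (u - p.v_rest) - p.g_k * n ** 4 * (u - p.v_k)

    return brentq(f, -90.0, -45.0, xtol=1e-10)
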