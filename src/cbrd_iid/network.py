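"""Coupled excitatory/inhibitory network, stimulation protocols and observables.

Wires the two refractory-density populations through the synapse layer,
drives the interneurons with a common Ornstein-Uhlenbeck current, and emits
firing rates, mean voltages, conductances, a virtual voltage-clamp current
and a dipole-proxy LFP.  The discharge regimes are selected by the GABA-A
reversal potential: -50 mV yields purely GABAergic discharges carried by the
interneuron network (IID1), -45 mV recruits the pyramidal population into
glutamatergically maintained discharges (IID2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels as K
from .cbrd_core import TStarGrid, WeightDistribution, build_lognormal_bins
from .ion_channels import (ExcitatoryParams, InterneuronParams, resting_state,
                           steady_gates)
from .synapses import (DepressionParams, GapJunctionDef, PROJECTION_ORDER,
                       ProjectionDef, default_projections, nmda_block)

__all__ = [
    "OUParams",
    "StimulusTrain",
    "NetworkConfig",
    "NetworkState",
    "TraceSet",
    "PROTOCOLS",
    "init_state",
    "step_network",
    "simulate",
    "run_protocol",
    "ou_step",
    "virtual_clamp_current",
    "lfp_signal",
]

TRACE_CHANNELS = (
    ("time", "ms"),
    ("nu_E", "Hz"), ("nu_I", "Hz"),
    ("U_mean_E", "mV"), ("U_mean_I", "mV"),
    ("g_AMPA_E", "mS/cm^2"), ("g_NMDA_E", "mS/cm^2"), ("g_GABA_E", "mS/cm^2"),
    ("g_AMPA_I", "mS/cm^2"), ("g_NMDA_I", "mS/cm^2"), ("g_GABA_I", "mS/cm^2"),
    ("I_clamp", "pA"), ("LFP", "a.u."),
    ("x_glu_D", "1"), ("x_gaba_D", "1"), ("I_ou", "pA"),
)


@dataclass(frozen=True)
class OUParams:
    """Common Ornstein-Uhlenbeck current drive (applied to the interneurons)."""

    sigma: float = 20.0   # pA
    tau: float = 4.0      # ms
    to_e: bool = False    # also inject the same realisation into E


@dataclass(frozen=True)
class StimulusTrain:
    """Train of synchronous afferent volleys injected into the GABA projections."""

    n_pulses: int = 25
    rate: float = 20.0       # Hz
    pulse_area: float = 1.0  # spikes per presynaptic neuron per volley
    onset: float = 500.0     # ms

    def __post_init__(self):
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")

    def rate_waveform(self, n_steps: int, dt: float) -> np.ndarray:
        """Presynaptic-rate impulses (1/ms) on the simulation grid."""
        phi = np.zeros(n_steps)
        for p in range(self.n_pulses):
            idx = int(round((self.onset + p * 1000.0 / self.rate) / dt))
            if 0 <= idx < n_steps:
                phi[idx] += self.pulse_area / dt
        return phi


@dataclass(frozen=True)
class NetworkConfig:
    """Full parameter set of a simulation; defaults reproduce the model's
    reference conditions (quiescent network, hyperpolarised V_GABA)."""

    dt: float = 0.1               # ms
    duration: float = 20000.0     # ms of recorded time
    burn_in: float = 1000.0       # ms discarded before recording
    record_dt: float = 1.0        # ms between recorded samples
    seed: int = 0
    v_gaba: float = -70.0         # mV
    v_hold: float = -27.0         # mV, virtual clamp holding potential
    mg: float = 0.25              # mM
    lfp_gain: float = 1.0
    depression_enabled: bool = True
    feedback_enabled: bool = True
    sigma_ln: float = 0.5
    n_weight_bins: int = 10
    mean_normalize_weights: bool = True
    exc: ExcitatoryParams = field(default_factory=ExcitatoryParams)
    inh: InterneuronParams = field(default_factory=InterneuronParams)
    synapses: dict = field(default_factory=default_projections)
    depression: DepressionParams = field(default_factory=DepressionParams)
    gap: GapJunctionDef = field(default_factory=GapJunctionDef)
    ou: OUParams = field(default_factory=OUParams)
    stimulus: StimulusTrain | None = None

    def __post_init__(self):
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")

    @property
    def weights(self) -> WeightDistribution:
        if self.n_weight_bins == 1:
            return WeightDistribution.delta()
        return build_lognormal_bins(self.sigma_ln, self.n_weight_bins,
                                    self.mean_normalize_weights)

    @property
    def grid_e(self) -> TStarGrid:
        return TStarGrid(self.exc.grid_b, self.exc.grid_n)

    @property
    def grid_i(self) -> TStarGrid:
        return TStarGrid(self.inh.grid_b, self.inh.grid_n)

    def shared_vector(self) -> np.ndarray:
        sh = np.zeros(K.NSHARED)
        sh[K.S_DT] = self.dt
        sh[K.S_VGABA] = self.v_gaba
        sh[K.S_MG] = self.mg
        sh[K.S_GGJ] = self.gap.g_gj
        sh[K.S_OUSIG] = self.ou.sigma  # pA; the kernel converts per membrane area
        sh[K.S_OUTAU] = self.ou.tau
        sh[K.S_VHOLD] = self.v_hold
        sh[K.S_LFPGAIN] = self.lfp_gain
        sh[K.S_DEP_ON] = 1.0 if self.depression_enabled else 0.0
        sh[K.S_FB_ON] = 1.0 if self.feedback_enabled else 0.0
        sh[K.S_OU_TO_E] = 1.0 if self.ou.to_e else 0.0
        sh[K.S_TAUGLU] = self.depression.tau_glu
        sh[K.S_TAUGABA] = self.depression.tau_gaba
        sh[K.S_UGLU] = self.depression.u_glu
        sh[K.S_UGABA] = self.depression.u_gaba
        return sh

    def synapse_matrix(self) -> np.ndarray:
        syn = np.zeros((len(PROJECTION_ORDER), 4))
        for i, name in enumerate(PROJECTION_ORDER):
            p: ProjectionDef = self.synapses[name]
            syn[i] = (p.g_max, p.tau_rise, p.tau_decay, p.tau_s)
        return syn


@dataclass
class NetworkState:
    """All mutable arrays of one simulation, in kernel layout."""

    config: NetworkConfig
    tstar_e: np.ndarray
    rho_e: np.ndarray
    u_e: np.ndarray
    ud_e: np.ndarray
    gates_e: np.ndarray
    uf_e: np.ndarray
    udf_e: np.ndarray
    gatesf_e: np.ndarray
    dprev_e: np.ndarray
    dprevf_e: np.ndarray
    flux_e: np.ndarray
    pinned_e: np.ndarray
    tstar_i: np.ndarray
    rho_i: np.ndarray
    u_i: np.ndarray
    n_i: np.ndarray
    uf_i: np.ndarray
    nf_i: np.ndarray
    flux_i: np.ndarray
    pinned_i: np.ndarray
    m: np.ndarray
    m_dot: np.ndarray
    x_dep: np.ndarray
    misc: np.ndarray  # [ou, nu_E, nu_I, u_mean_E, u_mean_I]

    @property
    def nu_e(self) -> float:
        return self.misc[1]

    @property
    def nu_i(self) -> float:
        return self.misc[2]

    def density_mass(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-bin density mass (probes + boundary buffer) of each population."""
        return (self.rho_e.sum(axis=0) + self.flux_e,
                self.rho_i.sum(axis=0) + self.flux_i)


def init_state(config: NetworkConfig) -> NetworkState:
    """Resting initial state: density at t* = B, gates at steady state."""
    ge, gi = config.grid_e, config.grid_i
    kbins = config.weights.n_bins
    u0e, ud0e = resting_state(config.exc, "E")
    u0i = resting_state(config.inh, "I")

    ne, ni = ge.n_intervals, gi.n_intervals
    rho_e = np.zeros((ne, kbins))
    rho_e[ne - 1, :] = 1.0
    rho_i = np.zeros((ni, kbins))
    rho_i[ni - 1, :] = 1.0
    gate_e = np.tile(steady_gates(u0e, "E")[:, None], (1, ne))
    gate_i = steady_gates(u0i, "I")[0] * np.ones(ni)
    return NetworkState(
        config=config,
        tstar_e=ge.probe_positions.copy(),
        rho_e=rho_e,
        u_e=np.full(ne, u0e), ud_e=np.full(ne, ud0e),
        gates_e=gate_e.copy(),
        uf_e=np.full(ne, u0e), udf_e=np.full(ne, ud0e),
        gatesf_e=gate_e.copy(),
        dprev_e=np.zeros(ne), dprevf_e=np.zeros(ne),
        flux_e=np.zeros(kbins),
        pinned_e=np.zeros(ne),
        tstar_i=gi.probe_positions.copy(),
        rho_i=rho_i,
        u_i=np.full(ni, u0i), n_i=gate_i.copy(),
        uf_i=np.full(ni, u0i), nf_i=gate_i.copy(),
        flux_i=np.zeros(kbins),
        pinned_i=np.zeros(ni),
        m=np.zeros(6), m_dot=np.zeros(6),
        x_dep=np.ones(2),
        misc=np.array([0.0, 0.0, 0.0, u0e, u0i]),
    )


@dataclass
class TraceSet:
    """Uniformly sampled time series of all network observables."""

    data: np.ndarray                 # (NCHAN, n_samples)
    units: dict = field(default_factory=lambda: dict(TRACE_CHANNELS))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.shape[0] != len(TRACE_CHANNELS):
            raise ValueError("trace array has wrong channel count")

    def __getitem__(self, name: str) -> np.ndarray:
        names = [n for n, _ in TRACE_CHANNELS]
        return self.data[names.index(name)]

    @property
    def time(self) -> np.ndarray:
        return self["time"]

    @property
    def sample_interval(self) -> float:
        t = self.time
        return float(t[1] - t[0]) if len(t) > 1 else 0.0

    def conductance_ns(self, name: str, area: float = 1.0e-4) -> np.ndarray:
        """Cell-level conductance in nS for an areal density channel."""
        return self[name] * area * 1.0e6

    def to_frame(self) -> pd.DataFrame:
        names = [n for n, _ in TRACE_CHANNELS]
        return pd.DataFrame(self.data.T, columns=names)


def _run(state: NetworkState, n_steps: int, n_burn: int, record_stride: int,
         stim: np.ndarray, i_inj_e: np.ndarray, i_inj_i: np.ndarray,
         seed: int | None) -> np.ndarray:
    cfg = state.config
    n_rec = max(0, -(-(n_steps - n_burn) // record_stride))
    out = np.zeros((K.NCHAN, n_rec))
    if seed is not None:
        K.seed_rng(int(seed))
    status = K.run_network(
        n_steps, n_burn, record_stride,
        cfg.exc.to_vector(), cfg.inh.to_vector(), cfg.shared_vector(),
        cfg.synapse_matrix(), cfg.weights.bin_masses, cfg.weights.bin_scales,
        state.tstar_e, state.rho_e, state.u_e, state.ud_e, state.gates_e,
        state.uf_e, state.udf_e, state.gatesf_e,
        state.dprev_e, state.dprevf_e, state.flux_e, state.pinned_e,
        state.tstar_i, state.rho_i, state.u_i, state.n_i,
        state.uf_i, state.nf_i, state.flux_i, state.pinned_i,
        state.m, state.m_dot, state.x_dep, state.misc,
        stim, i_inj_e, i_inj_i, out)
    if status != 0:
        raise FloatingPointError(
            f"simulation diverged at step {status} "
            f"(U_mean_E={state.misc[3]:.1f} mV, U_mean_I={state.misc[4]:.1f} mV)")
    return out


def step_network(state: NetworkState, n_steps: int = 1,
                 stim: np.ndarray | None = None,
                 i_inj_e: np.ndarray | None = None,
                 i_inj_i: np.ndarray | None = None,
                 seed: int | None = None) -> NetworkState:
    """Advance the network in place by ``n_steps`` global steps.

    Repeated single-step calls reproduce one long call bit for bit provided
    the RNG was seeded once (pass ``seed`` on the first call only).
    """
    z = np.zeros(n_steps)
    _run(state, n_steps, n_steps, 1,
         z if stim is None else stim,
         z if i_inj_e is None else i_inj_e,
         z if i_inj_i is None else i_inj_i,
         seed)
    return state


def simulate(config: NetworkConfig,
             i_inj_e: np.ndarray | None = None,
             i_inj_i: np.ndarray | None = None) -> TraceSet:
    """Run a full simulation (burn-in + recorded epoch) from a resting state."""
    dt = config.dt
    n_burn = int(round(config.burn_in / dt))
    n_main = int(round(config.duration / dt))
    n_steps = n_burn + n_main
    record_stride = max(1, int(round(config.record_dt / dt)))
    stim = np.zeros(n_steps)
    if config.stimulus is not None:
        stim[n_burn:] = config.stimulus.rate_waveform(n_main, dt)

    def pad(w):
        if w is None:
            return np.zeros(n_steps)
        full = np.zeros(n_steps)
        full[n_burn:n_burn + min(len(w), n_main)] = w[:n_main]
        return full

    state = init_state(config)
    out = _run(state, n_steps, n_burn, record_stride,
               stim, pad(i_inj_e), pad(i_inj_i), config.seed)
    meta = {"seed": config.seed, "v_gaba": config.v_gaba,
            "depression_enabled": config.depression_enabled,
            "duration": config.duration, "dt": config.dt}
    return TraceSet(out, meta=meta)


def ou_step(value: float, tau: float, sigma: float, dt: float,
            rng: np.random.Generator) -> float:
    """Exact one-step update of an OU process with stationary SD ``sigma``."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    alpha = math.exp(-dt / tau)
    return value * alpha + sigma * math.sqrt(1.0 - alpha * alpha) * rng.standard_normal()


def virtual_clamp_current(g_ampa_ns, g_nmda_ns, g_gaba_ns, v_hold: float,
                          v_gaba: float, mg: float = 0.25) -> np.ndarray:
    """Somatic current (pA, outward positive) a voltage clamp at ``v_hold``
    would record for the given synaptic conductances (nS).

    The glutamatergic reversal is 0 mV, so at ``v_hold = 0`` the current
    isolates the GABAergic component.
    """
    g_ampa_ns = np.asarray(g_ampa_ns, dtype=float)
    return (np.asarray(g_gaba_ns, dtype=float) * (v_hold - v_gaba)
            + g_ampa_ns * v_hold
            + np.asarray(g_nmda_ns, dtype=float) * nmda_block(v_hold, mg) * v_hold)


def lfp_signal(state: NetworkState, gain: float | None = None) -> float:
    """Dipole-proxy local field potential of the two-compartment E population.

    Proportional to minus the density-weighted somato-dendritic axial
    current, so dendritic excitation deflects the signal negative.
    """
    cfg = state.config
    g = cfg.lfp_gain if gain is None else gain
    p = cfg.exc
    gcpl = 2.0 * p.gamma / p.ell * p.g_l
    w = (cfg.weights.bin_masses[None, :] * state.rho_e).sum(axis=1)
    return float(-g * np.sum(w * gcpl * (state.ud_e - state.u_e)))


def _protocol_config(name: str, config: NetworkConfig) -> NetworkConfig:
    if name == "iid1":
        return replace(config, v_gaba=-50.0, depression_enabled=True,
                       v_hold=-27.0, stimulus=None)
    if name == "iid2":
        return replace(config, v_gaba=-45.0, depression_enabled=True,
                       v_hold=-27.0, stimulus=None)
    if name == "no_depression":
        # depression frozen at 1; no burn-in so the transition time is
        # measured from the resting state
        return replace(config, v_gaba=-45.0, depression_enabled=False,
                       burn_in=0.0, v_hold=-27.0, stimulus=None)
    if name == "evoked_ipsc_control":
        return replace(config, v_gaba=-70.0, feedback_enabled=False,
                       v_hold=0.0,
                       stimulus=config.stimulus or StimulusTrain())
    if name == "evoked_ipsc_proepileptic":
        return replace(config, v_gaba=-45.0, feedback_enabled=True,
                       v_hold=0.0,
                       stimulus=config.stimulus or StimulusTrain())
    raise ValueError(f"unknown protocol {name!r}")


PROTOCOLS = ("iid1", "iid2", "no_depression",
             "evoked_ipsc_control", "evoked_ipsc_proepileptic")


def run_protocol(name: str, config: NetworkConfig | None = None, **overrides) -> TraceSet:
    """Run one of the named stimulation protocols.

    ``overrides`` replace NetworkConfig fields after the protocol presets
    (e.g. ``duration=60000, seed=3``).
    """
    cfg = _protocol_config(name, config or NetworkConfig())
    if overrides:
        cfg = replace(cfg, **overrides)
    trace = simulate(cfg)
    trace.meta["protocol"] = name
    return trace
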