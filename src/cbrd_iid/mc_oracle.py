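"""Monte-Carlo reference ensemble of individual stochastic neurons.

The standard equivalence check for refractory-density methods: N neurons with
the identical membrane, channel and reset equations, each receiving the common
input plus an individual colored (OU) noise current whose amplitude tracks the
neuron's momentary conductance state so that the subthreshold voltage SD stays
equal to the hazard's noise amplitude sigma_V.  The time-binned ensemble rate
should match the population solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .ion_channels import ExcitatoryParams, InterneuronParams, resting_state, steady_gates

__all__ = [
    "NeuronEnsemble",
    "noise_current_sd",
    "simulate_ensemble",
    "ensemble_rate",
    "save_raster",
    "load_raster",
]


@dataclass
class NeuronEnsemble:
    """Spike raster and final state of one ensemble simulation."""

    n_neurons: int
    duration: float         # ms
    spike_neurons: np.ndarray
    spike_times: np.ndarray

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


def noise_current_sd(sigma_v: float, g_tot: float, tau_m: float,
                     tau_noise: float) -> float:
    """OU current SD (uA/cm^2) producing voltage fluctuations of SD sigma_v.

    For an OU current of correlation time tau_noise into an RC membrane of
    conductance g_tot, Var(V) = sigma_I^2 / g^2 * tau_noise / (tau_m +
    tau_noise), hence sigma_I = sigma_v * g * sqrt(1 + k) with
    k = tau_m / tau_noise.  The ensemble kernels apply this with each
    neuron's momentary conductance.
    """
    return sigma_v * g_tot * math.sqrt(1.0 + tau_m / tau_noise)


def simulate_ensemble(params, pop: str, n_neurons: int, i_inj: np.ndarray,
                      dt: float, seed: int, sigma_v: float | None = None,
                      g_gj: float = 0.0) -> NeuronEnsemble:
    """Simulate ``n_neurons`` independent neurons under a common current.

    ``i_inj`` is the common injected current waveform (uA/cm^2) per time
    step.  Each neuron carries an individual colored (OU) voltage noise of
    SD ``sigma_v`` (default: the population's sigma_v0) which enters the
    threshold-crossing test -- exactly the stochastic premise under which
    the population hazard was derived.  Pass ``sigma_v=0`` for
    deterministic neurons.  For the interneuron population ``g_gj``
    couples each neuron to the ensemble-mean voltage.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    i_inj = np.ascontiguousarray(i_inj, dtype=float)
    n_steps = len(i_inj)
    if sigma_v is None:
        sigma_v = params.sigma_v0
    cap = max(1000, int(n_neurons * n_steps * dt / 1000.0 * 400))  # 400 Hz headroom
    spike_n = np.empty(cap, dtype=np.int64)
    spike_t = np.empty(cap, dtype=np.float64)
    K.seed_rng(int(seed))
    if pop == "E":
        p: ExcitatoryParams = params
        u0, ud0 = resting_state(p, "E")
        u = np.full(n_neurons, u0)
        ud = np.full(n_neurons, ud0)
        gates = np.tile(steady_gates(u0, "E")[:, None], (1, n_neurons))
        tsl = np.full(n_neurons, 1.0e6)
        noise = np.zeros(n_neurons)
        count = K.run_ensemble_exc(n_steps, dt, p.to_vector(), i_inj,
                                   float(sigma_v), p.tau_noise,
                                   u, ud, gates, tsl, noise, spike_n, spike_t)
    elif pop == "I":
        p: InterneuronParams = params
        u0 = resting_state(p, "I")
        u = np.full(n_neurons, u0)
        n_gate = steady_gates(u0, "I")[0] * np.ones(n_neurons)
        tsl = np.full(n_neurons, 1.0e6)
        noise = np.zeros(n_neurons)
        count = K.run_ensemble_inh(n_steps, dt, p.to_vector(), i_inj,
                                   float(sigma_v), p.tau_noise, g_gj,
                                   u, n_gate, tsl, noise, spike_n, spike_t)
    else:
        raise ValueError("pop must be 'E' or 'I'")
    count = min(count, cap)
    return NeuronEnsemble(n_neurons, n_steps * dt,
                          spike_n[:count].copy(), spike_t[:count].copy())


def ensemble_rate(ensemble: NeuronEnsemble, bin_ms: float = 20.0):
    """Per-neuron population rate (Hz) from binned spike counts.

    Returns ``(bin_centers_ms, rate_hz)``.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    n_bins = max(1, int(round(ensemble.duration / bin_ms)))
    edges = np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(ensemble.spike_times, bins=edges)
    rate = counts / ensemble.n_neurons / (bin_ms / 1000.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rate


def save_raster(ensemble: NeuronEnsemble, path) -> None:
    """Two-column (neuron, time-ms) delimited text raster."""
    np.savetxt(path, np.column_stack([ensemble.spike_neurons, ensemble.spike_times]),
               fmt=["%d", "%.4f"], delimiter="\t",
               header=f"n_neurons={ensemble.n_neurons}\tduration_ms={ensemble.duration}")


def load_raster(path) -> NeuronEnsemble:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip().split("\t")
    meta = dict(kv.split("=") for kv in header)
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        data = np.empty((0, 2))
    return NeuronEnsemble(int(meta["n_neurons"]), float(meta["duration_ms"]),
                          data[:, 0].astype(int), data[:, 1])
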