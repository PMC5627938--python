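"""Refractory-density transport in time-since-spike space.

A population of like neurons is represented by a density :math:`\\rho(t, t^*)`
over the time elapsed since the last spike, discretised on a Lagrangian grid
of probe neurons.  Spiking removes density at the hazard rate
:math:`H(U, dU/dt, t^*)` and re-injects it at :math:`t^* = 0`; the population
firing rate is the total hazard flux.  Heterogeneous synaptic weights are
carried by a lognormal weight distribution: each weight bin holds its own
density while sharing the probe voltage trajectories through the affine map
``U_x = U_free + (U - U_free) * x``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from . import _kernels as K

__all__ = [
    "TStarGrid",
    "WeightDistribution",
    "HazardParams",
    "PopulationState",
    "build_lognormal_bins",
    "hazard_rate",
    "advance_density",
    "firing_rate",
    "map_bin_voltages",
    "mean_voltage",
]


@dataclass(frozen=True)
class TStarGrid:
    """Bounded, uniformly discretised time-since-spike axis."""

    bound_B: float
    n_intervals: int

    def __post_init__(self):
        if self.n_intervals < 2:
            raise ValueError("n_intervals must be >= 2")
        if self.bound_B <= 0:
            raise ValueError("bound_B must be positive")

    @property
    def spacing(self) -> float:
        return self.bound_B / self.n_intervals

    @property
    def probe_positions(self) -> np.ndarray:
        """Initial probe coordinates: one per interval, strictly increasing in [0, B)."""
        return np.arange(self.n_intervals) * self.spacing


@dataclass(frozen=True)
class WeightDistribution:
    """Discretised lognormal synaptic-weight distribution.

    ``bin_scales`` are the representative relative input strengths x of each
    bin; ``bin_masses`` their probabilities (summing to one).
    """

    sigma_ln: float
    bin_scales: np.ndarray
    bin_masses: np.ndarray

    def __post_init__(self):
        scales = np.asarray(self.bin_scales, dtype=float)
        masses = np.asarray(self.bin_masses, dtype=float)
        object.__setattr__(self, "bin_scales", scales)
        object.__setattr__(self, "bin_masses", masses)
        if scales.shape != masses.shape:
            raise ValueError("bin_scales and bin_masses must have equal length")
        if np.any(scales <= 0):
            raise ValueError("bin_scales must be positive")
        if abs(masses.sum() - 1.0) > 1e-12:
            raise ValueError("bin_masses must sum to 1")

    @property
    def n_bins(self) -> int:
        return len(self.bin_scales)

    @classmethod
    def delta(cls) -> "WeightDistribution":
        """Degenerate distribution: every neuron receives the mean input (x = 1)."""
        return cls(0.0, np.array([1.0]), np.array([1.0]))


def build_lognormal_bins(sigma_ln: float, n_bins: int,
                         mean_normalize: bool = False) -> WeightDistribution:
    """Partition the lognormal weight density into equal-probability bins.

    Each bin carries mass ``1/n_bins``; its representative scale is the
    mass-weighted mean of x within the quantile interval (the conditional
    mean of a lognormal with median 1 and shape ``sigma_ln``).  With
    ``mean_normalize`` the scales are divided by the distribution mean
    ``exp(sigma_ln**2 / 2)`` so that the weighted mean scale is exactly one.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if sigma_ln <= 0:
        raise ValueError("sigma_ln must be positive")
    edges_z = norm.ppf(np.linspace(0.0, 1.0, n_bins + 1))
    mean = np.exp(sigma_ln ** 2 / 2.0)
    # conditional mean of exp(sigma*Z) on each standard-normal quantile slab
    upper = norm.cdf(edges_z[1:] - sigma_ln)
    lower = norm.cdf(edges_z[:-1] - sigma_ln)
    masses = np.full(n_bins, 1.0 / n_bins)
    scales = mean * (upper - lower) / masses
    if mean_normalize:
        scales = scales / mean
    return WeightDistribution(sigma_ln, scales, masses)


@dataclass(frozen=True)
class HazardParams:
    """Parameters of the hazard function of one population.

    ``sigma_v0`` is the voltage-noise amplitude at rest; the effective noise
    grows with the synaptic drive relative to the momentary total
    conductance, ``sigma_V = sigma_v0 * (1 + g_syn / (g_tot0 + g_syn))``,
    saturating at twice the resting amplitude.  ``tau_m`` entering the
    noise-crossing term is ``c_m / g_tot`` for the momentary total
    conductance, and ``k = tau_m / tau_noise``.
    """

    v_th_base: float = -40.0
    v_th_amp: float = 50.0
    v_th_tau: float = 10.0
    sigma_v0: float = 2.0
    tau_noise: float = 4.0
    c_m: float = 0.7
    g_tot0: float = 0.7 / 14.4
    dt_ap: float = 1.5

    def __post_init__(self):
        if self.sigma_v0 <= 0:
            raise ValueError("sigma_v0 must be positive")
        if self.v_th_tau <= 0:
            raise ValueError("v_th_tau must be positive")

    def sigma_v(self, g_syn: float = 0.0) -> float:
        return self.sigma_v0 * (1.0 + g_syn / (self.g_tot0 + g_syn))


def hazard_rate(u, du_dt, t_star, g_tot, params: HazardParams,
                g_syn: float = 0.0, h_max: float = 10.0):
    """Instantaneous firing hazard (1/ms) of a neuronal state.

    Sum of a noise-driven term A (colored-noise threshold crossing) and a
    drift term B active only while the state approaches the relaxing
    threshold.  Zero inside the spike window ``t_star < dt_ap``; clamped to
    ``h_max``.
    """
    u = np.asarray(u, dtype=float)
    du_dt = np.asarray(du_dt, dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(du_dt))):
        raise ValueError("non-finite voltage or voltage derivative")
    sigma = params.sigma_v(g_syn)
    u_b, du_b, ts_b, gt_b = np.broadcast_arrays(
        u, du_dt, np.asarray(t_star, dtype=float), np.asarray(g_tot, dtype=float))
    out = np.empty(u_b.shape)
    flat = (u_b.ravel(), du_b.ravel(), ts_b.ravel(), gt_b.ravel())
    o = out.ravel()
    for i in range(o.size):
        o[i] = K.hazard_scalar(flat[0][i], flat[1][i], flat[2][i], flat[3][i],
                               params.c_m, params.v_th_base, params.v_th_amp,
                               params.v_th_tau, sigma, params.tau_noise,
                               params.dt_ap, h_max)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class PopulationState:
    """Density, probe trajectories and boundary-flux buffers of one population."""

    grid: TStarGrid
    weights: WeightDistribution
    t_star: np.ndarray = field(default=None)
    rho: np.ndarray = field(default=None)
    flux: np.ndarray = field(default=None)
    u: np.ndarray = field(default=None)
    u_free: np.ndarray = field(default=None)
    nu: float = 0.0

    def __post_init__(self):
        n, k = self.grid.n_intervals, self.weights.n_bins
        if self.t_star is None:
            self.t_star = self.grid.probe_positions.copy()
        if self.rho is None:
            # all mass long after the last spike (oldest probe)
            self.rho = np.zeros((n, k))
            self.rho[np.argmax(self.t_star), :] = 1.0
        if self.flux is None:
            self.flux = np.zeros(k)
        if self.u is None:
            self.u = np.full(n, -65.0)
        if self.u_free is None:
            self.u_free = self.u.copy()

    def total_mass(self) -> np.ndarray:
        """Per-bin density mass including the accumulated boundary flux."""
        return self.rho.sum(axis=0) + self.flux


def advance_density(state: PopulationState, hazard: np.ndarray, dt: float):
    """One Lagrangian transport step of the density.

    Probe masses decay by ``exp(-H dt)``; the shed mass accumulates in the
    per-bin boundary-flux buffer; probe coordinates advance by ``dt``.  A
    probe reaching ``t* = B`` merges its residual mass into the now-oldest
    probe (neurons beyond the bound are lumped there) and restarts at
    ``t* = 0`` carrying the accumulated flux, so total mass is conserved
    exactly.  Sets ``state.nu`` and returns the recycled probe index or -1.
    """
    hazard = np.asarray(hazard, dtype=float)
    if hazard.shape != state.rho.shape:
        raise ValueError("hazard field shape mismatch")
    probe_flux = np.empty(state.grid.n_intervals)
    nu = K.density_step(state.rho, hazard, state.flux,
                        state.weights.bin_masses, probe_flux, dt,
                        int(np.argmin(state.t_star)))
    if np.any(state.rho < 0):
        raise FloatingPointError("negative density mass")
    state.nu = nu
    state.t_star += dt
    recycled = -1
    bound = state.grid.bound_B
    for i in np.nonzero(state.t_star >= bound - 1e-9)[0]:
        others = np.delete(np.arange(len(state.t_star)), i)
        j = others[np.argmax(state.t_star[others])]
        state.rho[j, :] += state.rho[i, :]
        state.rho[i, :] = state.flux
        state.flux[:] = 0.0
        state.t_star[i] = 0.0
        recycled = int(i)
    return recycled


def firing_rate(state: PopulationState, hazard: np.ndarray) -> float:
    """Population firing rate (1/ms): psi-weighted hazard flux of the density."""
    hazard = np.asarray(hazard, dtype=float)
    return float(np.einsum("k,ik,ik->", state.weights.bin_masses, state.rho, hazard))


def map_bin_voltages(u, u_free, weights: WeightDistribution) -> np.ndarray:
    """Affine rescaling of the synaptic perturbation per weight bin.

    Returns an array of shape ``(n_probes, n_bins)`` with
    ``U_x = U_free + (U - U_free) * x``.
    """
    u = np.asarray(u, dtype=float)
    u_free = np.asarray(u_free, dtype=float)
    return u_free[:, None] + (u - u_free)[:, None] * weights.bin_scales[None, :]


def mean_voltage(state: PopulationState, u=None, u_free=None) -> float:
    """Density- and psi-weighted mean membrane potential (mV)."""
    u = state.u if u is None else np.asarray(u, dtype=float)
    u_free = state.u_free if u_free is None else np.asarray(u_free, dtype=float)
    ux = map_bin_voltages(u, u_free, state.weights)
    w = state.weights.bin_masses[None, :] * state.rho
    return float((w * ux).sum() / w.sum())
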