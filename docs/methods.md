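# Methods

## Model overview

`cbrd_iid` simulates two recurrently coupled cortical populations — adaptive
regular-spiking pyramidal cells (E) and fast-spiking interneurons (I) — with
the conductance-based refractory density (CBRD) method, in the pro-epileptic
condition where the GABA-A reversal potential `V_GABA` is depolarised.  The
model generates the two types of interneuron-triggered interictal discharges:

* **IID1** (`V_GABA = -50 mV`): spontaneous interneuron spikes are amplified
  by the depolarising GABAergic recurrence within the interneuron network;
  the pyramidal population receives the GABAergic volley but stays below its
  firing threshold, so the discharge is purely GABAergic.
* **IID2** (`V_GABA = -45 mV`): the GABAergic depolarisation now reaches the
  pyramidal threshold; recurrent AMPA/NMDA excitation takes over and
  maintains the discharge, producing the characteristic outward-then-inward
  clamp current at a holding potential of −27 mV.

Both discharge types terminate through short-term synaptic depression: the
presynaptic resources `x_glu`, `x_gaba` (use fraction 0.04, recovery
2000 ms) deplete during a discharge and gate the next one, which sets the
discharge duration and the seconds-scale inter-event interval.  With
depression frozen at 1 the network instead switches irreversibly into a
sustained high-activity state.

## The refractory-density solver

Each population is a density `rho(t, t*)` over the time since the last
spike, discretised on a Lagrangian grid of probe neurons (E: 100 probes on
[0, 100] ms; I: 50 probes on [0, 40] ms).  Probe neurons integrate the
Hodgkin-Huxley-style membrane and gating equations along the characteristics
`dt* = dt`; the density loses mass at the hazard rate `H` and the lost flux
re-enters at `t* = 0`.  The firing rate is the psi-weighted hazard flux
`nu = sum_x psi(x) sum_probes rho H`.

**Hazard.**  `H = A + B` with `T = (V_th(t*) - U) / (sqrt(2) sigma_V)`.
`A` is an exponential-polynomial approximation of the colored-noise
first-passage rate, scaled by `1/tau_m` with `tau_m = C/g_tot` for the
momentary total conductance and `k = tau_m/tau_noise` (`tau_noise = 4 ms`).
`B = 2 [-dT/dt]_+ F(T)` with `F(T) = sqrt(2/pi) exp(-T^2)/(1 + erf(T))`
fires only while the state drifts toward the relaxing threshold
`V_th(t*) = base + amp*exp(-t*/10 ms)`.  Numerical guards: `T` clamped to
[−3, 8] inside the polynomial (outside, `A` saturates, respectively
vanishes); `F` evaluated by its asymptote `sqrt(2)|T|` below `T = -6`;
`H` clamped to `1/dt`; `H = 0` inside the spike window `t* < dt_AP` where
the voltage is pinned by the boundary conditions.

**Noise amplitude.**  `sigma_V` is the dispersion of an individual neuron's
voltage fluctuations, 2 mV (E) and 3 mV (I) at rest.  It grows with the
synaptic drive; the implementation uses the bounded form
`sigma_V = sigma_0 (1 + g_syn/(g_tot0 + g_syn))`, i.e. the drive is
measured against the momentary total conductance and the amplitude
saturates at `2 sigma_0`.  A resting-normalised variant
(`sigma_0 (1 + g_syn/g_tot0)` with `g_tot0 = C/tau_m0`) lets `sigma_V`
reach 8–20 mV during discharges; under that reading the coupled network
settles into a permanently active state at every `V_GABA` and produces no
discrete discharges at all, so the bounded form is the package default.
The composition of `g_tot0` is not uniquely determined by the printed
parameters; `g_tot0 = C/tau_m0` is consistent with the leak plus the
resting AHP conductance for E and with leak plus resting `I_K` for I.

**Lognormal synaptic weights.**  Within each population the synaptic input
is scaled per neuron by a lognormally distributed factor `x`
(`sigma_LN = 0.5`, 10 equal-probability bins, conditional-mean
representative scales).  Only the density is resolved per bin: bin voltages
are the affine map `U_x = U_free + (U - U_free) x` of the mean-input
trajectory and the zero-input (free) trajectory, both integrated alongside.
Because `x` multiplies the *mean-scaled* input, the bin scales are
normalised so that `E[x] = 1` (the printed density has median 1 and mean
`exp(sigma_LN^2/2) = 1.13`); a config switch (`mean_normalize_weights`)
restores the unnormalised variant.  With the unnormalised scales the top
weight decile receives enough surplus drive to recruit the pyramidal
population during IID1 and to prevent IID2 termination, contrary to the
discharge phenomenology the model exists to reproduce.  The affine map
linearises conductance saturation, so the strongest bins overestimate their
depolarisation for somatic GABA input; this is a known limitation of the
weight-distribution extension.

**Boundary conditions.**  A probe reaching `t* = B` merges its residual
mass into the now-oldest probe (neurons beyond the bound are lumped there)
and restarts at `t* = 0` carrying the boundary flux accumulated over the
last `B/N` interval, so total mass is conserved to machine precision.  If
flux arrived (the population fired), the probe takes the spike-state reset:
`U = -40 mV`, dendrite at rest, hard gate resets for the repolarising
currents (I_DR x/y = 0.262/0.473, I_A x/y = 0.743/0.691, I: n = 0.45), and
the slow adaptation gates incremented from their values at the peak of the
release distribution `t*_p` (I_M: +0.175 of the gap to 1, I_AHP: +0.018).
If no flux arrived, recycling is purely a coordinate bookkeeping step: the
probe keeps its carried state, no reset is applied and no adaptation
conductance is injected, which keeps a quiescent population exactly
stationary.  Mass waiting in the boundary buffer (neurons at
`t* < B/N`) contributes to the rate integral with the youngest probe's
hazard — zero whenever the buffer lies inside the spike window, exact in
the renewal limit.

**Membranes.**  E is two-compartment: somatic GABA (`I_soma =
g_GABA (V_GABA - U)`), dendritic glutamate passed through the
transient-sharpening operator `(l tau_m0/2 d/dt + 1 + l/2)` applied to
`g_AMPA (0 - U) + g_NMDA f_NMDA(U) (0 - U)` with a one-step backward
difference.  The squared dendritic length ratio `l` has no published
value; the default is `l = 1` (dendrite one characteristic length long),
exposed in the config.  Compartment coupling is `2 gamma/l g_L` (somatic)
and `2/l g_L` (dendritic) with `gamma = 2.85`.  I is single-compartment
with `I_K`, somatic AMPA/NMDA/GABA and gap junctions
`g_GJ (U_mean - U)` toward the density-weighted population mean.  All
printed maximal conductances are interpreted as mS/cm² (a µS/cm² reading
would make the leak time constant ~10^5 times too long).  Voltages update
by exponential Euler with the conductance terms in the decay rate; gates
by exponential Euler toward their steady states; `dU/dt` for the hazard
drift term is the pre-update right-hand side, which avoids recycling
artifacts.

**Initial state.**  Populations start at their self-consistent resting
equilibrium (the resting potassium conductances shift it ~0.7–1.4 mV below
the nominal leak reversal), with all density at `t* = B` and gates at
steady state; protocols discard a 1 s burn-in (except the depression-off
protocol, whose transition time is measured from the resting start).

## Synapses and depression

Each projection's dimensionless conductance `m` obeys
`tau_r tau_d m'' + (tau_r + tau_d) m' + m = tau_s (1 - m) phi` with the
presynaptic population rate `phi` (no axonal delay) and the normalisation
`tau_s` chosen so that a brief presynaptic volley of unit area produces a
unit peak of `m` in the linear regime, independent of `(tau_r, tau_d)`.
The pair is integrated by RK4 with `phi` frozen over the step.  NMDA is
multiplied by the magnesium block `1/(1 + Mg/3.57 exp(-0.062 V))`
(`Mg = 0.25 mM`), evaluated per probe at the somatic voltage.  One
glutamatergic and one GABAergic depression resource are shared by all
projections of the same mediator class and multiply their conductances;
the resource ODE is advanced by its exact exponential update for frozen
rates.  An NMDA projection onto the interneurons is included with its
printed weight (0.2 mS/cm²) even though the interneuron membrane equation
as published lists only AMPA and GABA terms.

## Drive, stimulation and observables

The stochastic drive is a single Ornstein-Uhlenbeck current (SD 20 pA,
correlation 4 ms), common to the interneuron population (optionally also to
E); individual variability is carried by `sigma_V` inside the hazard, not
by per-neuron input noise.  The exact OU discretisation is used.
"Extracellular" stimulation for the evoked-IPSC protocols is a train of
synchronous presynaptic volleys (default 25 pulses at 20 Hz, one spike per
presynaptic neuron per volley) injected into both GABA projections; the
control condition holds `V_GABA = -70 mV` with recurrent feedback disabled
so the responses are monosynaptic.

Observables: population rates, psi/rho-weighted mean voltages, projection
conductances (densities; nS via the 10^-4 cm² membrane area), the virtual
voltage-clamp current `I = g_GABA (V_h - V_GABA) + g_AMPA V_h +
g_NMDA f(V_h) V_h` (outward positive; −27 mV for discharge traces, 0 mV
for IPSC trains), the depression resources, and an LFP proxy.  The LFP is
the negative density-weighted somato-dendritic axial current of the E
population, `-c <(2 gamma/l) g_L (U_d - U)>`, so dendritic excitation
deflects it negative; only its sign and shape are meaningful, the gain `c`
is arbitrary.

## Monte-Carlo reference

`mc_oracle` simulates N individual neurons with the identical membrane,
channel and reset equations, the common injected current, and an explicit
threshold crossing of `V_th(t_since_spike)`.  Individual noise is an OU
current whose amplitude tracks the neuron's momentary total conductance,
`sigma_I(t) = sigma_V g_tot(t) sqrt(1 + tau_m(t)/tau_noise)`, so the
subthreshold voltage SD equals `sigma_V` at all times — the exact premise
of the hazard function.  (A rest-calibrated fixed `sigma_I` lets the
voltage noise collapse several-fold when the slow potassium conductances
activate, which tests the noise model rather than the density solver.)

The equivalence check runs one isolated population (single weight bin, no
synapses, no common noise) under a step or step-plus-sinusoid current and
compares 20 ms-binned rates.  The quantitative window starts 100 ms after
the stimulus onset: an instantaneous common step locks the whole ensemble
into delta-like synchronous volleys whose allocation to individual rate
bins is not meaningful for either solver (the ringing frequency itself
agrees from the first volley on).  At the default drives the normalized
RMS error is ~5% (E) and ~11% (I), within the 15% band expected for this
method family.  The residual steady-state offset for E reflects the
single-trajectory treatment of adaptation: the ensemble's adaptation-state
heterogeneity raises its mean rate slightly above the density solution.

## Event analysis

Discharges are detected on the interneuron rate trace with a hysteresis
threshold (on 10 Hz, off 2 Hz, minimum duration 10 ms, merge gap 50 ms) and
classed IID2 when the pyramidal population fires during the event (peak
`nu_E` > 2 Hz), IID1 otherwise.  Statistics: frequency = events per second
of simulated time; CV = SD/mean of inter-onset intervals (undefined below
two events and flagged); per-event conductance ratios are ratios of
within-event maxima.  The voltage-clamp decomposition solves, per 1 ms bin,
the nonnegative least-squares system `I(V_h) = g_AMPA f_AMPA(V_h) +
g_GABA f_GABA(V_h) + g_NMDA f_NMDA(V_h)` across holding potentials
(nonnegativity because conductances are physical; rank-deficient template
sets are rejected naming the potentials).  Model-generated templates are
`f_AMPA = V`, `f_GABA = V - V_GABA`, `f_NMDA = V * block(V)`.  `V_GABA`
estimation fits the GHK current equation for a monovalent anion with free
permeability scale and internal chloride (external chloride 132.5 mM from
the bath composition, 30 °C); the reported reversal is the Nernst potential
of the fitted concentrations, and fits without a sign change in the I-V
points are rejected.

## Synthetic fixtures

The fixture generator produces (i) multi-potential clamp recordings
synthesised from prescribed alpha-shaped conductance waveforms through the
template forward model, with optional Gaussian current noise; (ii) rate
traces with boxcar discharges planted at known times; (iii) GHK I-V samples
with known internal chloride.  Ground truth is stored with each fixture.
These fixtures exercise the analysis operations exactly; they do not carry
the correlated noise, drifts and access-resistance artifacts of real
recordings, so passing recovery tests demonstrates correctness of the
estimators, not robustness to every experimental nuisance.

## Problem sizes and numerical defaults

Time step 0.1 ms (an integer divisor of both probe spacings, so exactly one
probe recycles every 10 steps for E and every 8 for I); traces recorded at
1 ms.  Discharge statistics pool 3 seeds × 100 s per protocol; the
depression-off transition uses 5 s runs; the Monte-Carlo comparison uses
4000 neurons × 2.5 s.  All randomness in a simulation flows from the single
config seed (numba's RNG is seeded once per run), so identical
configurations reproduce traces bit for bit.

## Known limitations

* Per-bin weight heterogeneity shares one set of gating variables and one
  adaptation state with the mean trajectory; strongly driven bins would in
  reality adapt more.
* sigma_V enters as a population-level scalar; it is not resolved per
  weight bin.
* Discharge durations run ~2x longer and event frequencies ~1.5-2x higher
  than the published reference statistics under the default detector; the
  regime structure (class separation, regularity ordering IID2 < IID1,
  depression-controlled termination, sustained state without depression)
  is reproduced.
* Ionic concentrations are fixed; ictal (seizure-like) regimes, GABA-B
  currents and spatial propagation are out of scope.
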