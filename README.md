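# cbrd-iid

A conductance-based refractory density (CBRD) model of interneuron-triggered
interictal discharges, with the matching trace-analysis toolbox.

Interictal discharges (IIDs) are brief synchronized network events recorded
between seizures.  In the pro-epileptic condition (high K⁺, low Mg²⁺,
4-aminopyridine), intracellular chloride accumulates and the GABA-A reversal
potential `V_GABA` depolarises, turning GABA into an excitatory transmitter.
This package simulates two recurrently coupled cortical populations —
adaptive two-compartment pyramidal cells (E) and fast-spiking interneurons
(I) with gap junctions — and reproduces the two discharge types this
mechanism generates:

* **IID1**, purely GABAergic: regenerative GABA excitation within the
  interneuron network (`V_GABA = −50 mV`); pyramidal cells receive the
  volley but do not fire.
* **IID2**, GABA-initiated and glutamate-maintained (`V_GABA = −45 mV`):
  the GABAergic depolarisation recruits the pyramidal population, and
  recurrent AMPA/NMDA excitation carries the discharge, visible as an
  outward-then-inward clamp current at −27 mV.

Short-term synaptic depression (resource `x_D` with use fraction `U = 0.04`
and recovery `τ = 2000 ms`) terminates each discharge and sets the
seconds-scale inter-event interval; with depression disabled the network
switches irreversibly into a sustained high-activity state.

## The method

Each population is evolved as a neuronal density `ρ(t, t*)` over the time
since the last spike.  Probe neurons on a Lagrangian `t*` grid integrate
Hodgkin-Huxley-style membrane and gating equations
(`I_DR, I_A, I_M, I_AHP` for E; `I_K` for I), and the density loses mass at
the hazard rate

    H = A(T, k) + 2 [−dT/dt]₊ F(T),   T = (V_th(t*) − U) / (√2 σ_V),

the sum of a colored-noise threshold-crossing term and a drift term, with
the relaxing threshold `V_th(t*)` and noise amplitude `σ_V`.  The firing
rate is the hazard flux `ν(t) = ∫ ρ H dt*`, re-injected at `t* = 0` with
spike-state reset conditions.  Lognormally distributed synaptic weights
(σ_LN = 0.5, 10 bins) are carried per weight bin through the affine map
`U_x = U_free + (U − U_free)·x`.  Synaptic conductances follow damped
second-order kinetics driven by the presynaptic population rate; a common
Ornstein-Uhlenbeck current (20 pA, 4 ms) drives the interneurons.  A
Monte-Carlo ensemble of explicit stochastic neurons with identical
equations (module `mc_oracle`) validates the population solution to within
~5–11% normalized RMS error.

See `docs/methods.md` for the full model description, numerical choices and
known limitations.

## Worked example

```python
from cbrd_iid.network import run_protocol
from cbrd_iid.analysis import detect_events, event_statistics

trace = run_protocol("iid2", duration=60000.0, seed=1)   # 60 s, V_GABA = -45 mV
events = detect_events(trace)
stats = event_statistics(events, 60000.0)
print(f"{stats['n_events']} events, {stats['frequency_hz']:.3f} Hz, "
      f"interval CV {stats['cv_intervals']:.2f}")
print(events[["onset", "duration", "peak_nu_i", "peak_i_clamp",
              "event_class"]].head(5).round(1))
```

prints

```
28 events, 0.467 Hz, interval CV 0.40
    onset  duration  peak_nu_i  peak_i_clamp event_class
0     0.0     571.0       78.8         515.0        IID2
1  2171.0    1380.0      126.5         985.2        IID2
2  4427.0      23.0       17.0          55.9        IID1
3  4630.0    1303.0      118.5         936.7        IID2
4  7237.0    1218.0      122.5         957.7        IID2
```

Most detected events are glutamate-maintained IID2 discharges (interneuron
rate peaks above 100 Hz, clamp currents near 1 nA at −27 mV) recurring
every 2–3 s with low interval variability (CV 0.40); occasional small,
short, purely GABAergic events are classed IID1.  Running the `iid1`
protocol instead (`V_GABA = −50 mV`) yields almost exclusively IID1 events
with silent pyramidal cells and a markedly higher interval CV — the model's
signature distinction between the two discharge types.

The same can be done from the shell:

```
cbrd-iid run --protocol iid2 --duration 60 --seed 1 --out iid2.h5
cbrd-iid analyze iid2.h5 --out events.tsv
```

Other protocols: `iid1`, `no_depression` (depression frozen at 1 — the
network transitions to a permanent high-activity state within the first
seconds), `evoked_ipsc_control` and `evoked_ipsc_proepileptic` (25-pulse
20 Hz afferent trains read out at a 0 mV clamp; IPSC amplitudes run down
only when depression is enabled).  `cbrd-iid validate-oracle` runs the
CBRD-versus-Monte-Carlo equivalence check, `cbrd-iid decompose` applies the
voltage-clamp conductance decomposition to a multi-potential recording, and
`cbrd-iid fixture` generates synthetic test data with known ground truth.

Analysis utilities: `detect_events` (hysteresis detector on the interneuron
rate, IID1/IID2 classification), `event_statistics`, `conductance_ratios`
(per-event AMPA/GABA and NMDA/GABA peak-conductance ratios),
`decompose_conductances` (nonnegative least-squares decomposition of
multi-potential clamp currents into mediator conductances, 1 ms bins) and
`fit_vgaba_ghk` (Goldman-Hodgkin-Katz fit of `V_GABA` from I-V points).

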