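# reactorlifelines

Microbial **lifeline analysis** for gradient-rich industrial bioreactors, built
around a compartment-network surrogate of a 54 m³ two-Rushton penicillin
fermenter.

In a large fed-batch or chemostat vessel, glucose is fed at one point and
consumed everywhere, so cells circulating with the broth experience feast–famine
cycles rather than the average concentration. The time series of the scaled
uptake rate

  q_rel(t) = q_s / q_s,max = C_s / (K_s + C_s)   (Monod kinetics)

experienced by one tracked cell cluster (*parcel*) is its **lifeline**. This
package generates lifelines with known ground truth, applies the standard
statistics used for scale-down design — regime residence-time analysis and
threshold arc analysis — and converts the fluctuations into a relative loss of
the specific penicillin production rate q_p via a structured kinetic model.

## What it does

- **Compartment surrogate** (`network`, `tracer`, `substrate`, `calibration`):
  two circulation loops (one per impeller) joined by an inter-impeller exchange
  flow, calibrated by nested bisection so a simulated tracer pulse reproduces
  measured probe metrics (circulation time τ_circ = 2 × lag to 5% probe
  saturation; 95% mixing time τ_95). A constant feed with a volumetric Monod
  sink (q_s,max = 1600·10⁻⁶ mol/g_dw/h, K_s = 7.8·10⁻⁶ mol/kg, C_x = 55
  g_dw/kg) yields the steady substrate field and its excess / limitation /
  starvation regime layout (q_rel > 0.95 / between / < 0.05).
- **Parcel transport** (`parcels`): massless parcels follow the flow as an
  exact continuous-time Markov chain over compartments (jump rate
  flows[i,j]/V_i); lifelines are sampled every Δt_p = 0.03 s, with the first
  100 s discarded. First-passage theory on the same chain
  (`residence_oracle`) provides exact residence-time references.
- **Lifeline statistics** (`regimes`, `arcs`): moving-average filter
  (τ_lag = 0.36 s), hysteresis transition registration (boundary ± 0.01),
  residence-time distributions per transition pattern (LEL, LSL, ELE, ELS,
  SLE, SLS) with mean τ̄_reg = Σ τ·n_τ / Σ n_τ, Lagrangian regime fractions,
  and arc duration/magnitude (τ_arc, Ω_s,max) statistics about a single
  threshold.
- **Metabolic response** (`metabolism`, `pools`, `nine_pool_synthetic`):
  lifelines are merged back-to-back into composites spanning tens of process
  hours, fed into a pluggable multi-pool kinetic model initialised at its
  chemostat fixed point, and the ensemble q_p loss relative to ideal mixing is
  reported. A documented two-pool toy model and a synthetic nine-pool
  penicillin model (glucose repression + starvation energy limitation) are
  included.
- **CLI** (`reactorlifelines calibrate|mix|gradient|parcels|analyze|metabolic|all`,
  `analyze-external`): YAML-configured, deterministic, CSV + JSON report
  bundle. External CFD-produced lifelines enter through a documented CSV
  schema (`parcel_id,time_s,q_rel` + YAML sidecar).

## Worked example

```python
import reactorlifelines as rl

calib = rl.calibrate_network()                       # two-loop surrogate
print(f"tau_circ = {calib.achieved.tau_circ:.1f} s, tau_95 = {calib.achieved.tau_95:.1f} s")

network = calib.network.with_feed(0.37)              # 0.37 mol/s glucose feed
kinetics = rl.KineticsParams.penicillin_reference()
field = rl.steady_substrate_field(network, kinetics, feed=0.37)
print(f"volume-mean saturation = {field.volume_mean_saturation():.3f}")
print("compartment regimes:", "".join(field.regime))

raw = rl.simulate_parcels(network, field, n_parcels=100,
                          duration=700.0, sample_dt=0.03, seed=7)
lifelines = rl.discard_initial(raw, burn_in=100.0)
fractions = rl.regime_fractions(lifelines)
print("Lagrangian regime fractions [%]:",
      {k: round(v, 1) for k, v in fractions.items()})
```

prints

```
tau_circ = 20.7 s, tau_95 = 58.8 s
volume-mean saturation = 0.278
compartment regimes: ELLLSSSS
Lagrangian regime fractions [%]: {'E': 6.8, 'L': 30.1, 'S': 63.1}
```

The calibrated surrogate reproduces the vessel's probe metrics (targets
21.7 s / 58.8 s within 10%); the volume-mean saturation equals the analytic
feed balance F_s/(q_s,max·C_x·M) ≈ 0.278; the feed-zone compartment sits in
excess while the bottom circulation loop starves, and parcels register those
zones in proportion to how long they reside there.

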