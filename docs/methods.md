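# Methods

This note documents the models behind `reactorlifelines`: what is being
approximated, the parameters that matter, the numerical choices, and what the
synthetic machinery can and cannot say about real reactors.

## 1. The reactor and its surrogate

The target system is an industrial 54 m³ penicillin fermenter: a flat-bottom
tank (diameter T = 3 m, liquid height H_l = 7.7 m, broth treated as water at
ρ = 1000 kg/m³) stirred by two Rushton turbines, fed 0.37 mol/s glucose at the
top. In such two-impeller vessels, circulation loops form around each impeller
and the exchange across the inter-impeller plane is rate-limiting for mixing.

The package replaces resolved CFD with a **compartment network**: well-mixed
zones exchanging volumetric flow. The default preset is two closed one-way
loops of four compartments each (eight total), joined by a symmetric exchange
flow across the inter-impeller plane — the minimal structure that reproduces
the two-compartment mixing bottleneck. Tracer/feed injection is in the top
compartment; the mixing probe sits mid-way round the bottom loop, mirroring
the top-injection / bottom-probe protocol.

Compartment volumes: the feed-zone compartment takes 7.8% of the total volume
and the rest is split evenly. The feed zone must be much smaller than a
quarter-loop to resolve the glucose-excess region around the feed point at
all; 7.8% ties its volume share to the Lagrangian excess fraction observed in
the reference simulation of this reactor, which is the one number the preset
is asked to reproduce structurally. Molecular diffusion of glucose
(D ≈ 6·10⁻¹⁰ m²/s) is negligible against convective exchange at compartment
scale and enters no exchange term; an optional `dispersion_rate` adds
symmetric flow on connected pairs to emulate turbulent dispersion when wanted.

**Calibration.** The two free flows map nearly orthogonally onto the two
probe metrics: in-loop circulation flow → circulation time (τ_circ, twice the
lag to 5% probe saturation), inter-loop exchange → 95% mixing time (τ_95,
last departure from the ±5% band around the plateau). `calibrate_network`
alternates bracketed Brent searches on the two flows (both metrics are
monotone decreasing in their flow) until both land within 10% (configurable)
of the targets, by default τ_circ = 21.7 s and τ_95 = 58.8 s — the probe
metrics measured for this vessel. The calibrated preset lands at circulation
≈ 1.1 m³/s and exchange ≈ 1.9 m³/s.

**Tracer transport.** At compartment granularity the scalar transport
equation reduces to the linear system dC/dt = A·C with
A[i,j] = exchange[j,i]/V_i. It is marched with fixed-step RK4; the step must
resolve the fastest compartment turnover (dt ≤ 0.1·min V_i/outflow_i), and
total tracer mass — a linear invariant — is checked to 1e-8 relative. The
standard pulse is 0.5 mol/L in a 0.4 m sphere (≈ 16.8 mol), injected as a
point source into the feed compartment (the sphere is far smaller than any
compartment).

## 2. Substrate gradient

Uptake is Monod: q_s = q_s,max·C_s/(K_s + C_s) with q_s,max = 1600·10⁻⁶
mol/g_dw/h, K_s = 7.8·10⁻⁶ mol/kg, biomass C_x = 55 g_dw/kg. The steady
field solves A·C + f − q_s,max·C_x·C/(K_s+C) = 0 (f = feed per unit broth
mass). Following the transport solver's structure, the field is marched by
operator splitting — an exact exchange propagator expm(A·dt) followed by an
RK4 reaction step (dt = 0.05 s; the reaction relaxation rate is bounded by
q_s,max·C_x/K_s ≈ 3.1 s⁻¹, so the step is stable and accurate). A Lie-split
fixed point retains an O(dt) commutator residual, so the marched field is
polished with damped Newton iterations on the full steady-state equations
down to max|dC_s/dt| < 1e-10 mol/kg/s.

At steady state, feed equals consumption, which fixes the mass-weighted mean
saturation exactly: mean(q_rel) = F_s/(q_s,max·C_x·M) ≈ 0.278 for the
reference conditions. This closure (to 0.5%, and feed = consumption to 0.1%)
is the primary analytic check. Feed at or above q_s,max·C_x·M has no steady
state and raises a washout error.

Eulerian regime labels per compartment use plain thresholds: starvation
q_rel < 0.05, excess q_rel > 0.95. The calibrated default gradient comes out
as E L L L | S S S S from feed to bottom.

## 3. Parcel transport and lifelines

Parcels are massless (micron-sized cells, Stokes number ≈ 0) and follow the
liquid exactly. At compartment granularity this is a continuous-time Markov
chain with jump rate flows[i,j]/V_i. Trajectories are generated
**event-driven** (exact exponential waiting times), not with per-step jump
probabilities: this removes time-discretisation bias and makes first-passage
theory an exact oracle. Because the network is flow-balanced, the stationary
occupancy is proportional to compartment volume; parcels are initialised from
that distribution rather than from a localised release, and the study's 100 s
burn-in discard is still applied by default for fidelity to the recording
protocol (the spec of a localised release followed by ~60 s dispersal is a
CFD artefact the surrogate does not need).

Lifelines sample the current compartment's q_rel every Δt_p = 0.03 s
(decoupled from the jump process), giving floor(duration/Δt_p)+1 samples with
the first at t = 0; the default study conditions are 2500 parcels × 2000 s
with the first 100 s discarded (the burn-in drops floor(100/0.03) = 3333
samples, leaving 63,334 of 66,667). Sample times are always reconstructed as
t_start + k·Δt_p, never accumulated, to avoid floating drift over 66k
samples. By default parcels ride over the *frozen* converged field
(quasi-steady gradient); the gradient of the real reactor is statistically
stationary, and a dynamic field is a documented extension, not the default.

`residence_oracle` computes the expected mean sojourn in any compartment
subset from the fundamental matrix of the chain restricted to the subset,
weighted by the stationary entry flux. Empirical residence means from
sampled lifelines agree with it within two standard errors *provided the
subset's uptake levels sit clear of the hysteresis bands* (a compartment
inside a band makes visits history-dependent, which the subset-sojourn
oracle does not describe); the test networks are chosen accordingly.

## 4. Regime and arc analysis

Regimes on lifelines: starvation S (q_rel < 0.05), excess E (q_rel > 0.95),
limitation L between. Before classification a **centered moving average**
with window τ_lag = 0.36 s is applied — w = round(τ_lag/Δt_p) = 12 samples;
an even window centered on sample k spans [k−6, k+5], truncated at the series
ends, so results are bit-reproducible. A centered (non-causal) filter is
chosen over a trailing one because it adds no phase lag that would bias
transition times; the trailing alternative would shift every transition by
~τ_lag/2.

Transitions register only when the smoothed signal passes the boundary by a
hysteresis margin of 0.01, with strict inequalities: E→L only below 0.94,
L→E only above 0.96, and 0.04/0.06 at the starvation boundary; a sample
resting exactly on a shifted boundary does not trigger. The initial regime
uses plain thresholds on the first smoothed sample; first and last visits are
censored and excluded from all distributions. A single-sample jump across
both boundaries registers both transitions at the same timestamp with a
zero-duration L visit, which keeps the visit sequence alternating and is
excluded from statistics. Passages through limitation are coded by origin and
destination (ELE, ELS, SLE, SLS); excess and starvation visits are LEL and
LSL. (Reference tables that label the starvation residence itself "SLS" are
mapped here to the unambiguous LSL.) Mean residence per pattern is
Σ τ·n_τ / Σ n_τ over exact, un-binned durations; histograms default to 0.3 s
bins (10 samples; the reference binning is unstated).

Arc analysis applies the same filter and hysteresis about a single threshold
(default 0.05): alternating above/below arcs, above arcs carrying the maximum
smoothed q_rel (Ω_s,max). With the threshold on the starvation boundary,
below-arc durations coincide exactly with LSL residence times — asserted in
the tests. Joint (τ_arc, Ω_s,max) statistics are column-normalised per
duration bin with a mean-magnitude curve.

## 5. Metabolic response

Slow intracellular pools respond over hours, so recorded lifelines are merged
back-to-back (uniform sampling with replacement, seeded) into **composite
lifelines** spanning 80 h by default, ensemble of 15 (10 is a supported
alternative); the brief uptake jump at each merge point is immaterial to the
slow pools. Pools start from the **chemostat fixed point** at constant uptake
equal to the reactor's volume-mean saturation (≈ 0.278) — found by 50 h of
relaxation plus a root polish to residual norm < 1e-10 — and the loss is
100·(q_p,ref − mean final q_p)/q_p,ref over the ensemble.

**Pool models are pluggable.** The published nine-pool penicillin model's
equations and parameters live in literature supplementary material that is
not reproduced here, so the package ships:

- `two_pool_toy` — frozen transport capacity plus one product precursor with
  dx/dt = k(u−x), q_p = x/(K+x): the minimal concave-response (Jensen)
  mechanism by which fluctuations at fixed mean uptake cost productivity.
- `nine_pool_synthetic` — a *synthetic* structured model with the reported
  pool layout (frozen glucose-transport capacity xE11, glycolytic and ATP
  pools, three amino-acid precursors, ACV, isopenicillin N, and a slow
  penicillin-synthase expression level). Its two loss mechanisms are the
  documented physiology of the organism: starvation drains the fast
  energy/precursor pools, and glucose excess represses synthase expression
  (carbon catabolite repression, τ ≈ 2 h). Turnover rates (30 s for ATP,
  1 min glycolysis, 10 min precursors, 2 h expression) and saturation
  constants are chosen on order-of-magnitude physiological grounds; the model
  is suitable for *relative* losses and directional comparisons only, and its
  absolute q_p carries no literature pedigree.

The transport-capacity pool is frozen (chemostat mimic), so its equation is
inert and it is excluded from fixed-point solving.

**Integration.** The uptake input is piecewise constant at sub-second scale,
which is pathological for adaptive stiff solvers (they pay per-switch without
gaining accuracy on pool timescales ≥ 30 s). The default integrator
block-averages the input to 0.5 s and takes one classical RK4 step per input
interval, vectorised across the ensemble; stability is checked against the
model's declared fastest rate (needs fastest_rate·dt < 2.78, satisfied by two
orders of magnitude at the defaults). An LSODA path (rtol 1e-8) is retained
for smooth/constant inputs and serves as the cross-check route in the tests;
the two routes agree to ~0.2% on slow pools, with fast tracking pools
differing only through the adaptive solver's smearing of input switches.

Under the calibrated surrogate's gradient the synthetic nine-pool model loses
roughly three quarters of its chemostat q_p, and a five-fold better-mixed
variant loses distinctly less; the package asserts only the *direction* of
that comparison (sharper gradients → larger loss), which is the property the
synthetic model is designed to carry. The ideal-mixing control (each lifeline
replaced by its time mean) gives ≈ 0% loss, and the loss is non-decreasing in
the starvation fraction of synthetic two-level lifelines at fixed mean
uptake.

## 6. What the surrogate does and does not show

The surrogate reproduces: the two-loop mixing bottleneck and its probe
metrics, exact mass/feed balances, volume-proportional parcel occupancy, a
gradient spanning all three regimes with the excess share tied to the feed
zone, and the full statistical machinery applied to lifelines with known
ground truth. It does **not** reproduce: turbulent fine structure and
macro-instabilities (lifelines are piecewise-constant over compartment
visits, hence less "noisy" than CFD lifelines), spatially resolved regime
maps, gas-phase or rheology effects, or the reference run's exact residence
distributions — with eight compartments, intra-loop positional detail is
coarse, which inflates long starvation residences relative to the resolved
simulation. Passing tests therefore validate the *analysis machinery* and
the surrogate's *calibrated mixing/balance behaviour*, not CFD-level gradient
fidelity.

## 7. Problem sizes used in the shipped runs

Tests and the acceptance script run scaled-down conditions chosen as the
package's own defaults for desk use: 60–200 parcels over 500–900 s of flow
time (burn-in 100 s) for lifeline statistics, 15 h / 5–6 composites for the
metabolic ensemble, and first-passage checks on 4–6 compartment networks with
≥ 10⁴ visits. The full study conditions (2500 parcels × 2000 s, 80 h × 15
composites) remain the `PipelineConfig` defaults.

## 8. Known limitations and open choices

- Δt_write (a distinct recording interval) is assumed equal to Δt_p; no
  value was ever stated for it.
- The filter is centered; a trailing filter is the plausible alternative
  (see §4 for why centered was chosen).
- The compartment count (8) is the minimal two-loop structure; finer presets
  are a constructor argument away but are not the tested default.
- The nine-pool parameterisation is synthetic (see §5); swap in a literature
  `PoolModelSpec` for quantitative q_p work.
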