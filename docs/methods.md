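# Methods

## Membrane model

The neuron is a single-compartment regular-spiking cortical cell with four
current densities (µA/cm²): transient sodium ḡ_Na m³h (V−E_Na),
delayed-rectifier potassium ḡ_K n⁴ (V−E_K), slow non-inactivating
potassium (M-current) ḡ_M p (V−E_K), and leak g_leak (V−E_leak).  The
stimulus enters as an additional current density J_stim on the right-hand
side of the membrane equation.  Gating kinetics for m, h, n use the
standard rational/exponential α/β forms shifted by the spike-threshold
adjustment voltage V_T; the M-current gate p relaxes toward a logistic
p_∞(V) (midpoint −35 mV, slope 10 mV) with a bell-shaped τ_p(V) scaled by
τ_max.  α_m, β_m and α_n have removable 0/0 points at V_T+13, V_T+40 and
V_T+15 mV; within 10⁻⁶ mV of those voltages the analytic limits (1.28,
1.4 and 0.16 ms⁻¹) are substituted, keeping every rate continuous.

Default parameters (the package's single source of truth,
`HHParameters`): C_m = 1 µF/cm², g_leak = 0.016, ḡ_Na = 50, ḡ_K = 4.8,
ḡ_M = 0.13 mS/cm², E_leak = −70.3, E_Na = +50, E_K = −90, V_T = −61.5 mV,
τ_max = 1123.5 ms.  With these values the resting potential computes to
−73.22 mV.

Assumptions worth keeping in mind: a point neuron (no axonal geometry, so
pulse *direction* PA/AP cannot change the physics and is carried as
metadata), deterministic channels, no temperature dependence, and a
stimulus that enters as a uniform transmembrane current density
proportional to the induced electric field.

## Numerics

* Fixed-step forward Euler, dt = 1 µs, 20 000 steps (20 ms window);
  stimulus onset at t = 0, the rest of the window is stimulus-free so
  delayed spikes can develop.  Rates are evaluated at the current step;
  gates are clamped to [0,1] after every update (Euler can overshoot
  during the AP upstroke).  Halving dt moves the headline threshold by
  ~0.5% (tested bound: <1%), and a 20 ms trace agrees with an adaptive
  high-order integration of the same ODEs to <0.5 mV.
* Initialization: the resting state is solved algebraically — gates at
  their voltage fixed points, V at the first zero of the steady-state
  current above E_K — and cross-checked against a 5 s settle integration
  (agreement < 0.01 mV).
* Spike criterion: first upward crossing of 0 mV anywhere in the window.
  The action potential is all-or-none here (thresholds are identical for
  detection levels 0, +20 or +40 mV), so the exact level is immaterial; it
  is still configurable (`SimulationConfig.spike_voltage`).
* Sign convention: public waveforms are depolarizing-positive; the minus
  sign of the membrane equation is applied in exactly one place (the Euler
  kernel).
* Bisection tolerances: 0.05% MSO for amplitude, 0.1 µs for width — one
  order below the precision the reported values are quoted at.  The
  reported value is the high endpoint of the final bracket (smallest
  stimulus known to spike).  Amplitude searches bracket [0, 200]% MSO
  (auto-doubling to 400% before declaring the configuration unexcitable);
  width searches bracket [1, 1000] µs.  Everything is deterministic —
  repeated runs are bit-identical.

## Stimulus construction

Ideal rectangles stand in for the device's near-rectangular phases; users
who simulate the power electronics can inject sampled waveforms through the
CSV import path.  Phase widths are rounded to the dt grid and the
compensatory amplitude is then re-solved so the discrete phase areas cancel
exactly (the charge-balance invariant is tested at 10⁻⁹, far inside the
0.5% specification).  The major (named-width) phase leads and depolarizes
by default.  The leading-compensatory alternative is exposed
(`major_phase_first=False`, `depolarizing_phase`), but note that a
charge-balanced pulse whose depolarizing phase comes *second* nets
approximately zero depolarization on this membrane (the hyperpolarizing
lead-in is exactly undone) and never fires at any intensity — which is why
major-first is the default everywhere.

The monophasic family's m-ratio is not fixed by the published pulse
descriptions; the default is m = 0.2, matching the unidirectional pulses,
and it is overridable per pulse.

## Intensity calibration and its uncertainty

%MSO maps to current density linearly: amplitude/100 × 2.8 kV ×
100 (V/m)/kV × 0.27 S/m → 7560 µA/cm² at 100% MSO.  This scalar chain is
the weakest link of the whole approach: with the nominal constants the
point neuron is several-fold more excitable than published
population-average motor thresholds for the same pulses (model 8.9% MSO vs
32% MSO measured for the 60 µs, m = 0.2 unidirectional pulse), because a
uniform σE current density ignores cell geometry, the fraction of induced
current that actually crosses the membrane, and population variability.
Quantities referenced to the model's own threshold are immune to this
scale: the threshold pulse width at 120% of the model's RMT computes to
52.5 µs against 47.3 µs measured (~11%), and strength–duration *shapes*,
parameter sensitivities and family comparisons are likewise
calibration-free.  Absolute %MSO predictions should be treated as relative
numbers until the coupling is recalibrated (the `CouplingModel` fields are
the knobs; individualizing them per subject is the natural extension).

## Sensitivity analysis

One-at-a-time sweeps recompute the threshold of the reference pulse
(unidirectional, initial-AP, m = 0.2; width 60 µs — the published reports
never print the reference pulse's width, so the validation pulse's width is
reused) with exactly one quantity changed per grid point (enforced by a
field-diff test).  Stated sweep ranges: C_m 0.6–1.4 µF/cm², ḡ_Na
10–90 mS/cm², ḡ_M 0.0325–0.52 mS/cm², coupling 21.5–32.5 A/m² per kV
(tissue conductivity ±20%).  g_leak, ḡ_K and τ_max have no stated range
and default to ±50%.  Default grid: 9 points, endpoints included
(acceptance tests use 5).  Normalization defaults to the model's own
default-parameter threshold, since the experimentally measured reference is
not available as a number; an experimental value can be supplied.

Computed orderings at the defaults: C_m dominates (normalized threshold
spans ~0.56–1.46 over its range; threshold rises with capacitance since
more charge is needed per mV), ḡ_Na second (~0.92–1.34, falling as sodium
conductance grows); ḡ_K and τ_max are exactly insensitive at this pulse
duration (the fast-K and M currents barely engage within ~60 µs + spike
latency), and the coupling sweep rescales %MSO exactly inversely (threshold
current density is a membrane property — verified as an internal
closed-form check).  g_leak is the one surprise: over the (invented) ±50%
range it moves the threshold by ~7.6% — not through the membrane time
constant (τ_m ≈ 60 ms ≫ pulse) but by shifting the resting potential and
hence the distance to threshold.  The "<2%" insensitivity bound therefore
holds for ḡ_K and τ_max but not for g_leak at that range width; the
acceptance test records this honestly rather than narrowing the range.

## What the synthetic inputs do and do not show

There are no external datasets; all stimuli are generated by
`build_pulse` under the study conditions (families monophasic /
unidirectional / bidirectional; widths 30–120 µs; m = 0.2; the validation
pair 60 µs @ m 0.2 and its 120%-RMT width search).  Ideal rectangles omit
capacitor droop and switching transients of real devices — effects on
threshold are expected at the few-percent level and can be probed through
the CSV waveform import.  Passing tests therefore demonstrate correctness
of the model, the searches and the calibration arithmetic, and the *shape*
claims (strength–duration monotonicity, sensitivity ordering); they do not
demonstrate absolute %MSO accuracy in humans, for the calibration reasons
above.

## Problem sizes

Default runs integrate 20 000 Euler steps per trial; an amplitude bisection
needs ~13 trials (<0.2 s), the full validation pipeline ~26 trials, and the
seven-parameter sensitivity study at 9 points per sweep ~800 trials (a few
seconds with the JIT-compiled kernel, a few minutes in pure Python).
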