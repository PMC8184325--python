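# ctmsmt

Motor-threshold estimation for controllable-TMS (cTMS) near-rectangular
pulses with a conductance-based cortical point neuron.

## The problem

Transcranial magnetic stimulation (TMS) protocols are calibrated to the
motor threshold (MT) — the lowest stimulator intensity, in percent of
maximum stimulator output (%MSO), that evokes a motor response.  cTMS
devices generate near-rectangular pulses whose width, direction and
phase-amplitude ratio are adjustable, which makes empirical MT hunting
expensive: every new pulse shape needs a fresh titration on human subjects.
`ctmsmt` predicts how MT depends on pulse shape by driving a
Hodgkin–Huxley-type neuron with the pulse's induced current density and
searching for the weakest stimulus that fires an action potential.  It is
aimed at neurostimulation researchers exploring the pulse-shape parameter
space (strength–duration trade-offs, charge-balanced phase design) before
or instead of experiments.

## The model

A single-compartment membrane with four conductances — transient Na⁺,
delayed-rectifier K⁺, slow non-inactivating K⁺ (M-current) and leak —
driven by the stimulus current density J_stim:

    C_m dV/dt = −J_leak − J_Na − J_K − J_M − J_stim
    J_Na = ḡ_Na m³h (V − E_Na),   J_K = ḡ_K n⁴ (V − E_K),
    J_M  = ḡ_M p (V − E_K),       J_leak = g_leak (V − E_leak)

with standard α/β kinetics for m, h, n (threshold-adjustment voltage
V_T = −61.5 mV) and p relaxing to p_∞(V) with time constant τ_p(V),
τ_max = 1123.5 ms.  Equations are integrated by fixed-step forward Euler
(dt = 1 µs, 20 000 steps = 20 ms window).

Pulses are ideal charge-balanced rectangles: a major phase of width PW at
the mapped amplitude, and a compensatory phase at `m_ratio` times that
amplitude and width PW/m, so the phase areas cancel ("m-ratio" is the
minor/major peak ratio; the bidirectional family is the symmetric case
m = 1).  Intensity maps to current density through the device/tissue
coupling: 100% MSO = 2800 V on the coil, 100 V/m induced per kV at the
hand-motor area, J = σE with σ = 0.27 S/m — i.e. 27 A/m² per kV.

The MT surrogate is found by bisection: the smallest %MSO (or, for the
threshold pulse width ThPW, the smallest major-phase width at fixed
intensity) whose waveform elicits an action potential (an upward crossing
of 0 mV).

## Worked example

```
$ ctmsmt mt-amplitude --family unidirectional --pw 60 --m-ratio 0.2 --direction AP
threshold amplitude: 8.9 %MSO

$ ctmsmt sd-curve --family monophasic --widths 30,60,120
 width_us  mt_pct_mso
     30.0   23.339844
     60.0    8.935547
    120.0    3.662109

$ ctmsmt validate
                            label measure     model  experimental units  abs_error  rel_error_pct      provenance  acceptance_eligible
#1RMT 60us m0.2 unidirectional AP     RMT  8.935547          32.0  %MSO  23.064453      72.076416 printed-in-text                 True
               ThPW at 120% #1RMT    ThPW 52.523132          47.3    us   5.223132      11.042563 printed-in-text                 True
```

Reading the numbers: the 60 µs unidirectional pulse (m = 0.2) needs 8.9%
MSO to fire the model neuron; halving the width roughly trebles, and
doubling it roughly halves, the required intensity (the strength–duration
relationship — threshold charge is nearly constant for these brief pulses).
`validate` compares the model's two headline estimates with published
population-average measurements for the same pulse (32% MSO; ThPW 47.3 µs
at 120% of RMT).  The width threshold (52.5 µs vs 47.3 µs measured, ~11%
relative error) is insensitive to the intensity calibration because it is
referenced to the model's own RMT; the absolute intensity is not — with the
nominal coupling constants above, the point neuron is several-fold more
excitable than the population average, so the raw %MSO error is large.  See
`docs/methods.md` for why the %MSO-to-current-density mapping is the
dominant uncertainty, and the `sensitivity` subcommand for how the
threshold depends on each membrane parameter.

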