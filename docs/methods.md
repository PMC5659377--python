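# Methods

This note records the models implemented by `dynclamp`, the numerical
choices behind them, and what the synthetic experiments do and do not
demonstrate.

## Unit system

All internal quantities use mV, pA, nS, ms, pF (and MΩ for resistances).
These are mutually consistent up to fixed powers of ten:
`I[pA] = g[nS]·V[mV]`, `ΔV[mV] = 10⁻³·I[pA]·R[MΩ]`,
`τ[ms] = 10⁻³·R[MΩ]·C[pF]`.  Every CSV column name carries its unit.

## The plant

The model cell is a single-compartment RC circuit,
`C·dV/dt = (E_rest − V)/R + I(t)`, with defaults R = 507.7 MΩ,
C = 35.9 pF, E_rest = −70 mV (the lumped fitted values of a commercial
patch-clamp model cell; τ = RC = 18.23 ms).  Between controller cycles the
plant is advanced with the **exact** exponential solution for
piecewise-constant current — the physical cell is continuous reality, and
only the controller is subject to discretization, so modeling the plant
with Euler would conflate two distinct error sources.  When series
resistance and stray capacitance are both nonzero the update is the exact
matrix exponential of the two-node linear circuit; both default to zero
(bridge balance and capacitance compensation on a real amplifier).

## Conductance models

All conductances inject `I = −g_eff(V − E_rev)`, positive depolarizing.

- **Shunt**: `g_eff = g_max`.
- **HCN**: one activation gate, `g_eff = g_max·s`,
  `ds/dt = −(s − s_inf(V))/τ_s(V)`.  Default kinetics are a Boltzmann
  steady state `s_inf = 1/(1 + exp((V + 82)/9))` (activated by
  hyperpolarization, half-activation −82 mV) and a bell-shaped
  `τ_s(V) = 1 + 50/cosh((V + 82)/14)` ms peaking near half-activation.
  The default reversal (−30 mV) sits near the base of the activation
  curve, the configuration that produces sag and subthreshold resonance.
- **Transient sodium**: `g_eff = g_max·m³h` with classical squid-axon rate
  functions (−65 mV resting convention), an optional voltage shift, and a
  temperature factor q = 3 applied to both gates so that τ_m stays below
  0.5 ms over the physiologic range (τ_m ≈ 60–80 µs between −70 and
  0 mV).  Fast activation is what makes sodium the stress test for a
  real-time integrator.
- **EPSC**: two-stage kinetic synapse, `dx/dt = −x/τ_x + Σᵢδ(t − tᵢ)`,
  `ds/dt = −s/τ_s + α_s·x·(1 − s)`, `g_eff = g_max·s`.  AMPA-like defaults
  τ_x = 1 ms, τ_s = 10 ms, α_s = 1/ms, E_rev = 0 mV.  A spike whose time
  falls in a cycle's window increments x by exactly 1 at that cycle;
  simultaneous spikes sum.  Since ds/dt < 0 at s = 1, s cannot exceed 1
  from below.
- **OU background pair**: independent excitatory and inhibitory
  Ornstein–Uhlenbeck conductances,
  `dg/dt = −(g − g₀)/τ + √D·χ(t)`, stationary variance `σ² = Dτ/2`.
  Note the amplitude convention: some write the noise term as `D·χ(t)`,
  which is dimensionally inconsistent with σ² = Dτ/2 and with D quoted in
  nS²/ms; this package uses `√D`, the convention under which both hold.
  Defaults τ_E = 2.7 ms, τ_I = 10.5 ms, E_E = 0 mV, E_I = −75 mV — the
  standard point-conductance values; all configurable.  Negative
  conductance excursions are allowed by default (faithful to the SDE);
  a rectify-at-zero flag exists.

Kinetics are overridable parametrically or as tabulated `(V, s_inf, τ)`
CSV tables with linear interpolation and flat extrapolation.  An M-type
potassium conductance ships as a configuration of the generic single-gate
machinery (depolarization-activated Boltzmann gate, E_rev = −90 mV),
demonstrating that new single-gate conductances need no new code.

Gate values are **not clamped** to [0, 1] by default: forward-Euler
divergence at large time steps is a real failure mode of real-time
controllers and must be observable.  A per-conductance flag enables
clamping.

## Integrators and their oracles

For the linear relaxation `ds/dt = −(s − s_inf)/τ` at fixed V:

- forward Euler (`s ← s − dt·(s − s_inf)/τ`) is what the emulated
  controller runs; it is stable iff `dt < 2τ` (amplification factor
  `|1 − dt/τ| < 1`) and first-order accurate — the suite verifies a
  log–log error slope of 1 in dt;
- the exact update `s ← s_inf + (s − s_inf)·e^(−dt/τ)` is closed-form for
  piecewise-constant V and composes as a semigroup; it is the oracle;
- classical RK4 provides an independent high-order cross-check (within
  0.1% of exact at 10 µs steps on the sodium voltage-step protocol).

The OU processes use the exact stationary-preserving update
`g ← g₀ + (g − g₀)a + σ√(1 − a²)·N(0,1)`, `a = e^(−dt/τ)`, which keeps
the stationary law correct at any cycle time; an Euler–Maruyama variant
exists for cross-checks.  Randomness comes from a seeded PCG64 generator;
identical seeds give bitwise-identical runs.

A coupled-ODE RK4 reference (`simulate_reference`, default 1 µs step)
integrates membrane plus gates without any rig artifacts.  With ≥24-bit
converters, zero jitter and zero latency, the closed loop's maximum
voltage deviation from this reference halves as the cycle time halves
(measured at 80/40/20 µs).

## The emulated loop

Per cycle: (1) the cycle duration is drawn from a Gaussian
(mean 10 µs, configurable jitter SD, truncated below at half the mean);
(2) V_m is read through amplifier scaling (0.1 V per mV, from the ±90 mV ↔
±9 V convention) → input circuit → 12-bit ADC over 0–3.3 V, then inverted
through the controller's calibration map; (3) every conductance is
advanced by the **measured** elapsed time using the read voltage (Euler
for gates, exact for OU); (4) the summed current is pushed through the
inverse output map, the 12-bit DAC, and the physical output map
(400 pA/V command sensitivity), yielding the current actually injected;
(5) the amplifier command `I_AMP = I_CC + I_DC` takes effect a whole
number of cycles later (default 1, ≈10 µs at ~100 kHz).  The recorded
trace satisfies `I_AMP = I_CC + I_DC` identically at every sample.

Quantizer levels are spaced `span/2^bits` apart with the top of the span
included, so rounding error is bounded by half a step everywhere.  A run
whose |V_m| exceeds 500 mV halts with a `diverged` flag in the metadata,
preserving the partial trace (divergence is data, not an exception).

The controller's calibration map and the true ("physical") circuit map are
separate objects: setting them differently emulates an uncalibrated or
mis-calibrated rig, and the difference appears as a read/write residual.

## Calibration

The ideal circuit maps are affine:
`V_OUT = (1 + R6/R5)[R4R2/((R3+R4)(R1+R2))·V_IN + R3/(R3+R4)·V₊]` for the
input chain and `V_DC = (1 + R10/R9)[R8/(R7+R8)·V_DAC + R7/(R7+R8)·V₋]`
for the output chain, with the published nominal resistor values as
defaults (input slope 0.14649, intercept 1.6001 V; output slope 1.6479,
intercept −3.1685 V).  With these values the full ±9 V amplifier span maps
strictly inside 0–3.3 V, and one ADC step corresponds to 0.055 mV of
membrane potential.  Op-amp non-ideality (bandwidth, slew, non-rail-to-rail
limits) is *not* simulated; component imperfection is represented
abstractly as slope/intercept perturbation plus additive noise in the
fixture generator (default tolerance 2%, matching a few-percent deviation
of real inexpensive parts).

Empirical calibration is ordinary least squares on (known input, measured
output) voltage pairs (≥3 pairs spanning a nonzero range).  Model-cell
calibration recovers both maps from recordings of a cell with known R and
E_rest: voltage commands regress the ADC reading on the commanded
potential (input map); current commands use the Ohmic steady-state
prediction `V = E_rest + I·R` through the already-fitted input map to
regress out the output map.  The summing stage uses unit weights (two
cascaded inverting amplifiers cancel in polarity and, with equal
resistors, in gain); weights are overridable from resistor ratios.

## Analyses

- `fit_rin_tau`: nonlinear least-squares single-exponential fit of the
  step window, initialized from a log-linear regression of the early
  decay; R_in is the fitted steady deflection over the step amplitude.
- `impedance_profile`: `|Z(f)| = |FFT(V − V̄)/FFT(I − Ī)|`, smoothed by a
  0.5 Hz moving average (the bin-by-bin FFT quotient is noisy; the width
  is configurable); a resonance is an interior maximum exceeding the
  low-frequency end.
- `error_stats`: mean/SD/max of |measured − reference| plus a histogram;
  the reference series comes from a high-order integrator run on the same
  recorded voltages.
- `vm_stats`: mean/SD/histogram of V_m with samples within ±2 ms of an
  upward threshold crossing removed (the clipping window is a choice; real
  spike widths vary).

## Synthetic experiments: scope and limits

The fixture generator emulates the *measurable consequences* of a physical
rig — component tolerance as slope perturbation, measurement noise as
additive Gaussians, figure-style experiments as ready-made configs
(step-family + shunt, HCN chirp, sodium voltage step, EPSC trains at
10–50 Hz, OU background with gE0 = gI0 = 4 nS).  It does not emulate
amplifier-specific artifacts (pipette transients, bridge imbalance),
op-amp dynamics, thermal drift, or real neurons; passing tests therefore
certify the numerics and the loop logic, not biological fidelity or
hardware throughput.  Wall-clock speed claims of any physical controller
are out of scope: timing is *emulated* (sampled cycle durations), never
benchmarked.

Because the published HCN/Na kinetic curves exist only as firmware code
and plots, the defaults here are shape-faithful, not digit-faithful;
quantitative waveform agreement with any particular hardware figure is
deliberately not asserted.  The acceptance checks instead pin quantities
that are arithmetic consequences of printed values (quantization step,
input-chain resolution, parallel-conductance input resistance, OU
stationary statistics) and structural signatures (resonance appears with
HCN, EPSC summation at 50 Hz, Euler instability past 2τ).

## Problem sizes

The default test and reproduction runs use desk-scale sizes chosen to make
stochastic estimates stable: OU statistics from 10⁶ exact-update steps;
impedance from a 15 s chirp at 50 µs cycles; the background
input-resistance ratio from 8 (tests) or 48 (reproduction script) probe
sweeps of 500 ms each at 10 µs cycles.  The expected ratio at 4 + 4 nS
mean background on the 507.7 MΩ cell is `R_m·(1/R_m + 8 nS) = 5.06`; the
probe-step estimator carries a few-percent standard error dominated by the
slow (τ_I = 10.5 ms) inhibitory fluctuations, which is why the sweeps are
averaged.

## Known limitations

- The plant is passive; spiking (active) plants are out of scope, so
  closed-loop behavior with regenerative currents is only exercised up to
  the sodium conductance riding on the RC cell.
- The ADC read is a single sample (no firmware-style multi-sample
  averaging), and latency is quantized to whole cycles.
- Euler instability thresholds depend on the chosen kinetics; with the
  default q = 3 sodium rates the stability boundary on the −70 → 0 mV
  step protocol sits near dt ≈ 2·τ_m(0 mV) ≈ 160 µs.
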