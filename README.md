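# dynclamp

A fully software **dynamic-clamp rig**: a passive model cell coupled in
closed loop to an emulated real-time conductance-injection controller.

Dynamic clamp is the electrophysiology configuration in which a computer
reads a neuron's membrane potential `V_m` in real time and injects the
current a *simulated* ion channel would have passed,

```
I = −g_eff · (V_m − E_rev)
```

where `g_eff` is the instantaneous conductance (nS) and `E_rev` its
reversal potential (mV).  Microcontroller-based implementations make this
cheap, but they bring real-time constraints: 12-bit ADC/DAC quantization,
linear interface circuits that must be calibrated, ~10 µs loop cycles with
microsecond jitter, one-cycle latency, and forward-Euler integration of the
gating equations.  `dynclamp` reproduces that whole loop in software so its
numerical consequences can be studied, bounded and regression-tested
against exact analytic oracles — useful for anyone designing, teaching or
validating a dynamic-clamp setup.

## What is modeled

- **Model cell** — single-compartment RC circuit (default 507.7 MΩ,
  35.9 pF, rest −70 mV), advanced between controller cycles with the exact
  exponential update; internal units are mV / pA / nS / ms / pF.
- **Conductances** — constant shunt; single-gate HCN
  (hyperpolarization-activated, `ds/dt = −(s − s_inf(V))/τ_s(V)`); transient
  sodium `g_Na·m³h·(V − E_Na)` with fast activation (min τ_m < 0.5 ms);
  two-stage kinetic EPSC (`dx/dt = −x/τ_x + Σδ(t−t_i)`,
  `ds/dt = −s/τ_s + α_s·x·(1−s)`); and an excitatory/inhibitory
  Ornstein–Uhlenbeck pair (point-conductance synaptic background,
  stationary variance `σ² = D·τ/2`).  A potassium M-type conductance is a
  pure configuration of the generic gate machinery.
- **The loop** — per cycle: jittered cycle time, quantized calibrated read
  of `V_m`, Euler update of every conductance with the measured elapsed
  time, quantized DAC write of `I_DC`, summing with the command current
  (`I_AMP = I_CC + I_DC`), applied after a whole number of latency cycles.
- **Calibration** — the ideal linear circuit maps between amplifier (±9 V)
  and controller (0–3.3 V) domains, OLS fitting of measured voltage pairs,
  and model-cell-based recovery of both maps.
- **Analysis** — input resistance / time constant by exponential step fits,
  impedance profiles (FFT ratio) with resonance detection,
  measured-vs-reference error statistics, spike-clipped V_m statistics.
- **Oracles** — exact gate/OU/membrane updates and an RK4 coupled-ODE
  reference the closed loop provably converges to.

## Worked example

Add a 5 nS shunt to the model cell and measure the input resistance from a
−50 pA step, exactly as one would on a physical rig:

```python
import dynclamp as dc
from dynclamp.analysis import StepDescriptor, fit_rin_tau

cell = dc.MembraneParams(R_m=507.7, C_m=35.9, E_rest=-70.0)
shunt = dc.shunt_conductance(5.0, E_rev=-70.0)
protocol = dc.step_protocol(-50.0, onset_ms=100, duration_ms=300, tail_ms=50)

step = StepDescriptor(t_on=100, t_off=400, amplitude_pA=-50.0)
for label, conds in [("control", []), ("+5 nS shunt", [shunt])]:
    trace = dc.run_closed_loop(cell, conds, protocol, seed=1)
    r_in, tau = fit_rin_tau(trace, step)
    print(f"{label:12s} R_in = {r_in:6.1f} MOhm   tau = {tau:5.2f} ms")
```

prints

```
control      R_in =  507.7 MOhm   tau = 18.23 ms
+5 nS shunt  R_in =  144.0 MOhm   tau =  5.17 ms
```

The shunt acts purely as an added leak: the fitted input resistance drops
to the parallel value `1/(1/507.7 MΩ + 5 nS) = 143.5 MΩ` (the 0.3%
difference is the quantized read of `V_m`), and the time constant scales
down with it.  The trace also records `Vm_read_mV`, `I_CC_pA`, `I_DC_pA`,
`I_AMP_pA`, per-cycle `dt_cycle_us` and each conductance, so every rig
artifact is inspectable.

A command-line interface wraps the same machinery:

```sh
dynclamp simulate --config run.json --out trace.csv
dynclamp voltage-step --method euler --dt-us 12 --jitter-us 2 --out na.csv
dynclamp calibrate --pairs pairs.csv --out fit.json
dynclamp analyze rin --trace trace.csv --step-on 100 --step-off 400 \
    --amplitude -50 --out rin.json
dynclamp fixtures fig8_ou --out fixtures/ --seed 3
```

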