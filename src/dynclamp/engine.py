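"""The closed loop: quantized read → conductance update → delayed injection.

Each controller cycle emulates what the real-time loop does:

1. sample the cycle duration (Gaussian jitter around the mean);
2. read the membrane through the physical chain — amplifier scaling →
   input circuit → ADC quantization — and invert through the controller's
   *calibration* map to get ``Vm_read``;
3. advance every conductance state by the measured elapsed time using
   ``Vm_read`` (forward Euler for gates, exact update for the OU pair);
4. sum the conductance currents into ``I_DC`` and push it through the DAC
   (quantized) and output circuit, yielding the current actually injected;
5. form the amplifier command ``I_AMP = I_CC + I_DC`` (summing stage),
   which takes effect ``latency_cycles`` later;
6. advance the plant exactly over the cycle under the applied current.

The physical circuits and the controller's belief about them are separate
``CalibrationMap`` objects (``physical`` vs ``calib``); with a perfect
calibration they coincide and the only read error is quantization.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationMap
from .cell import MembraneParams, PA_MOHM_TO_MV
from .conductances import (
    ConductanceSpec,
    conductance_current,
    effective_conductance,
    epsc_step,
    step_gates,
)
from .ou import OUPairState, gaussian_stream, pair_current, step_pair
from .stimuli import StimulusProtocol
from .trace import Trace

__all__ = [
    "ClampTiming",
    "QuantizerSpec",
    "quantize",
    "sample_cycle_dt",
    "run_closed_loop",
    "simulate_reference",
]

#: |V_m| beyond which the loop is declared divergent and halted, mV
DIVERGENCE_LIMIT_MV = 500.0


@dataclass(frozen=True)
class ClampTiming:
    """Real-time loop timing contract.

    ``mean_cycle`` and ``jitter_sd`` are in µs; ``latency_cycles`` is the
    whole number of cycles between a membrane-potential read and the
    corresponding command taking effect (default 1, ≈10 µs at ~100 kHz).
    """

    mean_cycle: float = 10.0
    jitter_sd: float = 0.0
    latency_cycles: int = 1

    def __post_init__(self) -> None:
        if not self.mean_cycle > 0:
            raise ValueError("mean_cycle must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if self.latency_cycles < 0 or self.latency_cycles != int(self.latency_cycles):
            raise ValueError("latency_cycles must be a non-negative integer")


@dataclass(frozen=True)
class QuantizerSpec:
    """ADC/DAC converter: bit depth and voltage span (12 bits over 0–3.3 V)."""

    bits: int = 12
    v_min: float = 0.0
    v_max: float = 3.3

    def __post_init__(self) -> None:
        if self.bits < 1:
            raise ValueError("bits must be ≥ 1")
        if not self.v_max > self.v_min:
            raise ValueError("v_max must exceed v_min")

    @property
    def levels(self) -> int:
        return 2**self.bits

    @property
    def step(self) -> float:
        """Voltage increment between adjacent levels, V."""
        return (self.v_max - self.v_min) / self.levels


def quantize(v: float | np.ndarray, spec: QuantizerSpec):
    """Clip to the converter span and round to the nearest of 2^bits levels.

    Levels are spaced ``(v_max − v_min)/2^bits`` apart starting at v_min,
    with the span's top included, so ``|quantize(v) − clip(v)| ≤ step/2``
    for every input.
    """
    v = np.asarray(v, dtype=float)
    code = np.rint((v - spec.v_min) / spec.step)
    code = np.clip(code, 0, spec.levels)
    out = spec.v_min + code * spec.step
    return float(out) if out.ndim == 0 else out


def sample_cycle_dt(timing: ClampTiming, rng: np.random.Generator) -> float:
    """Draw one cycle duration, µs: Gaussian truncated below at mean/2.

    With ``jitter_sd = 0`` returns the mean exactly (no RNG draw), so
    deterministic runs consume no random numbers for timing.
    """
    if timing.jitter_sd == 0:
        return timing.mean_cycle
    dt = timing.mean_cycle + timing.jitter_sd * float(rng.standard_normal())
    return max(dt, timing.mean_cycle / 2.0)


def run_closed_loop(
    cell: MembraneParams,
    conductances: list[ConductanceSpec],
    protocol: StimulusProtocol,
    *,
    duration: float | None = None,
    timing: ClampTiming | None = None,
    adc: QuantizerSpec | None = None,
    dac: QuantizerSpec | None = None,
    calib: CalibrationMap | None = None,
    physical: CalibrationMap | None = None,
    seed: int = 0,
    V0: float | None = None,
    gate_method: str = "euler",
) -> Trace:
    """Run the full closed loop and record everything.

    Parameters
    ----------
    cell : MembraneParams
        The passive plant.
    conductances : list of ConductanceSpec
        Simulated conductances (may be empty → pure current clamp through
        the rig's quantizers).
    protocol : StimulusProtocol
        Current-clamp command I_CC(t) plus presynaptic spike times.
    duration : float, optional
        Simulated span, ms (defaults to the protocol's).
    timing, adc, dac : optional
        Loop timing and converter specs (defaults: 10 µs cycles, no jitter,
        1-cycle latency; 12 bits over 0–3.3 V).
    calib : CalibrationMap, optional
        The controller's calibration (default: ideal circuit formulas).
    physical : CalibrationMap, optional
        The true circuits (default: same as ``calib``); set differently to
        emulate an imperfect calibration.
    seed : int
        Seeds timing jitter and the OU streams; identical seeds give
        bitwise-identical runs.
    gate_method : str
        Integrator for the gating variables ("euler", the real-time choice,
        or "rk4"/"exact" for idealized controllers).

    Returns
    -------
    Trace
        Channels ``Vm_mV``, ``Vm_read_mV``, ``I_CC_pA``, ``I_DC_pA``,
        ``I_AMP_pA``, ``dt_cycle_us`` and one ``g_<name>_nS`` per
        conductance.  If |V_m| exceeds 500 mV the loop halts, the partial
        trace is returned, and ``metadata["diverged"]`` is set.
    """
    timing = timing or ClampTiming()
    adc = adc or QuantizerSpec()
    dac = dac or QuantizerSpec()
    calib = calib or CalibrationMap.ideal()
    physical = physical or calib
    if duration is None:
        duration = protocol.duration
    if duration <= 0:
        raise ValueError("nothing to simulate: zero duration")

    rng = gaussian_stream(seed)
    n_est = int(duration / (timing.mean_cycle * 1e-3)) + 2

    # split specs into gated / synaptic / stochastic families once
    states: list = []
    for spec in conductances:
        if spec.kind == "ou_pair":
            p = spec.ou_params
            states.append(OUPairState(gE=p.exc.g0, gI=p.inh.g0))
        else:
            states.append(spec.initial_state(V0 if V0 is not None else cell.E_rest))

    V = cell.E_rest if V0 is None else V0
    t = 0.0
    tau = cell.tau
    r_mv = cell.R_m * PA_MOHM_TO_MV
    E = cell.E_rest

    i_cc0 = protocol.current_at(0.0)
    pending: deque[float] = deque([i_cc0] * timing.latency_cycles)

    cols = {
        name: np.empty(n_est)
        for name in ("t", "Vm", "Vm_read", "I_CC", "I_DC", "I_AMP", "dt_us")
    }
    g_cols = {spec.name: np.empty(n_est) for spec in conductances}
    diverged = False

    adc_step = adc.step
    adc_levels = adc.levels
    dac_step = dac.step
    dac_levels = dac.levels

    k = 0
    while t < duration and k < n_est:
        dt_us = sample_cycle_dt(timing, rng)
        dt = dt_us * 1e-3  # measured elapsed time, ms

        # --- read V_m through amplifier → input circuit → ADC → calibration
        v_pin = physical.input_forward(V / physical.amp_mV_per_V)
        code = round((v_pin - adc.v_min) / adc_step)
        code = min(max(code, 0), adc_levels)
        v_q = adc.v_min + code * adc_step
        Vm_read = (v_q - calib.input_intercept) / calib.input_slope * calib.amp_mV_per_V

        # --- advance conductance states with the measured elapsed time
        I_DC_raw = 0.0
        for i, spec in enumerate(conductances):
            if spec.kind == "ou_pair":
                states[i] = step_pair(states[i], dt, spec.ou_params, rng)
                I_DC_raw += pair_current(states[i], spec.ou_params, Vm_read)
                g_cols[spec.name][k] = states[i].gE + states[i].gI
            elif spec.kind == "epsc":
                n_spk = protocol.spikes_in(t, t + dt)
                states[i] = epsc_step(states[i], n_spk, dt, spec)
                I_DC_raw += conductance_current(spec, states[i], Vm_read)
                g_cols[spec.name][k] = effective_conductance(spec, states[i])
            elif spec.kind == "shunt":
                I_DC_raw += conductance_current(spec, states[i], Vm_read)
                g_cols[spec.name][k] = spec.g_max
            else:
                states[i] = step_gates(spec, states[i], Vm_read, dt, gate_method)
                I_DC_raw += conductance_current(spec, states[i], Vm_read)
                g_cols[spec.name][k] = effective_conductance(spec, states[i])

        # --- command the current through DAC + output circuit
        if conductances:
            v_dac = (I_DC_raw / calib.amp_pA_per_V - calib.output_intercept) / calib.output_slope
            code = round((v_dac - dac.v_min) / dac_step)
            code = min(max(code, 0), dac_levels)
            v_dac_q = dac.v_min + code * dac_step
            I_DC = (physical.output_slope * v_dac_q + physical.output_intercept) * physical.amp_pA_per_V
        else:
            I_DC = 0.0

        I_CC = protocol.current_at(t)
        I_AMP = I_CC + I_DC  # summing stage (unit weights, polarity restored)

        pending.append(I_AMP)
        applied = pending.popleft()

        # --- record the cycle, then advance the plant exactly
        cols["t"][k] = t
        cols["Vm"][k] = V
        cols["Vm_read"][k] = Vm_read
        cols["I_CC"][k] = I_CC
        cols["I_DC"][k] = I_DC
        cols["I_AMP"][k] = I_AMP
        cols["dt_us"][k] = dt_us
        k += 1

        v_inf = E + applied * r_mv
        V = v_inf + (V - v_inf) * math.exp(-dt / tau)
        t += dt

        if abs(V) > DIVERGENCE_LIMIT_MV:
            diverged = True
            break

    channels = {
        "Vm_mV": cols["Vm"][:k],
        "Vm_read_mV": cols["Vm_read"][:k],
        "I_CC_pA": cols["I_CC"][:k],
        "I_DC_pA": cols["I_DC"][:k],
        "I_AMP_pA": cols["I_AMP"][:k],
        "dt_cycle_us": cols["dt_us"][:k],
    }
    for name, arr in g_cols.items():
        channels[f"g_{name}_nS"] = arr[:k]
    return Trace(
        t=cols["t"][:k],
        channels=channels,
        metadata={
            "kind": "closed_loop",
            "seed": seed,
            "diverged": diverged,
            "mean_cycle_us": timing.mean_cycle,
            "jitter_sd_us": timing.jitter_sd,
            "latency_cycles": timing.latency_cycles,
            "adc_bits": adc.bits,
            "dac_bits": dac.bits,
            "gate_method": gate_method,
            "units": {"V": "mV", "I": "pA", "g": "nS", "t": "ms"},
        },
    )


def simulate_reference(
    cell: MembraneParams,
    conductances: list[ConductanceSpec],
    protocol: StimulusProtocol,
    *,
    duration: float | None = None,
    dt: float = 0.001,
    V0: float | None = None,
) -> Trace:
    """Idealized coupled simulation: RK4 at a fine fixed step, no rig.

    Integrates membrane + gating variables as one ODE system (no
    quantization, jitter or latency); the oracle the closed loop should
    approach as its cycle time shrinks and its converters sharpen.  Only
    deterministic conductances are supported (no OU pair); EPSC spike
    deltas are applied at the sample boundary containing the spike.
    """
    if duration is None:
        duration = protocol.duration
    if any(s.kind == "ou_pair" for s in conductances):
        raise ValueError("reference simulation is deterministic: no ou_pair")
    n = int(round(duration / dt))
    t_grid = np.arange(n + 1) * dt
    I_cc = protocol.current(t_grid[:-1])

    gate_specs = []  # (cond_index, gate) in state-vector order
    for ci, spec in enumerate(conductances):
        for gate in spec.gates:
            gate_specs.append((ci, gate))
    n_gates = len(gate_specs)
    epsc_idx = [ci for ci, s in enumerate(conductances) if s.kind == "epsc"]

    C = cell.C_m
    E = cell.E_rest

    # state: V, gate vector, and per-epsc (x, s) pairs
    V = cell.E_rest if V0 is None else V0
    gates = np.array(
        [gate.s_inf(V) for _, gate in gate_specs], dtype=float
    )
    xs = {ci: 0.0 for ci in epsc_idx}
    ss = {ci: 0.0 for ci in epsc_idx}

    Vs = np.empty(n + 1)
    Vs[0] = V

    def deriv(V: float, gates: np.ndarray, ss_local: dict[int, float], xs_local: dict[int, float], I_ext: float):
        gi = 0
        dgates = np.empty_like(gates)
        I = I_ext
        for ci, spec in enumerate(conductances):
            if spec.kind == "shunt":
                I += -spec.g_max * (V - spec.E_rev)
            elif spec.kind == "epsc":
                I += -spec.g_max * ss_local[ci] * (V - spec.E_rev)
            else:
                g = spec.g_max
                for gate in spec.gates:
                    s = gates[gi]
                    dgates[gi] = -(s - gate.s_inf(V)) / gate.tau(V)
                    g *= s**gate.exponent
                    gi += 1
                I += -g * (V - spec.E_rev)
        I += cell.g_leak * (E - V)
        dV = I / C
        dss = {
            ci: -ss_local[ci] / conductances[ci].synapse.tau_s
            + conductances[ci].synapse.alpha_s * xs_local[ci] * (1.0 - ss_local[ci])
            for ci in epsc_idx
        }
        dxs = {ci: -xs_local[ci] / conductances[ci].synapse.tau_x for ci in epsc_idx}
        return dV, dgates, dss, dxs

    for k in range(n):
        for ci in epsc_idx:
            xs[ci] += protocol.spikes_in(t_grid[k], t_grid[k + 1])
        I_ext = I_cc[k]

        dV1, dg1, ds1, dx1 = deriv(V, gates, ss, xs, I_ext)
        V2 = V + 0.5 * dt * dV1
        g2 = gates + 0.5 * dt * dg1
        s2 = {ci: ss[ci] + 0.5 * dt * ds1[ci] for ci in epsc_idx}
        x2 = {ci: xs[ci] + 0.5 * dt * dx1[ci] for ci in epsc_idx}
        dV2, dg2, ds2d, dx2d = deriv(V2, g2, s2, x2, I_ext)
        V3 = V + 0.5 * dt * dV2
        g3 = gates + 0.5 * dt * dg2
        s3 = {ci: ss[ci] + 0.5 * dt * ds2d[ci] for ci in epsc_idx}
        x3 = {ci: xs[ci] + 0.5 * dt * dx2d[ci] for ci in epsc_idx}
        dV3, dg3, ds3d, dx3d = deriv(V3, g3, s3, x3, I_ext)
        V4 = V + dt * dV3
        g4 = gates + dt * dg3
        s4 = {ci: ss[ci] + dt * ds3d[ci] for ci in epsc_idx}
        x4 = {ci: xs[ci] + dt * dx3d[ci] for ci in epsc_idx}
        dV4, dg4, ds4d, dx4d = deriv(V4, g4, s4, x4, I_ext)

        V = V + dt * (dV1 + 2 * dV2 + 2 * dV3 + dV4) / 6.0
        gates = gates + dt * (dg1 + 2 * dg2 + 2 * dg3 + dg4) / 6.0
        for ci in epsc_idx:
            ss[ci] += dt * (ds1[ci] + 2 * ds2d[ci] + 2 * ds3d[ci] + ds4d[ci]) / 6.0
            xs[ci] += dt * (dx1[ci] + 2 * dx2d[ci] + 2 * dx3d[ci] + dx4d[ci]) / 6.0
        Vs[k + 1] = V

    return Trace(
        t=t_grid[:-1],
        channels={"Vm_mV": Vs[:-1], "I_pA": I_cc},
        metadata={"kind": "reference_rk4", "dt_ms": dt},
    )
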