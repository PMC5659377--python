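"""Simulated conductances: shunt, HCN, transient sodium, and kinetic EPSC.

Each conductance injects a current ``I = −g_eff·(V_m − E_rev)`` (pA, with
the convention that a positive return value depolarizes the cell), where
the effective conductance is

    shunt : g_max
    hcn   : g_max · s           (one activation gate)
    na    : g_max · m³h         (three activation gates, one inactivation)
    epsc  : g_max · s           (two-stage kinetic synapse)

Voltage-gated gates relax toward a voltage-dependent steady state,
``ds/dt = −(s − s_inf(V))/τ(V)``.  Three steppers are provided: forward
Euler (what a real-time controller runs), classical RK4, and the exact
exponential update (valid for piecewise-constant V), which serves as the
oracle.  Gate values are *not* clamped to [0,1] by default — forward-Euler
instability at large time steps is legitimate, observable output.

The HCN and Na kinetics shipped here are parametric defaults (Boltzmann
steady states, bell-shaped or rate-function time constants) with the right
qualitative shape: HCN activates with hyperpolarization around −82 mV; the
Na activation gate is fast (min τ_m < 0.5 ms, via a 3× temperature factor
on classic squid-axon rates).  Both are fully overridable, parametrically
or as tabulated V/s_inf/τ tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Any, Callable, Literal, Sequence

import numpy as np

__all__ = [
    "GateSpec",
    "ConductanceSpec",
    "ConductanceState",
    "conductance_current",
    "gate_step_euler",
    "gate_step_exact",
    "gate_step_rk4",
    "epsc_step",
    "na_step_response",
    "boltzmann_gate",
    "tabulated_gate",
    "shunt_conductance",
    "hcn_conductance",
    "na_conductance",
    "epsc_conductance",
    "m_type_conductance",
]

Kind = Literal["shunt", "hcn", "na", "epsc", "ou_pair"]

#: supported voltage range for kinetics, mV
V_RANGE = (-120.0, 60.0)


@dataclass(frozen=True)
class GateSpec:
    """One gating variable: steady state s_inf(V), time constant τ(V), exponent.

    ``steady_state`` maps V (mV) to [0, 1]; ``time_constant`` maps V (mV)
    to a strictly positive τ (ms).  ``exponent`` is the power the gate is
    raised to in the conductance product (3 for the sodium m gate).
    """

    steady_state: Callable[[float], float]
    time_constant: Callable[[float], float]
    exponent: int = 1
    name: str = "s"

    def __post_init__(self) -> None:
        if self.exponent < 1:
            raise ValueError("gate exponent must be a positive integer")

    def s_inf(self, V: float) -> float:
        return float(self.steady_state(V))

    def tau(self, V: float) -> float:
        tau = float(self.time_constant(V))
        if not tau > 0:
            raise ValueError(f"gate {self.name}: τ({V} mV) = {tau} must be > 0")
        return tau


def boltzmann_gate(
    V_half: float,
    slope: float,
    tau_fn: Callable[[float], float],
    *,
    exponent: int = 1,
    name: str = "s",
) -> GateSpec:
    """Boltzmann steady state ``1/(1+exp((V−V_half)/slope))``.

    Positive ``slope`` gives a gate activated by hyperpolarization (HCN
    style); negative slope gives a depolarization-activated gate.
    """

    def s_inf(V: float) -> float:
        return 1.0 / (1.0 + math.exp((V - V_half) / slope))

    return GateSpec(s_inf, tau_fn, exponent=exponent, name=name)


def tabulated_gate(
    V_mV: Sequence[float],
    s_inf: Sequence[float],
    tau_ms: Sequence[float],
    *,
    exponent: int = 1,
    name: str = "s",
) -> GateSpec:
    """Gate kinetics from a table (linear interpolation, flat extrapolation)."""
    V = np.asarray(V_mV, dtype=float)
    si = np.asarray(s_inf, dtype=float)
    ta = np.asarray(tau_ms, dtype=float)
    if not (V.size == si.size == ta.size and V.size >= 2):
        raise ValueError("tabulated gate needs ≥2 rows of equal length")
    if np.any(np.diff(V) <= 0):
        raise ValueError("V grid must be strictly increasing")
    if np.any(ta <= 0):
        raise ValueError("tabulated τ must be positive")
    return GateSpec(
        lambda v: float(np.interp(v, V, si)),
        lambda v: float(np.interp(v, V, ta)),
        exponent=exponent,
        name=name,
    )


@dataclass(frozen=True)
class SynapseParams:
    """Two-stage kinetic synapse constants: rise τ_x, decay τ_s, saturation α_s."""

    tau_x: float = 1.0  # ms, rise
    tau_s: float = 10.0  # ms, decay
    alpha_s: float = 1.0  # 1/ms

    def __post_init__(self) -> None:
        if self.tau_x <= 0 or self.tau_s <= 0:
            raise ValueError("synapse time constants must be positive")
        if not self.tau_x < self.tau_s:
            raise ValueError("rise time τ_x must be shorter than decay τ_s")


@dataclass(frozen=True)
class ConductanceSpec:
    """One simulated conductance: kind, maximal conductance, reversal, kinetics."""

    kind: Kind
    g_max: float  # nS
    E_rev: float  # mV
    gates: tuple[GateSpec, ...] = ()
    synapse: SynapseParams | None = None
    ou_params: Any = None  # OUPairParams for kind="ou_pair" (see dynclamp.ou)
    clamp_gates: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")
        if self.kind == "epsc" and self.synapse is None:
            object.__setattr__(self, "synapse", SynapseParams())
        if not self.name:
            object.__setattr__(self, "name", self.kind)

    def initial_state(self, V_hold: float) -> "ConductanceState":
        """State with gates at steady state for the holding potential."""
        return ConductanceState(
            gate_values=tuple(g.s_inf(V_hold) for g in self.gates)
        )


@dataclass(frozen=True)
class ConductanceState:
    """Evolving state of one conductance.

    ``gate_values`` are nominally in [0,1] but may leave it when the Euler
    stepper is unstable and clamping is off; ``synapse_x``/``synapse_s``
    are the two-stage synapse variables.
    """

    gate_values: tuple[float, ...] = ()
    synapse_x: float = 0.0
    synapse_s: float = 0.0


def effective_conductance(spec: ConductanceSpec, state: ConductanceState) -> float:
    """g_eff in nS: g_max times the gate product (or synapse s)."""
    if spec.kind == "shunt":
        return spec.g_max
    if spec.kind == "epsc":
        return spec.g_max * state.synapse_s
    if spec.kind in ("hcn", "na") or spec.gates:
        if len(state.gate_values) != len(spec.gates):
            raise ValueError(
                f"{spec.name}: state has {len(state.gate_values)} gates, "
                f"spec has {len(spec.gates)}"
            )
        g = spec.g_max
        for gate, s in zip(spec.gates, state.gate_values):
            g *= s**gate.exponent
        return g
    raise ValueError(f"cannot evaluate conductance of kind {spec.kind!r}")


def conductance_current(
    spec: ConductanceSpec, state: ConductanceState, V_m: float
) -> float:
    """Injected current I = −g_eff·(V_m − E_rev), pA (positive depolarizes)."""
    return -effective_conductance(spec, state) * (V_m - spec.E_rev)


# ---------------------------------------------------------------------------
# Gate steppers


def gate_step_euler(
    s: float, V: float, dt: float, gate: GateSpec, *, clamp: bool = False
) -> float:
    """One forward-Euler step of ds/dt = −(s − s_inf(V))/τ(V).

    No clamping unless requested: divergence at dt > 2τ is legitimate
    output (it is how real-time Euler instability manifests).
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    s1 = s - dt * (s - gate.s_inf(V)) / gate.tau(V)
    if clamp:
        s1 = min(1.0, max(0.0, s1))
    return s1


def gate_step_exact(s: float, V: float, dt: float, gate: GateSpec) -> float:
    """Exact relaxation over dt at constant V (composable: semigroup in dt)."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    s_inf = gate.s_inf(V)
    return s_inf + (s - s_inf) * math.exp(-dt / gate.tau(V))


def gate_step_rk4(s: float, V: float, dt: float, gate: GateSpec) -> float:
    """Classical fourth-order Runge–Kutta step (V held constant over dt)."""
    if not dt > 0:
        raise ValueError("dt must be positive")
    s_inf, tau = gate.s_inf(V), gate.tau(V)

    def f(y: float) -> float:
        return -(y - s_inf) / tau

    k1 = f(s)
    k2 = f(s + 0.5 * dt * k1)
    k3 = f(s + 0.5 * dt * k2)
    k4 = f(s + dt * k3)
    return s + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0


def step_gates(
    spec: ConductanceSpec,
    state: ConductanceState,
    V: float,
    dt: float,
    method: str = "euler",
) -> ConductanceState:
    """Advance every gate of a voltage-gated conductance by dt."""
    steppers = {
        "euler": lambda s, g: gate_step_euler(s, V, dt, g, clamp=spec.clamp_gates),
        "exact": lambda s, g: gate_step_exact(s, V, dt, g),
        "rk4": lambda s, g: gate_step_rk4(s, V, dt, g),
    }
    if method not in steppers:
        raise ValueError(f"unknown method {method!r}; use euler, rk4 or exact")
    step = steppers[method]
    return replace(
        state,
        gate_values=tuple(step(s, g) for s, g in zip(state.gate_values, spec.gates)),
    )


# ---------------------------------------------------------------------------
# Two-stage kinetic synapse


def epsc_step(
    state: ConductanceState,
    n_spikes_in_window: int,
    dt: float,
    spec: ConductanceSpec,
) -> ConductanceState:
    """Advance the two-stage synapse by dt, delivering any spikes first.

    ``dx/dt = −x/τ_x + Σ δ(t − t_i)``: each presynaptic spike whose time
    falls in the current window increments x by exactly 1 (simultaneous
    spikes sum).  ``ds/dt = −s/τ_s + α_s·x·(1 − s)`` keeps s ≤ 1 for
    s₀ ≤ 1 (ds/dt < 0 at s = 1).  Forward Euler, matching the real-time
    controller.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if n_spikes_in_window < 0:
        raise ValueError("spike count must be non-negative")
    syn = spec.synapse or SynapseParams()
    x = state.synapse_x + n_spikes_in_window
    s = state.synapse_s
    s1 = s + dt * (-s / syn.tau_s + syn.alpha_s * x * (1.0 - s))
    x1 = x * (1.0 - dt / syn.tau_x)
    return replace(state, synapse_x=x1, synapse_s=s1)


# ---------------------------------------------------------------------------
# Default conductance constructors


def shunt_conductance(g_nS: float, E_rev: float = -70.0) -> ConductanceSpec:
    """Constant (leak-like) conductance."""
    return ConductanceSpec(kind="shunt", g_max=g_nS, E_rev=E_rev, name="shunt")


def _hcn_tau(tau_peak: float = 50.0, tau_min: float = 1.0,
             V_peak: float = -82.0, width: float = 14.0) -> Callable[[float], float]:
    def tau(V: float) -> float:
        return tau_min + tau_peak / math.cosh((V - V_peak) / width)

    return tau


def hcn_conductance(
    g_nS: float,
    *,
    E_rev: float = -30.0,
    V_half: float = -82.0,
    slope: float = 9.0,
    tau_fn: Callable[[float], float] | None = None,
    gate: GateSpec | None = None,
) -> ConductanceSpec:
    """Hyperpolarization-activated (HCN) conductance with one activation gate.

    Defaults: Boltzmann steady state with half-activation −82 mV and 9 mV
    slope (activation grows with hyperpolarization), bell-shaped τ peaking
    at ~50 ms near V_half, reversal −30 mV (near the base of the
    activation curve, the configuration that yields sag and resonance).
    """
    if gate is None:
        gate = boltzmann_gate(V_half, slope, tau_fn or _hcn_tau(), name="s")
    return ConductanceSpec(kind="hcn", g_max=g_nS, E_rev=E_rev, gates=(gate,), name="hcn")


def _hh_rate_gate(
    alpha: Callable[[float], float],
    beta: Callable[[float], float],
    q: float,
    exponent: int,
    name: str,
) -> GateSpec:
    def s_inf(V: float) -> float:
        a, b = alpha(V), beta(V)
        return a / (a + b)

    def tau(V: float) -> float:
        return 1.0 / (q * (alpha(V) + beta(V)))

    return GateSpec(s_inf, tau, exponent=exponent, name=name)


def _vtrap(x: float, y: float) -> float:
    # x/(exp(x/y) − 1) with the removable singularity at x = 0 filled in
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / (2.0 * y))
    return x / (math.expm1(x / y))


def na_conductance(
    g_nS: float,
    *,
    E_rev: float = 50.0,
    V_shift: float = 0.0,
    q: float = 3.0,
    gates: tuple[GateSpec, GateSpec] | None = None,
) -> ConductanceSpec:
    """Transient sodium conductance, m³h, with classic rate-function kinetics.

    The rates are the classical squid-axon forms (expressed at a −65 mV
    resting convention) with an optional voltage shift and a temperature
    factor ``q`` (default 3) accelerating both gates so that the activation
    time constant satisfies min τ_m < 0.5 ms — fast kinetics are what make
    sodium the most demanding conductance for a real-time integrator.
    """
    if gates is None:

        def am(V: float) -> float:
            return 0.1 * _vtrap(-(V - V_shift + 40.0), 10.0)

        def bm(V: float) -> float:
            return 4.0 * math.exp(-(V - V_shift + 65.0) / 18.0)

        def ah(V: float) -> float:
            return 0.07 * math.exp(-(V - V_shift + 65.0) / 20.0)

        def bh(V: float) -> float:
            return 1.0 / (1.0 + math.exp(-(V - V_shift + 35.0) / 10.0))

        gates = (
            _hh_rate_gate(am, bm, q, exponent=3, name="m"),
            _hh_rate_gate(ah, bh, q, exponent=1, name="h"),
        )
    return ConductanceSpec(kind="na", g_max=g_nS, E_rev=E_rev, gates=gates, name="na")


def epsc_conductance(
    g_nS: float,
    *,
    E_rev: float = 0.0,
    tau_x: float = 1.0,
    tau_s: float = 10.0,
    alpha_s: float = 1.0,
) -> ConductanceSpec:
    """AMPA-like synaptic conductance (two-stage kinetic scheme).

    Defaults E_rev = 0 mV, τ_s = 10 ms, τ_x = 1 ms, α_s = 1/ms.
    """
    return ConductanceSpec(
        kind="epsc",
        g_max=g_nS,
        E_rev=E_rev,
        synapse=SynapseParams(tau_x=tau_x, tau_s=tau_s, alpha_s=alpha_s),
        name="epsc",
    )


def m_type_conductance(
    g_nS: float,
    *,
    E_rev: float = -90.0,
    V_half: float = -35.0,
    slope: float = -9.0,
    tau_ms: float = 50.0,
) -> ConductanceSpec:
    """Slow, non-inactivating potassium (M-type) conductance.

    Purely a configuration of the generic single-gate machinery: one
    depolarization-activated Boltzmann gate with a potassium reversal.
    """
    gate = boltzmann_gate(V_half, slope, lambda V: tau_ms, name="s")
    spec = ConductanceSpec(kind="hcn", g_max=g_nS, E_rev=E_rev, gates=(gate,), name="m_type")
    return spec


# ---------------------------------------------------------------------------
# Voltage-step experiment (integrator comparison)


def na_step_response(
    *,
    method: str,
    dt: float,
    spec: ConductanceSpec | None = None,
    V_hold: float = -70.0,
    V_step: float = 0.0,
    t_step: float = 20.0,
    duration: float = 50.0,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Sodium current under an instantaneous voltage-clamp step.

    The command potential is held at ``V_hold``, stepped instantaneously to
    ``V_step`` at ``t_step`` (ms), and the gating equations are integrated
    with the chosen ``method`` ("euler", "rk4" or "exact") at nominal time
    step ``dt`` (ms), optionally jittered per step by a Gaussian of SD
    ``jitter_sd`` (ms) truncated at dt/2 — emulating a controller whose
    cycle time fluctuates.  Gates start at steady state for ``V_hold``.

    Returns
    -------
    Trace
        Channels ``V_mV`` (imposed), ``I_pA`` and one ``<gate>`` channel
        per gating variable.
    """
    from .trace import Trace

    if spec is None:
        spec = na_conductance(20.0)
    if method not in ("euler", "rk4", "exact"):
        raise ValueError(f"unknown method {method!r}; use euler, rk4 or exact")
    if not dt > 0:
        raise ValueError("dt must be positive")
    if jitter_sd > 0 and rng is None:
        rng = np.random.default_rng(0)

    state = spec.initial_state(V_hold)
    t = 0.0
    ts = [t]
    Vs = [V_hold]
    Is = [conductance_current(spec, state, V_hold)]
    gate_hist = [list(state.gate_values)]
    while t < duration:
        h = dt
        if jitter_sd > 0:
            h = max(dt / 2.0, dt + jitter_sd * float(rng.standard_normal()))
        V = V_hold if t < t_step else V_step
        state = step_gates(spec, state, V, h, method)
        t += h
        V_now = V_hold if t < t_step else V_step
        ts.append(t)
        Vs.append(V_now)
        Is.append(conductance_current(spec, state, V_now))
        gate_hist.append(list(state.gate_values))

    channels = {"V_mV": np.array(Vs), "I_pA": np.array(Is)}
    for i, gate in enumerate(spec.gates):
        channels[gate.name] = np.array([g[i] for g in gate_hist])
    return Trace(
        t=np.array(ts),
        channels=channels,
        metadata={
            "kind": "voltage_step",
            "method": method,
            "dt_ms": dt,
            "jitter_sd_ms": jitter_sd,
            "V_hold_mV": V_hold,
            "V_step_mV": V_step,
            "t_step_ms": t_step,
        },
    )
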