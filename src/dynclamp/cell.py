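"""Passive model cell: the RC "neuron" that the virtual rig injects current into.

The plant is a single-compartment RC circuit (optionally with a series
resistor and stray capacitance, as in commercial patch-clamp model cells).
Internal unit system, used throughout the package:

    voltage      mV
    current      pA
    conductance  nS
    resistance   MΩ
    capacitance  pF
    time         ms

These are mutually consistent up to powers of ten fixed here once:
``I[pA] = g[nS] · V[mV]``, ``ΔV[mV] = 1e-3 · I[pA] · R[MΩ]`` and
``τ[ms] = 1e-3 · R[MΩ] · C[pF]``.

Between controller updates the membrane is advanced with the *exact*
exponential solution of the linear ODE (the physical cell is not subject to
the controller's Euler approximation), which also makes this module the
analytic oracle for the integrator tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .stimuli import StimulusProtocol
from .trace import Trace

__all__ = [
    "MembraneParams",
    "MembraneState",
    "membrane_update",
    "simulate_open_loop",
]

#: mV per (pA · MΩ)
PA_MOHM_TO_MV = 1e-3
#: ms per (MΩ · pF)
MOHM_PF_TO_MS = 1e-3


@dataclass(frozen=True)
class MembraneParams:
    """Passive membrane parameters of the model cell.

    Parameters
    ----------
    R_m : float
        Membrane (input) resistance, MΩ.
    C_m : float
        Membrane capacitance, pF.
    E_rest : float
        Resting / leak reversal potential, mV.
    R_series : float, optional
        Electrode series resistance, MΩ.  Default 0 (bridge-balanced).
    C_stray : float, optional
        Stray (pipette) capacitance, pF.  Default 0 (compensated).
    """

    R_m: float
    C_m: float
    E_rest: float = -70.0
    R_series: float = 0.0
    C_stray: float = 0.0

    def __post_init__(self) -> None:
        if not (self.R_m > 0 and self.C_m > 0):
            raise ValueError("R_m and C_m must be positive")
        if self.R_series < 0 or self.C_stray < 0:
            raise ValueError("R_series and C_stray must be non-negative")
        for name in ("R_m", "C_m", "E_rest", "R_series", "C_stray"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def tau(self) -> float:
        """Membrane time constant R_m·C_m, ms (derived, never stored)."""
        return self.R_m * self.C_m * MOHM_PF_TO_MS

    @property
    def g_leak(self) -> float:
        """Leak conductance 1/R_m, nS."""
        return 1e3 / self.R_m


@dataclass(frozen=True)
class MembraneState:
    """Instantaneous state of the membrane: potential (mV) and time (ms)."""

    V_m: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.V_m) and math.isfinite(self.t)):
            raise ValueError("V_m and t must be finite")


def steady_state_voltage(params: MembraneParams, I: float) -> float:
    """Steady-state potential under constant current I (pA): E_rest + I·R_m."""
    return params.E_rest + I * params.R_m * PA_MOHM_TO_MV


def membrane_update(
    state: MembraneState,
    I_total: float,
    dt: float,
    params: MembraneParams,
) -> MembraneState:
    """Advance the membrane by ``dt`` under constant total current.

    Uses the exact solution of ``C·dV/dt = (E_rest − V)/R + I`` over the
    interval: ``V' = V_∞ + (V − V_∞)·exp(−dt/τ)`` with
    ``V_∞ = E_rest + I·R_m``.  Exact for piecewise-constant current, which
    is precisely how the clamp engine drives the plant.

    When ``C_stray > 0`` and ``R_series > 0`` the cell is a two-compartment
    linear circuit (pipette node + membrane node); the update then uses the
    exact matrix exponential of the 2×2 linear system, and ``V_m`` tracks
    the membrane node.

    Parameters
    ----------
    state : MembraneState
    I_total : float
        Total injected current (command + dynamic clamp), pA, held constant.
    dt : float
        Interval, ms; must be positive.
    params : MembraneParams
    """
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if not math.isfinite(I_total):
        raise ValueError("I_total must be finite")

    if params.C_stray > 0 and params.R_series > 0:
        V = _two_compartment_update(state.V_m, I_total, dt, params)
        return MembraneState(V_m=V, t=state.t + dt)

    v_inf = steady_state_voltage(params, I_total)
    V = v_inf + (state.V_m - v_inf) * math.exp(-dt / params.tau)
    return MembraneState(V_m=V, t=state.t + dt)


def _two_compartment_update(
    V_m: float, I: float, dt: float, p: MembraneParams
) -> float:
    # Pipette node V_p (across C_stray) connects to the membrane node V_m
    # through R_series; current enters at the pipette node.  The pipette
    # node is assumed equilibrated with the membrane at call time (the
    # stray time constant R_series·C_stray is ≪ dt at clamp rates), so we
    # integrate the 2x2 system from [V_p*, V_m] exactly via expm.
    from scipy.linalg import expm

    g_s = 1e3 / p.R_series  # nS
    g_l = p.g_leak
    # x = [V_p, V_m]; C_stray dV_p/dt = I − g_s (V_p − V_m)
    #                 C_m    dV_m/dt = g_s (V_p − V_m) − g_l (V_m − E)
    A = np.array(
        [
            [-g_s / p.C_stray, g_s / p.C_stray],
            [g_s / p.C_m, -(g_s + g_l) / p.C_m],
        ]
    )
    b = np.array([I / p.C_stray, g_l * p.E_rest / p.C_m])
    x0 = np.array([V_m + I * p.R_series * PA_MOHM_TO_MV, V_m])
    x_inf = -np.linalg.solve(A, b)
    x = x_inf + expm(A * dt) @ (x0 - x_inf)
    return float(x[1])


def simulate_open_loop(
    params: MembraneParams,
    protocol: StimulusProtocol,
    dt: float,
    *,
    duration: float | None = None,
    V0: float | None = None,
) -> Trace:
    """Pure current-clamp simulation of the model cell (no dynamic clamp).

    The stimulus is sampled at the start of each interval and held constant
    over it (zero-order hold), matching how a DAQ board delivers a command
    waveform; the membrane is advanced exactly over each interval.

    Parameters
    ----------
    params : MembraneParams
    protocol : StimulusProtocol
        Current-clamp command waveform, I(t) in pA.
    dt : float
        Sample interval, ms.
    duration : float, optional
        Total simulated time, ms; defaults to the protocol's span.
    V0 : float, optional
        Initial potential, mV; defaults to the resting potential.

    Returns
    -------
    Trace
        Channels ``Vm_mV`` and ``I_pA`` on a uniform time base.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if duration is None:
        duration = protocol.duration
    if duration <= 0:
        raise ValueError("protocol is empty: nothing to simulate")

    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    I = protocol.current(t[:-1])
    V = np.empty(n + 1)
    V[0] = params.E_rest if V0 is None else V0

    decay = math.exp(-dt / params.tau)
    r = params.R_m * PA_MOHM_TO_MV
    E = params.E_rest
    for k in range(n):
        v_inf = E + I[k] * r
        V[k + 1] = v_inf + (V[k] - v_inf) * decay

    return Trace(
        t=t[:-1],
        channels={"Vm_mV": V[:-1], "I_pA": I},
        metadata={
            "kind": "open_loop",
            "dt_ms": dt,
            "R_m_MOhm": params.R_m,
            "C_m_pF": params.C_m,
            "E_rest_mV": params.E_rest,
        },
    )
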