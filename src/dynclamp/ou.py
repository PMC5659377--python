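"""Ornstein–Uhlenbeck synaptic background: the point-conductance model.

In vivo–like synaptic bombardment is modeled as two stochastic conductance
trains — one excitatory, one inhibitory — each following the mean-reverting
SDE

    dg/dt = −(g − g0)/τ + sqrt(D)·χ(t),

with g0 the mean conductance (nS), τ the correlation time (ms), D the
diffusion constant (nS²/ms) and χ(t) unit-variance Gaussian white noise.
The stationary distribution is Gaussian with variance σ² = D·τ/2.

Note on the noise amplitude: writing the noise term as D·χ(t) (as some
descriptions do) is dimensionally inconsistent with σ² = D·τ/2 and with D
quoted in nS²/ms; the sqrt(D) convention used here is the one under which
both hold, and the one the package implements throughout.

Two steppers are provided: the *exact* update (preserves the stationary
law at any dt) and an Euler–Maruyama variant for cross-checks.  Negative
conductance excursions are allowed by default (faithful to the SDE); an
optional rectify flag clips at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "OUParams",
    "OUPairParams",
    "OUPairState",
    "gaussian_stream",
    "ou_step",
    "ou_step_euler",
    "simulate_ou",
]


@dataclass(frozen=True)
class OUParams:
    """One OU conductance train.

    Parameters
    ----------
    g0 : float
        Mean conductance, nS.
    tau : float
        Correlation time, ms.
    D : float
        Diffusion constant, nS²/ms.
    E_rev : float
        Reversal potential, mV.
    """

    g0: float
    tau: float
    D: float
    E_rev: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.D < 0:
            raise ValueError("D must be non-negative")

    @property
    def stationary_sd(self) -> float:
        """Stationary standard deviation sqrt(D·τ/2), nS (derived)."""
        return math.sqrt(self.D * self.tau / 2.0)

    @classmethod
    def from_sd(cls, g0: float, tau: float, sd: float, E_rev: float) -> "OUParams":
        """Construct from the stationary SD instead of D (σ² = Dτ/2 ⇒ D = 2σ²/τ)."""
        return cls(g0=g0, tau=tau, D=2.0 * sd * sd / tau, E_rev=E_rev)


#: Correlation times and reversals commonly used for the point-conductance
#: background (excitatory/inhibitory); configurable everywhere they appear.
DEFAULT_TAU_E = 2.7  # ms
DEFAULT_TAU_I = 10.5  # ms
DEFAULT_E_E = 0.0  # mV
DEFAULT_E_I = -75.0  # mV


@dataclass(frozen=True)
class OUPairParams:
    """Excitatory + inhibitory OU pair (the full point-conductance model)."""

    exc: OUParams
    inh: OUParams
    rectify: bool = False

    @classmethod
    def from_config(
        cls,
        *,
        gE0: float,
        gI0: float,
        DE: float | None = None,
        DI: float | None = None,
        sE: float | None = None,
        sI: float | None = None,
        tauE: float = DEFAULT_TAU_E,
        tauI: float = DEFAULT_TAU_I,
        EE: float = DEFAULT_E_E,
        EI: float = DEFAULT_E_I,
        rectify: bool = False,
    ) -> "OUPairParams":
        """Accepts either diffusion constants (DE, DI) or stationary SDs (sE, sI)."""
        if (DE is None) == (sE is None):
            raise ValueError("give exactly one of DE or sE")
        if (DI is None) == (sI is None):
            raise ValueError("give exactly one of DI or sI")
        exc = (
            OUParams(gE0, tauE, DE, EE)
            if DE is not None
            else OUParams.from_sd(gE0, tauE, sE, EE)
        )
        inh = (
            OUParams(gI0, tauI, DI, EI)
            if DI is not None
            else OUParams.from_sd(gI0, tauI, sI, EI)
        )
        return cls(exc=exc, inh=inh, rectify=rectify)


@dataclass(frozen=True)
class OUPairState:
    """Instantaneous conductances of the pair, nS (may be transiently negative)."""

    gE: float
    gI: float


def gaussian_stream(seed: int) -> np.random.Generator:
    """Deterministic, seed-reproducible source of unit normals.

    Returns a numpy Generator (PCG64); draw with ``rng.standard_normal()``.
    Identical seeds give bitwise-identical streams.
    """
    return np.random.default_rng(seed)


def ou_step(
    g: float, dt: float, params: OUParams, rng: np.random.Generator
) -> float:
    """Exact (stationary-preserving) OU update over dt.

    ``g' = g0 + (g − g0)·e^{−dt/τ} + sqrt((Dτ/2)·(1 − e^{−2dt/τ}))·N(0,1)``.
    Exact in distribution for any dt, so large controller cycle times do
    not bias the stationary statistics.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    a = math.exp(-dt / params.tau)
    sd = math.sqrt(params.D * params.tau / 2.0 * (1.0 - a * a))
    return params.g0 + (g - params.g0) * a + sd * float(rng.standard_normal())


def ou_step_euler(
    g: float, dt: float, params: OUParams, rng: np.random.Generator
) -> float:
    """Euler–Maruyama OU update: g' = g − (g−g0)·dt/τ + sqrt(D·dt)·N(0,1)."""
    if not dt > 0:
        raise ValueError("dt must be positive")
    return (
        g
        - (g - params.g0) * dt / params.tau
        + math.sqrt(params.D * dt) * float(rng.standard_normal())
    )


def step_pair(
    state: OUPairState,
    dt: float,
    params: OUPairParams,
    rng: np.random.Generator,
    *,
    method: str = "exact",
) -> OUPairState:
    """Advance both trains by dt (excitatory drawn first, then inhibitory)."""
    step = ou_step if method == "exact" else ou_step_euler
    gE = step(state.gE, dt, params.exc, rng)
    gI = step(state.gI, dt, params.inh, rng)
    if params.rectify:
        gE, gI = max(0.0, gE), max(0.0, gI)
    return OUPairState(gE=gE, gI=gI)


def pair_current(state: OUPairState, params: OUPairParams, V_m: float) -> float:
    """Total injected background current, pA (positive depolarizes)."""
    return -state.gE * (V_m - params.exc.E_rev) - state.gI * (V_m - params.inh.E_rev)


def simulate_ou(
    params: OUParams,
    n_steps: int,
    dt: float,
    seed: int,
    *,
    method: str = "exact",
    g0: float | None = None,
) -> np.ndarray:
    """Vectorized single-train OU trajectory of length ``n_steps + 1``.

    Uses the same update as :func:`ou_step` (or Euler–Maruyama), applied
    recursively via scipy's linear filter for speed; starts at the mean
    unless ``g0`` is given.
    """
    from scipy.signal import lfilter

    rng = gaussian_stream(seed)
    z = rng.standard_normal(n_steps)
    if method == "exact":
        a = math.exp(-dt / params.tau)
        sd = math.sqrt(params.D * params.tau / 2.0 * (1.0 - a * a))
    elif method == "euler":
        a = 1.0 - dt / params.tau
        sd = math.sqrt(params.D * dt)
    else:
        raise ValueError(f"unknown method {method!r}")
    x0 = (g0 - params.g0) if g0 is not None else 0.0
    # x[k+1] = a·x[k] + sd·z[k]  ⇒  IIR filter with initial condition x0
    x, _ = lfilter([sd], [1.0, -a], z, zi=np.array([a * x0]))
    return params.g0 + np.concatenate(([x0], x))
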