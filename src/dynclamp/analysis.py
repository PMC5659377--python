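"""Response analysis: input resistance/time constant, impedance, error stats.

These reproduce the standard desk analyses of a dynamic-clamp experiment:

- fit a single exponential to a current-step response to estimate input
  resistance R_in (steady deflection / step amplitude) and time constant τ;
- divide the Fourier transforms of voltage and current under a broadband
  (chirp) drive to get the impedance magnitude |Z(f)| and locate any
  resonance (interior maximum exceeding the low-frequency value);
- summarize measured-vs-reference current differences (the "error"
  histograms of closed-loop validation);
- subthreshold membrane-potential statistics with optional spike clipping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .trace import Trace

__all__ = [
    "StepDescriptor",
    "ErrorStats",
    "ImpedanceProfile",
    "fit_rin_tau",
    "impedance_profile",
    "error_stats",
    "vm_stats",
    "VmStats",
]


@dataclass(frozen=True)
class StepDescriptor:
    """Where the current step sits in a trace: onset/offset (ms), amplitude (pA)."""

    t_on: float
    t_off: float
    amplitude_pA: float

    def __post_init__(self) -> None:
        if not self.t_off > self.t_on:
            raise ValueError("t_off must exceed t_on")
        if self.amplitude_pA == 0:
            raise ValueError("step amplitude must be nonzero")


def fit_rin_tau(
    trace: Trace, step: StepDescriptor, *, vm_channel: str = "Vm_mV"
) -> tuple[float, float]:
    """Input resistance (MΩ) and time constant (ms) from a step response.

    Fits ``V(t) = V_ss + (V_0 − V_ss)·exp(−(t − t_on)/τ)`` to the window
    from step onset to step end by nonlinear least squares, initialized
    from a log-linear regression.  ``R_in`` is the steady deflection
    (fitted ``V_ss`` minus the pre-step baseline mean) divided by the step
    amplitude.  The trace must cover ≥3τ of the response for the fit to be
    meaningful; at least a handful of samples are required.
    """
    t = trace.t
    V = trace[vm_channel]
    on_mask = (t >= step.t_on) & (t < step.t_off)
    base_mask = t < step.t_on
    if on_mask.sum() < 5:
        raise ValueError("step window contains too few samples")
    if base_mask.sum() < 1:
        raise ValueError("no pre-step baseline in trace")
    V_base = float(np.mean(V[base_mask][-max(1, base_mask.sum() // 2) :]))

    tw = t[on_mask] - step.t_on
    Vw = V[on_mask]
    V_ss0 = float(np.mean(Vw[tw > 0.8 * tw[-1]]))
    V_00 = float(Vw[0])
    if V_ss0 == V_00:
        # flat response: infinite-speed or zero-deflection degenerate case
        return (V_ss0 - V_base) / step.amplitude_pA * 1e3, 0.0

    # log-linear initial guess for τ from the early decay
    dev = (Vw - V_ss0) / (V_00 - V_ss0)
    pos = dev > 0.05
    tau0 = 1.0
    if pos.sum() >= 3:
        slope = np.polyfit(tw[pos], np.log(dev[pos]), 1)[0]
        if slope < 0:
            tau0 = -1.0 / slope

    def model(x, V_ss, dV, tau):
        return V_ss + dV * np.exp(-x / tau)

    popt, _ = curve_fit(
        model,
        tw,
        Vw,
        p0=[V_ss0, V_00 - V_ss0, tau0],
        maxfev=10000,
    )
    V_ss, _, tau = popt
    R_in = (V_ss - V_base) / step.amplitude_pA * 1e3  # mV/pA → MΩ
    return float(R_in), float(abs(tau))


@dataclass(frozen=True)
class ImpedanceProfile:
    """Impedance magnitude on a frequency grid, with any resonance frequency.

    ``resonance_f`` is reported only when an interior maximum exceeds the
    zero-frequency (lowest-band) value; a pure RC membrane has none.
    """

    f: np.ndarray  # Hz
    magnitude: np.ndarray  # MΩ
    resonance_f: float | None

    @property
    def z0(self) -> float:
        """Impedance at the lowest analyzed frequency, MΩ."""
        return float(self.magnitude[0])


def impedance_profile(
    V: np.ndarray,
    I: np.ndarray,
    dt_ms: float,
    *,
    band: tuple[float, float] = (0.5, 15.0),
    smooth_Hz: float = 0.5,
) -> ImpedanceProfile:
    """|Z(f)| = |FFT(V − mean) / FFT(I − mean)| over the analysis band.

    With V in mV and I in pA the raw ratio is in GΩ; the profile is
    reported in MΩ.  The bin-by-bin quotient is smoothed with a
    moving average of width ``smooth_Hz`` to stabilize the bin-by-bin FFT
    quotient; a resonance is an interior maximum of the smoothed curve
    that exceeds its low-frequency end.
    """
    V = np.asarray(V, dtype=float)
    I = np.asarray(I, dtype=float)
    if V.shape != I.shape or V.ndim != 1:
        raise ValueError("V and I must be one-dimensional and the same length")
    n = V.size
    fs = 1e3 / dt_ms  # Hz
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    Vf = np.fft.rfft(V - V.mean())
    If = np.fft.rfft(I - I.mean())

    lo, hi = band
    m = (f >= lo) & (f <= hi)
    if not np.any(m):
        raise ValueError("analysis band contains no frequency bins")
    power = np.abs(If[m])
    if np.max(power) == 0:
        raise ValueError("stimulus has no power in the analysis band")

    Z = np.abs(Vf[m]) / np.maximum(np.abs(If[m]), 1e-300) * 1e3  # MΩ
    fb = f[m]

    df = fb[1] - fb[0] if fb.size > 1 else smooth_Hz
    w = max(1, int(round(smooth_Hz / df)))
    if w > 1:
        kernel = np.ones(w) / w
        Z = np.convolve(Z, kernel, mode="same")
        # trim half-window edges where the moving average is one-sided
        h = w // 2
        fb, Z = fb[h : fb.size - h], Z[h : Z.size - h]

    imax = int(np.argmax(Z))
    resonance = None
    if 0 < imax < Z.size - 1 and Z[imax] > Z[0]:
        resonance = float(fb[imax])
    return ImpedanceProfile(f=fb, magnitude=Z, resonance_f=resonance)


@dataclass(frozen=True)
class ErrorStats:
    """Statistics of (measured − reference) current, pA."""

    mean_abs: float
    sd_abs: float
    max_abs: float
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        # mean of |e| can exceed max by one ulp-scale rounding error
        assert self.max_abs >= self.mean_abs * (1.0 - 1e-12)
        assert self.mean_abs >= 0


def error_stats(
    measured: np.ndarray, reference: np.ndarray, *, bins: int = 50
) -> ErrorStats:
    """Summarize the deviation between a measured and a reference current.

    Mirrors the closed-loop validation histograms: the reference series is
    what an ideal integrator (e.g. RK4 at a fine step) would have injected
    for the same recorded voltages.
    """
    measured = np.asarray(measured, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if measured.shape != reference.shape:
        raise ValueError("measured and reference must have equal length")
    err = measured - reference
    abs_err = np.abs(err)
    counts, edges = np.histogram(err, bins=bins)
    return ErrorStats(
        mean_abs=float(abs_err.mean()),
        sd_abs=float(abs_err.std()),
        max_abs=float(abs_err.max()),
        bin_edges=edges,
        counts=counts,
    )


@dataclass(frozen=True)
class VmStats:
    """Subthreshold membrane-potential statistics (spike-clipped if asked)."""

    mean: float
    sd: float
    bin_edges: np.ndarray
    counts: np.ndarray
    n_clipped: int


def vm_stats(
    trace: Trace,
    *,
    spike_threshold: float | None = None,
    clip_window_ms: float = 2.0,
    bins: int = 60,
    vm_channel: str = "Vm_mV",
) -> VmStats:
    """Mean, SD and histogram of V_m, excluding spikes if a threshold is set.

    Samples within ±``clip_window_ms`` of an upward threshold crossing are
    removed before computing the statistics (the standard way to describe
    the subthreshold distribution of an actively firing recording).
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    V = trace[vm_channel]
    t = trace.t
    keep = np.ones(V.size, dtype=bool)
    if spike_threshold is not None:
        above = V >= spike_threshold
        crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
        for idx in crossings:
            keep &= np.abs(t - t[idx]) > clip_window_ms
    if not np.any(keep):
        raise ValueError("all samples fall inside spike-clipping windows")
    Vk = V[keep]
    counts, edges = np.histogram(Vk, bins=bins)
    return VmStats(
        mean=float(Vk.mean()),
        sd=float(Vk.std()),
        bin_edges=edges,
        counts=counts,
        n_clipped=int(V.size - Vk.size),
    )
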