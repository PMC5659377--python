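"""Canned validation experiments composed from the library primitives.

These are the measurements a rig operator would script: membrane-potential
resolution of the input chain, and the input-resistance drop produced by
point-conductance synaptic background.  They are used both by the test
suite and by the reproduction script, so the procedure is defined once.
"""

from __future__ import annotations

import numpy as np

from .calibration import CalibrationMap
from .cell import MembraneParams
from .conductances import ConductanceSpec
from .engine import QuantizerSpec, run_closed_loop
from .fixtures import MODEL_CELL
from .ou import OUPairParams
from .stimuli import Segment, StimulusProtocol

__all__ = [
    "adc_step_mV",
    "vm_resolution_mV",
    "ou_background_rin",
    "ou_background_rin_ratio",
]


def adc_step_mV(adc: QuantizerSpec | None = None) -> float:
    """ADC voltage increment in millivolts (12 bits over 3.3 V → 0.806 mV)."""
    adc = adc or QuantizerSpec()
    return adc.step * 1e3


def vm_resolution_mV(
    adc: QuantizerSpec | None = None, calib: CalibrationMap | None = None
) -> float:
    """Membrane-potential resolution of the full input chain, mV.

    One ADC increment divided by the combined gain of the amplifier scaling
    (V per mV of V_m) and the input-circuit slope (V per V).
    """
    adc = adc or QuantizerSpec()
    calib = calib or CalibrationMap.ideal()
    gain_V_per_mV = calib.input_slope / calib.amp_mV_per_V
    return adc.step / gain_V_per_mV


def _sweep_protocol(n_sweeps: int, baseline_ms: float, step_ms: float,
                    amplitude_pA: float) -> StimulusProtocol:
    segs = []
    t = 0.0
    for _ in range(n_sweeps):
        segs.append(Segment("hold", t, baseline_ms, {"amplitude_pA": 0.0}))
        t += baseline_ms
        segs.append(Segment("step", t, step_ms, {"amplitude_pA": amplitude_pA}))
        t += step_ms
    return StimulusProtocol(segments=tuple(segs))


def ou_background_rin(
    *,
    background: OUPairParams | None,
    cell: MembraneParams = MODEL_CELL,
    amplitude_pA: float = -20.0,
    step_ms: float = 500.0,
    baseline_ms: float = 500.0,
    n_sweeps: int = 8,
    settle_ms: float = 250.0,
    seed: int = 0,
) -> float:
    """Input resistance (MΩ) from repeated hyperpolarizing probe steps.

    Runs the closed loop (with the OU background pair if given), presents
    ``n_sweeps`` baseline/step cycles, and measures the mean steady-state
    deflection — the tail of each window after ``settle_ms`` — divided by
    the step amplitude, averaged over sweeps.  Averaging across sweeps is
    what beats down the slow inhibitory OU fluctuations.
    """
    conds: list[ConductanceSpec] = []
    if background is not None:
        conds.append(
            ConductanceSpec(kind="ou_pair", g_max=0.0, E_rev=0.0,
                            ou_params=background, name="ou")
        )
    protocol = _sweep_protocol(n_sweeps, baseline_ms, step_ms, amplitude_pA)
    tr = run_closed_loop(cell, conds, protocol, seed=seed)
    t, V = tr.t, tr["Vm_mV"]

    deflections = []
    t0 = 0.0
    for _ in range(n_sweeps):
        base = V[(t >= t0 + settle_ms) & (t < t0 + baseline_ms)].mean()
        step = V[(t >= t0 + baseline_ms + settle_ms) & (t < t0 + baseline_ms + step_ms)].mean()
        deflections.append(step - base)
        t0 += baseline_ms + step_ms
    return float(np.mean(deflections) / amplitude_pA * 1e3)  # mV/pA → MΩ


def ou_background_rin_ratio(
    *,
    gE0: float = 4.0,
    gI0: float = 4.0,
    sE: float = 0.25,
    sI: float = 0.25,
    seed: int = 0,
    n_sweeps: int = 8,
) -> float:
    """R_in without / with the point-conductance background (fold change).

    With mean conductances gE0 + gI0 added to the leak, the expected ratio
    is R_m·(1/R_m + gE0 + gI0); at 4 nS each on the 507.7 MΩ model cell the
    background cuts the input resistance about five-fold.
    """
    quiet = ou_background_rin(background=None, seed=seed, n_sweeps=max(1, n_sweeps // 4))
    busy = ou_background_rin(
        background=OUPairParams.from_config(gE0=gE0, gI0=gI0, sE=sE, sI=sI),
        seed=seed,
        n_sweeps=n_sweeps,
    )
    return quiet / busy
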