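"""Voltage maps between amplifier and controller domains, and their calibration.

The controller reads 0–3.3 V but the amplifier speaks ±9 V, so two linear
circuits sit between them:

- input chain (amplifier → controller): follower + divider + differential
  amplifier, ``V_OUT = (1 + R6/R5)·[R4·R2/((R3+R4)(R1+R2))·V_IN
  + R3/(R3+R4)·V_+]``;
- output chain (controller → amplifier): differential amplifier,
  ``V_DC = (1 + R10/R9)·[R8/(R7+R8)·V_DAC + R7/(R7+R8)·V_−]``;
- summing stage: two cascaded inverting amplifiers add the dynamic-clamp
  command to the DAQ's current-clamp command with restored polarity.

Real components deviate from the ideal formulas by a few percent, which is
why the slopes and intercepts are calibrated empirically: either by driving
the circuits directly with known voltages (``fit_calibration``) or by
recording a model cell of known architecture (``model_cell_calibration``).
Op-amp non-ideality (bandwidth, slew rate, non-rail-to-rail behavior) is
not modeled; component imperfection is represented abstractly as
slope/intercept deviation plus noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CircuitResistors",
    "CalibrationMap",
    "ideal_input_map",
    "ideal_output_map",
    "summing_map",
    "fit_calibration",
    "model_cell_calibration",
    "ModelCellRecording",
    "LineFit",
]


@dataclass(frozen=True)
class CircuitResistors:
    """Resistor values (Ω) and supply rails (V) of the interface circuits.

    Defaults are the published breadboard values; R1–R6 form the input
    divider/differential stage, R7–R10 the output stage, R11–R17 the
    summing stage.
    """

    R1: float = 2200.0
    R2: float = 470.0
    R3: float = 4700.0
    R4: float = 22000.0
    R5: float = 10000.0
    R6: float = 100.0
    R7: float = 4700.0
    R8: float = 22000.0
    R9: float = 10000.0
    R10: float = 10000.0
    R11: float = 10000.0
    R12: float = 10000.0
    R13: float = 10000.0
    R14: float = 3300.0
    R15: float = 10000.0
    R16: float = 10000.0
    R17: float = 4700.0
    V_plus: float = 9.0
    V_minus: float = -9.0

    def __post_init__(self) -> None:
        for i in range(1, 18):
            if getattr(self, f"R{i}") <= 0:
                raise ValueError(f"R{i} must be positive")

    def perturbed(self, fraction: float, rng: np.random.Generator) -> "CircuitResistors":
        """Copy with every resistor multiplied by 1 + N(0, fraction).

        Emulates component tolerance (e.g. fraction=0.02 for ~2% parts).
        """
        changes = {
            f"R{i}": getattr(self, f"R{i}") * (1.0 + fraction * float(rng.standard_normal()))
            for i in range(1, 18)
        }
        return replace(self, **changes)

    # slope/intercept of the ideal maps, for direct use
    @property
    def input_slope(self) -> float:
        return (1.0 + self.R6 / self.R5) * self.R4 * self.R2 / (
            (self.R3 + self.R4) * (self.R1 + self.R2)
        )

    @property
    def input_intercept(self) -> float:
        return (1.0 + self.R6 / self.R5) * self.R3 / (self.R3 + self.R4) * self.V_plus

    @property
    def output_slope(self) -> float:
        return (1.0 + self.R10 / self.R9) * self.R8 / (self.R7 + self.R8)

    @property
    def output_intercept(self) -> float:
        return (1.0 + self.R10 / self.R9) * self.R7 / (self.R7 + self.R8) * self.V_minus


def ideal_input_map(V_IN: float | np.ndarray, r: CircuitResistors | None = None):
    """Amplifier output (±9 V) → controller ADC input (0–3.3 V), ideal components."""
    r = r or CircuitResistors()
    return r.input_slope * np.asarray(V_IN, dtype=float) + r.input_intercept


def ideal_output_map(V_DAC: float | np.ndarray, r: CircuitResistors | None = None):
    """Controller DAC output (0–3.3 V) → amplifier command (±9 V), ideal components."""
    r = r or CircuitResistors()
    return r.output_slope * np.asarray(V_DAC, dtype=float) + r.output_intercept


def summing_map(
    V_DC: float | np.ndarray,
    V_DAQ: float | np.ndarray,
    weights: tuple[float, float] = (1.0, 1.0),
):
    """Summing stage: V_AMP = w1·V_DC + w2·V_DAQ.

    The physical stage is two cascaded inverting amplifiers, so the double
    inversion restores polarity; with equal resistors the weights are unit.
    """
    w1, w2 = weights
    return w1 * np.asarray(V_DC, dtype=float) + w2 * np.asarray(V_DAQ, dtype=float)


@dataclass(frozen=True)
class CalibrationMap:
    """Linear voltage maps in both directions plus amplifier scaling factors.

    ``input_slope/intercept`` give V_OUT per V_IN (amplifier→controller);
    ``output_slope/intercept`` give V_DC per V_DAC (controller→amplifier);
    ``amp_mV_per_V`` converts amplifier output volts to membrane mV
    (default 10 mV/V i.e. 0.1 V per mV); ``amp_pA_per_V`` converts command
    volts to injected pA (default 400 pA/V).
    """

    input_slope: float
    input_intercept: float
    output_slope: float
    output_intercept: float
    amp_mV_per_V: float = 10.0
    amp_pA_per_V: float = 400.0

    def __post_init__(self) -> None:
        for name in ("input_slope", "output_slope", "amp_mV_per_V", "amp_pA_per_V"):
            if getattr(self, name) == 0:
                raise ValueError(f"{name} must be nonzero")

    @classmethod
    def ideal(cls, r: CircuitResistors | None = None, **amp) -> "CalibrationMap":
        """Map computed from the ideal circuit formulas (exact components)."""
        r = r or CircuitResistors()
        return cls(
            input_slope=r.input_slope,
            input_intercept=r.input_intercept,
            output_slope=r.output_slope,
            output_intercept=r.output_intercept,
            **amp,
        )

    @classmethod
    def identity(cls) -> "CalibrationMap":
        return cls(1.0, 0.0, 1.0, 0.0, amp_mV_per_V=1.0, amp_pA_per_V=1.0)

    # forward/inverse maps -------------------------------------------------
    def input_forward(self, V_IN):
        return self.input_slope * np.asarray(V_IN, dtype=float) + self.input_intercept

    def input_inverse(self, V_OUT):
        return (np.asarray(V_OUT, dtype=float) - self.input_intercept) / self.input_slope

    def output_forward(self, V_DAC):
        return self.output_slope * np.asarray(V_DAC, dtype=float) + self.output_intercept

    def output_inverse(self, V_DC):
        return (np.asarray(V_DC, dtype=float) - self.output_intercept) / self.output_slope

    # full-chain conversions ----------------------------------------------
    def vm_to_adc_volts(self, V_m_mV):
        """Membrane mV → voltage at the controller's ADC pin."""
        return self.input_forward(np.asarray(V_m_mV, dtype=float) / self.amp_mV_per_V)

    def adc_volts_to_vm(self, v):
        """ADC-pin volts → inferred membrane mV."""
        return self.input_inverse(v) * self.amp_mV_per_V

    def current_to_dac_volts(self, I_pA):
        """Desired injected pA → DAC-pin volts commanding it."""
        return self.output_inverse(np.asarray(I_pA, dtype=float) / self.amp_pA_per_V)

    def dac_volts_to_current(self, v):
        """DAC-pin volts → current actually injected, pA."""
        return self.output_forward(v) * self.amp_pA_per_V

    def to_dict(self) -> dict:
        return {
            "input_slope": self.input_slope,
            "input_intercept": self.input_intercept,
            "output_slope": self.output_slope,
            "output_intercept": self.output_intercept,
            "amp_mV_per_V": self.amp_mV_per_V,
            "amp_pA_per_V": self.amp_pA_per_V,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationMap":
        return cls(**d)


@dataclass(frozen=True)
class LineFit:
    """Ordinary-least-squares line: slope, intercept, residual SD."""

    slope: float
    intercept: float
    residual_sd: float


def fit_calibration(pairs) -> LineFit:
    """OLS straight-line fit of (known input, measured output) voltage pairs.

    Requires at least 3 pairs spanning a nonzero input range.  Returns the
    slope, intercept and residual standard deviation — the empirical
    replacement for the ideal circuit formula.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (input, output)")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 calibration pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("calibration inputs must span a nonzero range")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    dof = max(1, x.size - 2)
    return LineFit(float(slope), float(intercept), float(math.sqrt(resid @ resid / dof)))


@dataclass(frozen=True)
class ModelCellRecording:
    """Responses of a known model cell used for calibration.

    Voltage commands (amplifier in voltage mode, membrane driven to known
    potentials) probe the input chain directly:
      ``v_cmd_mV`` → ``v_adc_V`` (voltage read at the ADC pin).
    Current commands (controller drives the DAC, cell settles Ohmically)
    probe the output chain through the cell:
      ``v_dac_V`` → ``v_adc_i_V`` (steady-state ADC reading).
    """

    v_cmd_mV: np.ndarray
    v_adc_V: np.ndarray
    v_dac_V: np.ndarray
    v_adc_i_V: np.ndarray


def model_cell_calibration(
    rec: ModelCellRecording,
    cell,
    *,
    amp_mV_per_V: float = 10.0,
    amp_pA_per_V: float = 400.0,
) -> CalibrationMap:
    """Infer both calibration maps from recordings of a known model cell.

    The input map comes from regressing the ADC reading on the commanded
    membrane potential (converted to amplifier volts).  The output map
    comes from the steady-state Ohmic prediction: a DAC voltage ``v`` makes
    the amplifier inject ``I = amp_pA_per_V·(a_out·v + b_out)`` pA, which
    deflects the cell to ``E_rest + I·R_m``; regressing the *inferred*
    membrane potential (through the already-fitted input map) on ``v``
    then yields ``a_out`` and ``b_out`` by Ohm's law.

    Requires ≥3 distinct command amplitudes in each protocol.
    """
    v_cmd = np.asarray(rec.v_cmd_mV, dtype=float)
    if np.unique(v_cmd).size < 3:
        raise ValueError("need ≥3 distinct voltage-command amplitudes")
    if np.unique(np.asarray(rec.v_dac_V)).size < 3:
        raise ValueError("need ≥3 distinct current-command amplitudes")

    fin = fit_calibration(np.column_stack([v_cmd / amp_mV_per_V, rec.v_adc_V]))

    # invert the fitted input map to recover membrane mV under each current
    # command, then compare with the Ohmic prediction
    vm = (np.asarray(rec.v_adc_i_V, dtype=float) - fin.intercept) / fin.slope * amp_mV_per_V
    # vm = E_rest + 1e-3·R_m·amp_pA_per_V·(a_out·v_dac + b_out)
    k = 1e-3 * cell.R_m * amp_pA_per_V
    fout = fit_calibration(np.column_stack([np.asarray(rec.v_dac_V), (vm - cell.E_rest) / k]))

    return CalibrationMap(
        input_slope=fin.slope,
        input_intercept=fin.intercept,
        output_slope=fout.slope,
        output_intercept=fout.intercept,
        amp_mV_per_V=amp_mV_per_V,
        amp_pA_per_V=amp_pA_per_V,
    )
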