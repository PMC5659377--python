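"""Deterministic synthetic inputs: everything the tests and demos consume.

This module stands in for the physical rig.  It fabricates calibration
voltage pairs (with component tolerance and measurement noise), model-cell
recordings through a known-but-imperfect chain, and ready-made run configs
reproducing each validation experiment (step family + shunt, HCN chirp,
sodium voltage step, EPSC trains, OU background).  Every output is a pure
function of the seed; the manifest records the true generating parameters
so parameter-recovery tests can assert against them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationMap,
    CircuitResistors,
    ModelCellRecording,
)
from .cell import MembraneParams
from .ou import gaussian_stream

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "make_calibration_pairs",
    "make_model_cell_recording",
    "figure_config",
    "FIGURE_KINDS",
    "MODEL_CELL",
]

#: The reference passive model cell used by every validation experiment
#: (fitted lumped parameters of a commercial patch-clamp model cell).
MODEL_CELL = MembraneParams(R_m=507.7, C_m=35.9, E_rest=-70.0)

FIGURE_KINDS = ("fig4_shunt", "fig5_hcn", "fig6_na", "fig7_epsc", "fig8_ou")

#: Default component tolerance: real resistors land a couple of percent off
#: their nominal values, which is what makes empirical calibration necessary.
DEFAULT_PERTURBATION = 0.02


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: kind, seed, noise level, component tolerance."""

    kind: str
    seed: int = 0
    noise_sd: float = 0.0
    perturbation_fraction: float = 0.0
    figure: str | None = None  # for kind="figure_experiment"

    def __post_init__(self) -> None:
        if self.kind not in ("calibration_pairs", "cell_recording", "figure_experiment"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.perturbation_fraction < 0 or self.noise_sd < 0:
            raise ValueError("noise_sd and perturbation_fraction must be ≥ 0")
        if self.kind == "figure_experiment" and self.figure not in FIGURE_KINDS:
            raise ValueError(f"figure must be one of {FIGURE_KINDS}")


def make_calibration_pairs(
    *,
    direction: str = "input",
    n: int = 50,
    seed: int = 0,
    noise_sd: float = 0.0,
    perturbation_fraction: float = 0.0,
) -> tuple[np.ndarray, CircuitResistors]:
    """(known input V, measured output V) pairs from a possibly imperfect circuit.

    ``direction`` selects the input chain (±9 V span) or output chain
    (0–3.3 V span).  The circuit is the ideal map evaluated with resistors
    perturbed by the component tolerance, plus additive Gaussian
    measurement noise of ``noise_sd`` volts.  Returns the pairs and the
    *true* perturbed resistor set (the generating parameters).
    """
    if direction not in ("input", "output"):
        raise ValueError("direction must be 'input' or 'output'")
    rng = gaussian_stream(seed)
    r = CircuitResistors()
    if perturbation_fraction > 0:
        r = r.perturbed(perturbation_fraction, rng)
    if direction == "input":
        x = np.linspace(-9.0, 9.0, n)
        y = r.input_slope * x + r.input_intercept
    else:
        x = np.linspace(0.0, 3.3, n)
        y = r.output_slope * x + r.output_intercept
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(n)
    return np.column_stack([x, y]), r


def make_model_cell_recording(
    *,
    cell: MembraneParams = MODEL_CELL,
    true_map: CalibrationMap | None = None,
    n_commands: int = 9,
    seed: int = 0,
    noise_sd: float = 0.0,
    distortion: float = 0.0,
) -> tuple[ModelCellRecording, CalibrationMap]:
    """Steady-state model-cell responses through a known true chain.

    Voltage commands span ±80 mV; current commands span the DAC range.
    ``distortion`` multiplies the true slopes by (1 ± distortion), drawn
    once, emulating an uncalibrated circuit; ``noise_sd`` (volts) is added
    to every ADC reading.  Returns the recording and the true map.
    """
    rng = gaussian_stream(seed)
    if true_map is None:
        true_map = CalibrationMap.ideal()
    if distortion > 0:
        true_map = CalibrationMap(
            input_slope=true_map.input_slope * (1.0 + distortion * float(rng.standard_normal())),
            input_intercept=true_map.input_intercept
            + 0.01 * distortion * float(rng.standard_normal()),
            output_slope=true_map.output_slope * (1.0 + distortion * float(rng.standard_normal())),
            output_intercept=true_map.output_intercept
            + 0.01 * distortion * float(rng.standard_normal()),
            amp_mV_per_V=true_map.amp_mV_per_V,
            amp_pA_per_V=true_map.amp_pA_per_V,
        )

    v_cmd = np.linspace(-80.0, 80.0, n_commands)  # mV, voltage-clamp style
    v_adc = np.asarray(true_map.vm_to_adc_volts(v_cmd), dtype=float)

    v_dac = np.linspace(0.3, 3.0, n_commands)  # V at the DAC pin
    I = np.asarray(true_map.dac_volts_to_current(v_dac), dtype=float)  # pA actually injected
    vm = cell.E_rest + I * cell.R_m * 1e-3  # steady-state Ohmic deflection
    v_adc_i = np.asarray(true_map.vm_to_adc_volts(vm), dtype=float)

    if noise_sd > 0:
        v_adc = v_adc + noise_sd * rng.standard_normal(v_adc.size)
        v_adc_i = v_adc_i + noise_sd * rng.standard_normal(v_adc_i.size)

    rec = ModelCellRecording(
        v_cmd_mV=v_cmd, v_adc_V=v_adc, v_dac_V=v_dac, v_adc_i_V=v_adc_i
    )
    return rec, true_map


def figure_config(figure: str, *, seed: int = 0) -> dict[str, Any]:
    """Ready-made run config reproducing one validation experiment.

    - ``fig4_shunt``: −50..+50 pA step family (25 pA increments) on the
      model cell with a 5 nS shunt.
    - ``fig5_hcn``: chirp (0→15 Hz, 15 s) with 4 nS HCN — resonance.
    - ``fig6_na``: 40 ms current steps with 20 nS sodium conductance.
    - ``fig7_epsc``: 50 Hz train of 10 EPSC triggers, 2 nS synapse.
    - ``fig8_ou``: OU background, gE0 = gI0 = 4 nS, on a −20 pA probe step.
    """
    cell = {"R_m_MOhm": MODEL_CELL.R_m, "C_m_pF": MODEL_CELL.C_m, "E_rest_mV": MODEL_CELL.E_rest}
    base: dict[str, Any] = {"cell": cell, "seed": seed}
    if figure == "fig4_shunt":
        base["conductances"] = [{"kind": "shunt", "g_nS": 5.0, "E_rev_mV": -70.0}]
        base["protocol"] = {"kind": "step", "amplitude_pA": -50.0,
                            "onset_ms": 100.0, "duration_ms": 500.0, "tail_ms": 100.0}
    elif figure == "fig5_hcn":
        base["conductances"] = [{"kind": "hcn", "g_nS": 4.0}]
        base["protocol"] = {"kind": "chirp", "amplitude_pA": 20.0,
                            "f0_Hz": 0.0, "f1_Hz": 15.0, "duration_ms": 15000.0}
    elif figure == "fig6_na":
        base["conductances"] = [{"kind": "na", "g_nS": 20.0}]
        base["protocol"] = {"kind": "step", "amplitude_pA": 50.0,
                            "onset_ms": 20.0, "duration_ms": 40.0, "tail_ms": 40.0}
    elif figure == "fig7_epsc":
        base["conductances"] = [{"kind": "epsc", "g_nS": 2.0}]
        base["protocol"] = {"kind": "train", "rate_Hz": 50.0, "count": 10,
                            "start_ms": 50.0, "duration_ms": 400.0}
    elif figure == "fig8_ou":
        base["conductances"] = [{
            "kind": "ou_pair", "gE0_nS": 4.0, "gI0_nS": 4.0,
            "sE_nS": 0.25, "sI_nS": 0.25,
        }]
        base["protocol"] = {"kind": "step", "amplitude_pA": -20.0,
                            "onset_ms": 500.0, "duration_ms": 500.0, "tail_ms": 100.0}
    else:
        raise ValueError(f"unknown figure {figure!r}")
    return base


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Any]:
    """Write the fixture's files plus a manifest; returns the manifest.

    The manifest records the seed, the true generating parameters and a
    sha256 per file, so identical specs produce hash-identical fixtures
    and recovery tests can assert against the truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    truth: dict[str, Any] = {}

    if spec.kind == "calibration_pairs":
        for direction in ("input", "output"):
            pairs, r = make_calibration_pairs(
                direction=direction,
                seed=spec.seed,
                noise_sd=spec.noise_sd,
                perturbation_fraction=spec.perturbation_fraction,
            )
            path = out_dir / f"calibration_{direction}_pairs.csv"
            pd.DataFrame(pairs, columns=["v_in_V", "v_out_V"]).to_csv(
                path, index=False, float_format="%.12g"
            )
            files.append(path)
            truth[direction] = {
                "slope": r.input_slope if direction == "input" else r.output_slope,
                "intercept": r.input_intercept if direction == "input" else r.output_intercept,
            }
    elif spec.kind == "cell_recording":
        rec, true_map = make_model_cell_recording(
            seed=spec.seed, noise_sd=spec.noise_sd,
            distortion=spec.perturbation_fraction,
        )
        path = out_dir / "model_cell_recording.csv"
        pd.DataFrame(
            {
                "v_cmd_mV": rec.v_cmd_mV,
                "v_adc_V": rec.v_adc_V,
                "v_dac_V": rec.v_dac_V,
                "v_adc_i_V": rec.v_adc_i_V,
            }
        ).to_csv(path, index=False, float_format="%.12g")
        files.append(path)
        truth["true_map"] = true_map.to_dict()
        truth["cell"] = {"R_m_MOhm": MODEL_CELL.R_m, "C_m_pF": MODEL_CELL.C_m,
                         "E_rest_mV": MODEL_CELL.E_rest}
    else:  # figure_experiment
        config = figure_config(spec.figure, seed=spec.seed)
        path = out_dir / f"{spec.figure}_config.json"
        path.write_text(json.dumps(config, indent=2, sort_keys=True))
        files.append(path)
        truth["config"] = config

    manifest = {
        "kind": spec.kind,
        "figure": spec.figure,
        "seed": spec.seed,
        "noise_sd": spec.noise_sd,
        "perturbation_fraction": spec.perturbation_fraction,
        "truth": truth,
        "files": {p.name: _sha256(p) for p in files},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
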