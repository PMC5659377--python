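"""Configuration schema and structured I/O.

A run is described by a single JSON config (schema-validated, unknown keys
rejected) naming the cell, the conductances, the stimulus protocol, the
loop timing, the converters and the calibration.  Conductance kinetics may
be given inline (parametric) or as an external CSV table with columns
``V_mV, s_inf, tau_ms`` (linear interpolation, flat extrapolation).

Traces are CSV with units in the column headers plus a JSON metadata
sidecar (see :mod:`dynclamp.trace`); analysis results and calibration maps
are JSON; histograms are two-column CSV (bin_center, count).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import conductances as cond
from .calibration import CalibrationMap
from .cell import MembraneParams
from .engine import ClampTiming, QuantizerSpec
from .ou import DEFAULT_E_E, DEFAULT_E_I, DEFAULT_TAU_E, DEFAULT_TAU_I, OUPairParams
from .stimuli import StimulusProtocol, build_protocol

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "build_run",
    "read_kinetics_csv",
    "write_histogram_csv",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CellConfig(_Strict):
    R_m_MOhm: float = Field(gt=0)
    C_m_pF: float = Field(gt=0)
    E_rest_mV: float = -70.0
    R_series_MOhm: float = Field(default=0.0, ge=0)
    C_stray_pF: float = Field(default=0.0, ge=0)


class GateConfig(_Strict):
    """Parametric (Boltzmann + constant/bell τ) or tabulated gate kinetics."""

    V_half_mV: Optional[float] = None
    slope_mV: Optional[float] = None
    tau_ms: Optional[float] = None  # constant τ if given
    tau_peak_ms: Optional[float] = None  # bell-shaped τ otherwise
    tau_min_ms: float = 1.0
    tau_width_mV: float = 14.0
    exponent: int = Field(default=1, ge=1)
    table_csv: Optional[str] = None  # columns V_mV, s_inf, tau_ms
    name: str = "s"

    def build(self, base_dir: Path | None = None) -> cond.GateSpec:
        if self.table_csv is not None:
            path = Path(self.table_csv)
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            return read_kinetics_csv(path, exponent=self.exponent, name=self.name)
        if self.V_half_mV is None or self.slope_mV is None:
            raise ValueError("gate needs either table_csv or V_half_mV + slope_mV")
        if self.tau_ms is not None:
            tau = float(self.tau_ms)
            tau_fn = lambda V: tau  # noqa: E731
        else:
            peak = self.tau_peak_ms if self.tau_peak_ms is not None else 50.0
            v0, w, mn = self.V_half_mV, self.tau_width_mV, self.tau_min_ms
            tau_fn = lambda V: mn + peak / np.cosh((V - v0) / w)  # noqa: E731
        return cond.boltzmann_gate(
            self.V_half_mV, self.slope_mV, tau_fn, exponent=self.exponent, name=self.name
        )


class ConductanceConfig(_Strict):
    kind: Literal["shunt", "hcn", "na", "epsc", "ou_pair", "gated"]
    name: Optional[str] = None
    g_nS: float = Field(default=0.0, ge=0)
    E_rev_mV: Optional[float] = None
    # gated / hcn custom kinetics
    gates: Optional[list[GateConfig]] = None
    # na options
    V_shift_mV: float = 0.0
    q_factor: float = 3.0
    # epsc options
    tau_x_ms: float = 1.0
    tau_s_ms: float = 10.0
    alpha_s_per_ms: float = 1.0
    # ou_pair options (either D* or s* per train)
    gE0_nS: Optional[float] = None
    gI0_nS: Optional[float] = None
    DE_nS2_per_ms: Optional[float] = None
    DI_nS2_per_ms: Optional[float] = None
    sE_nS: Optional[float] = None
    sI_nS: Optional[float] = None
    tauE_ms: float = DEFAULT_TAU_E
    tauI_ms: float = DEFAULT_TAU_I
    EE_mV: float = DEFAULT_E_E
    EI_mV: float = DEFAULT_E_I
    rectify: bool = False
    clamp_gates: bool = False

    def build(self, base_dir: Path | None = None) -> cond.ConductanceSpec:
        name = self.name
        if self.kind == "shunt":
            spec = cond.shunt_conductance(
                self.g_nS, E_rev=self.E_rev_mV if self.E_rev_mV is not None else -70.0
            )
        elif self.kind == "hcn":
            kw: dict[str, Any] = {}
            if self.E_rev_mV is not None:
                kw["E_rev"] = self.E_rev_mV
            if self.gates:
                kw["gate"] = self.gates[0].build(base_dir)
            spec = cond.hcn_conductance(self.g_nS, **kw)
        elif self.kind == "na":
            spec = cond.na_conductance(
                self.g_nS,
                E_rev=self.E_rev_mV if self.E_rev_mV is not None else 50.0,
                V_shift=self.V_shift_mV,
                q=self.q_factor,
            )
        elif self.kind == "epsc":
            spec = cond.epsc_conductance(
                self.g_nS,
                E_rev=self.E_rev_mV if self.E_rev_mV is not None else 0.0,
                tau_x=self.tau_x_ms,
                tau_s=self.tau_s_ms,
                alpha_s=self.alpha_s_per_ms,
            )
        elif self.kind == "gated":
            if not self.gates:
                raise ValueError("kind=gated requires a gates list")
            spec = cond.ConductanceSpec(
                kind="hcn",  # generic single/multi-gate machinery
                g_max=self.g_nS,
                E_rev=self.E_rev_mV if self.E_rev_mV is not None else -90.0,
                gates=tuple(g.build(base_dir) for g in self.gates),
                name=name or "gated",
            )
        elif self.kind == "ou_pair":
            if self.gE0_nS is None or self.gI0_nS is None:
                raise ValueError("ou_pair requires gE0_nS and gI0_nS")
            params = OUPairParams.from_config(
                gE0=self.gE0_nS,
                gI0=self.gI0_nS,
                DE=self.DE_nS2_per_ms,
                DI=self.DI_nS2_per_ms,
                sE=self.sE_nS,
                sI=self.sI_nS,
                tauE=self.tauE_ms,
                tauI=self.tauI_ms,
                EE=self.EE_mV,
                EI=self.EI_mV,
                rectify=self.rectify,
            )
            spec = cond.ConductanceSpec(
                kind="ou_pair", g_max=0.0, E_rev=0.0, ou_params=params,
                name=name or "ou",
            )
        else:  # pragma: no cover
            raise ValueError(self.kind)
        if name and spec.name != name:
            spec = cond.ConductanceSpec(
                kind=spec.kind, g_max=spec.g_max, E_rev=spec.E_rev, gates=spec.gates,
                synapse=spec.synapse, ou_params=spec.ou_params,
                clamp_gates=self.clamp_gates, name=name,
            )
        elif self.clamp_gates:
            spec = cond.ConductanceSpec(
                kind=spec.kind, g_max=spec.g_max, E_rev=spec.E_rev, gates=spec.gates,
                synapse=spec.synapse, ou_params=spec.ou_params,
                clamp_gates=True, name=spec.name,
            )
        return spec


class TimingConfig(_Strict):
    mean_cycle_us: float = Field(default=10.0, gt=0)
    jitter_sd_us: float = Field(default=0.0, ge=0)
    latency_cycles: int = Field(default=1, ge=0)

    def build(self) -> ClampTiming:
        return ClampTiming(self.mean_cycle_us, self.jitter_sd_us, self.latency_cycles)


class QuantizerConfig(_Strict):
    bits: int = Field(default=12, ge=1)
    v_min: float = 0.0
    v_max: float = 3.3

    def build(self) -> QuantizerSpec:
        return QuantizerSpec(self.bits, self.v_min, self.v_max)


class CalibrationConfig(_Strict):
    input_slope: float
    input_intercept: float
    output_slope: float
    output_intercept: float
    amp_mV_per_V: float = 10.0
    amp_pA_per_V: float = 400.0

    def build(self) -> CalibrationMap:
        return CalibrationMap(**self.model_dump())


class RunConfig(_Strict):
    """Top-level schema for a closed-loop run."""

    cell: CellConfig
    conductances: list[ConductanceConfig] = Field(default_factory=list)
    protocol: dict[str, Any]
    timing: TimingConfig = Field(default_factory=TimingConfig)
    adc: QuantizerConfig = Field(default_factory=QuantizerConfig)
    dac: QuantizerConfig = Field(default_factory=QuantizerConfig)
    calibration: CalibrationConfig | Literal["ideal"] = "ideal"
    seed: int = 0
    duration_ms: Optional[float] = Field(default=None, gt=0)
    gate_method: Literal["euler", "rk4", "exact"] = "euler"

    @model_validator(mode="after")
    def _check_protocol(self) -> "RunConfig":
        if "kind" not in self.protocol:
            raise ValueError("protocol must name a 'kind'")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a JSON run config (fail-fast on unknown keys)."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}:{e.lineno}: invalid JSON: {e.msg}") from e
    return RunConfig.model_validate(raw)


def config_hash(config: RunConfig) -> str:
    """Stable content hash of a validated config (for run manifests)."""
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_run(config: RunConfig, base_dir: Path | None = None) -> dict[str, Any]:
    """Turn a validated config into the concrete simulation objects."""
    cell = MembraneParams(
        R_m=config.cell.R_m_MOhm,
        C_m=config.cell.C_m_pF,
        E_rest=config.cell.E_rest_mV,
        R_series=config.cell.R_series_MOhm,
        C_stray=config.cell.C_stray_pF,
    )
    protocol: StimulusProtocol = build_protocol(config.protocol)
    calib = (
        CalibrationMap.ideal()
        if config.calibration == "ideal"
        else config.calibration.build()
    )
    return {
        "cell": cell,
        "conductances": [c.build(base_dir) for c in config.conductances],
        "protocol": protocol,
        "timing": config.timing.build(),
        "adc": config.adc.build(),
        "dac": config.dac.build(),
        "calib": calib,
        "seed": config.seed,
        "duration": config.duration_ms,
        "gate_method": config.gate_method,
    }


def read_kinetics_csv(path: str | Path, *, exponent: int = 1, name: str = "s") -> cond.GateSpec:
    """Tabulated gate kinetics from CSV with columns V_mV, s_inf, tau_ms."""
    df = pd.read_csv(path)
    missing = {"V_mV", "s_inf", "tau_ms"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: kinetics CSV missing columns {sorted(missing)}")
    return cond.tabulated_gate(
        df["V_mV"].to_numpy(), df["s_inf"].to_numpy(), df["tau_ms"].to_numpy(),
        exponent=exponent, name=name,
    )


def write_histogram_csv(path: str | Path, bin_edges: np.ndarray, counts: np.ndarray) -> None:
    """Two-column histogram CSV: bin_center, count."""
    centers = 0.5 * (np.asarray(bin_edges)[:-1] + np.asarray(bin_edges)[1:])
    pd.DataFrame({"bin_center": centers, "count": np.asarray(counts)}).to_csv(
        Path(path), index=False
    )
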