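"""Multichannel time-series container used by all simulations and analyses.

A :class:`Trace` is a thin wrapper around a strictly increasing time base
(ms) plus named channels of equal length.  Column names carry their units
(``Vm_mV``, ``I_DC_pA``, ``dt_cycle_us`` ...), so a written CSV is
self-describing; structured metadata (seed, config hash, divergence flag)
travels in a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

__all__ = ["Trace"]


@dataclass
class Trace:
    """Uniform-or-not multichannel recording.

    Attributes
    ----------
    t : ndarray
        Time stamps, ms, strictly increasing.
    channels : dict of str -> ndarray
        Named series, each the same length as ``t``; names carry units.
    metadata : dict
        Run metadata (seed, parameters, divergence flag, ...).
    """

    t: np.ndarray
    channels: dict[str, np.ndarray]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1:
            raise ValueError("t must be one-dimensional")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        self.channels = {
            k: np.asarray(v, dtype=float) for k, v in self.channels.items()
        }
        for name, v in self.channels.items():
            if v.shape != self.t.shape:
                raise ValueError(
                    f"channel {name!r} has length {v.size}, expected {self.t.size}"
                )

    def __len__(self) -> int:
        return self.t.size

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def window(self, t0: float, t1: float) -> "Trace":
        """Sub-trace with t0 ≤ t < t1 (metadata shared, arrays are views)."""
        m = (self.t >= t0) & (self.t < t1)
        return Trace(
            t=self.t[m],
            channels={k: v[m] for k, v in self.channels.items()},
            metadata=self.metadata,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_ms": self.t})
        for k, v in self.channels.items():
            df[k] = v
        return df

    def to_csv(self, path: str | Path, *, sidecar: bool = True) -> None:
        """Write the trace as CSV (full float precision) + JSON sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        if sidecar:
            meta_path = path.with_suffix(path.suffix + ".json")
            meta_path.write_text(json.dumps(_jsonable(self.metadata), indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        if "t_ms" not in df.columns:
            raise ValueError(f"{path}: trace CSV must have a 't_ms' column")
        meta_path = path.with_suffix(path.suffix + ".json")
        metadata: dict[str, Any] = {}
        if meta_path.exists():
            metadata = json.loads(meta_path.read_text())
        channels = {c: df[c].to_numpy() for c in df.columns if c != "t_ms"}
        return cls(t=df["t_ms"].to_numpy(), channels=channels, metadata=metadata)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
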