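"""Stimulus protocols: step families, slow ramps, chirp (ZAP), spike trains.

A :class:`StimulusProtocol` is an ordered list of non-overlapping segments
plus an optional list of presynaptic spike times (TTL emulation for the
simulated synapse).  ``protocol.current(t)`` evaluates the command current
in pA at arbitrary times; outside all segments it returns the baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = [
    "Segment",
    "StimulusProtocol",
    "build_protocol",
    "protocol_current",
    "step_protocol",
    "step_family",
    "ramp_protocol",
    "chirp_protocol",
    "train_protocol",
]

_KINDS = {"hold", "step", "ramp", "chirp", "custom"}


@dataclass(frozen=True)
class Segment:
    """One piece of a stimulus: kind, start (ms), duration (ms), parameters.

    Parameters by kind:
      hold / step : amplitude_pA
      ramp        : rate_pA_per_s (current grows linearly from 0)
      chirp       : amplitude_pA, f0_Hz, f1_Hz (linear frequency sweep)
      custom      : t_ms, I_pA arrays (linearly interpolated)
    """

    kind: str
    start: float
    duration: float
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.start < 0:
            raise ValueError("segment start must be non-negative")

    @property
    def end(self) -> float:
        return self.start + self.duration

    def current(self, t: np.ndarray) -> np.ndarray:
        """Current (pA) at local times inside the segment."""
        tl = t - self.start
        p = self.params
        if self.kind in ("hold", "step"):
            return np.full_like(tl, float(p["amplitude_pA"]))
        if self.kind == "ramp":
            # rate is quoted in pA/s; local time is ms
            return float(p["rate_pA_per_s"]) * tl * 1e-3
        if self.kind == "chirp":
            A = float(p["amplitude_pA"])
            f0 = float(p["f0_Hz"]) * 1e-3  # cycles/ms
            f1 = float(p["f1_Hz"]) * 1e-3
            T = self.duration
            # instantaneous frequency sweeps linearly f0→f1; the phase is
            # its integral, so the waveform is continuous in both value
            # and frequency
            phase = 2.0 * math.pi * (f0 * tl + (f1 - f0) * tl**2 / (2.0 * T))
            return A * np.sin(phase)
        if self.kind == "custom":
            return np.interp(tl, np.asarray(p["t_ms"]), np.asarray(p["I_pA"]))
        raise AssertionError(self.kind)


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered, non-overlapping current segments + presynaptic spike times."""

    segments: tuple[Segment, ...] = ()
    spike_times: tuple[float, ...] = ()
    baseline_current: float = 0.0

    def __post_init__(self) -> None:
        segs = tuple(sorted(self.segments, key=lambda s: s.start))
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end - 1e-12:
                raise ValueError(
                    f"segments overlap: [{a.start}, {a.end}) and [{b.start}, {b.end})"
                )
        object.__setattr__(self, "segments", segs)
        spikes = tuple(sorted(float(s) for s in self.spike_times))
        if spikes and spikes[0] < 0:
            raise ValueError("spike times must be non-negative")
        object.__setattr__(self, "spike_times", spikes)

    @property
    def duration(self) -> float:
        """Span of the protocol, ms (end of the last segment or spike)."""
        ends = [s.end for s in self.segments]
        if self.spike_times:
            ends.append(self.spike_times[-1])
        return max(ends, default=0.0)

    def current(self, t: float | np.ndarray) -> np.ndarray:
        """Command current I(t) in pA (vectorized piecewise evaluation)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < 0):
            raise ValueError("t must be non-negative")
        I = np.full(t.shape, self.baseline_current)
        for seg in self.segments:
            m = (t >= seg.start) & (t < seg.end)
            if np.any(m):
                I[m] = seg.current(t[m])
        return I

    def current_at(self, t: float) -> float:
        """Scalar I(t) in pA — fast path for the per-cycle engine loop."""
        for seg in self.segments:
            if seg.start <= t < seg.end:
                if seg.kind in ("hold", "step"):
                    return float(seg.params["amplitude_pA"])
                if seg.kind == "ramp":
                    return float(seg.params["rate_pA_per_s"]) * (t - seg.start) * 1e-3
                return float(seg.current(np.array([t]))[0])
        return self.baseline_current

    def spikes_in(self, t0: float, t1: float) -> int:
        """Number of presynaptic spikes with t0 ≤ t_i < t1."""
        lo = np.searchsorted(self.spike_times, t0, side="left")
        hi = np.searchsorted(self.spike_times, t1, side="left")
        return int(hi - lo)

    def to_dict(self) -> dict[str, Any]:
        return {
            "segments": [
                {
                    "kind": s.kind,
                    "start_ms": s.start,
                    "duration_ms": s.duration,
                    "params": {
                        k: (list(v) if isinstance(v, (np.ndarray, tuple)) else v)
                        for k, v in s.params.items()
                    },
                }
                for s in self.segments
            ],
            "spike_times_ms": list(self.spike_times),
            "baseline_current_pA": self.baseline_current,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StimulusProtocol":
        return cls(
            segments=tuple(
                Segment(
                    kind=s["kind"],
                    start=float(s["start_ms"]),
                    duration=float(s["duration_ms"]),
                    params=dict(s.get("params", {})),
                )
                for s in d.get("segments", [])
            ),
            spike_times=tuple(d.get("spike_times_ms", ())),
            baseline_current=float(d.get("baseline_current_pA", 0.0)),
        )


def protocol_current(protocol: StimulusProtocol, t: float | np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`StimulusProtocol.current`."""
    return protocol.current(t)


# ---------------------------------------------------------------------------
# Builders


def step_protocol(
    amplitude_pA: float,
    *,
    onset_ms: float = 100.0,
    duration_ms: float = 500.0,
    tail_ms: float = 100.0,
    baseline_pA: float = 0.0,
) -> StimulusProtocol:
    """Single current step preceded and followed by holds at baseline."""
    segs = []
    if onset_ms > 0:
        segs.append(Segment("hold", 0.0, onset_ms, {"amplitude_pA": baseline_pA}))
    segs.append(Segment("step", onset_ms, duration_ms, {"amplitude_pA": amplitude_pA}))
    if tail_ms > 0:
        segs.append(
            Segment("hold", onset_ms + duration_ms, tail_ms, {"amplitude_pA": baseline_pA})
        )
    return StimulusProtocol(segments=tuple(segs), baseline_current=baseline_pA)


def step_family(
    amplitudes_pA: Sequence[float],
    *,
    onset_ms: float = 100.0,
    duration_ms: float = 500.0,
    tail_ms: float = 100.0,
) -> list[StimulusProtocol]:
    """One protocol per amplitude, e.g. the −50..+50 pA step family."""
    return [
        step_protocol(a, onset_ms=onset_ms, duration_ms=duration_ms, tail_ms=tail_ms)
        for a in amplitudes_pA
    ]


def ramp_protocol(
    rate_pA_per_s: float, duration_ms: float, *, onset_ms: float = 0.0
) -> StimulusProtocol:
    """Slow current ramp from 0 at the stated rate (e.g. 5, 10, 20 pA/s)."""
    return StimulusProtocol(
        segments=(Segment("ramp", onset_ms, duration_ms, {"rate_pA_per_s": rate_pA_per_s}),)
    )


def chirp_protocol(
    *,
    amplitude_pA: float = 20.0,
    f0_Hz: float = 0.0,
    f1_Hz: float = 15.0,
    duration_ms: float = 15000.0,
    onset_ms: float = 0.0,
) -> StimulusProtocol:
    """ZAP stimulus: sinusoid whose frequency sweeps linearly f0→f1."""
    return StimulusProtocol(
        segments=(
            Segment(
                "chirp",
                onset_ms,
                duration_ms,
                {"amplitude_pA": amplitude_pA, "f0_Hz": f0_Hz, "f1_Hz": f1_Hz},
            ),
        )
    )


def train_protocol(
    rate_Hz: float, count: int, *, start_ms: float = 0.0, duration_ms: float | None = None
) -> StimulusProtocol:
    """Fixed-rate presynaptic spike train: spike k at start + k/rate."""
    if rate_Hz <= 0 or count <= 0:
        raise ValueError("rate and count must be positive")
    isi = 1e3 / rate_Hz
    spikes = tuple(start_ms + k * isi for k in range(count))
    segs: tuple[Segment, ...] = ()
    if duration_ms is not None:
        segs = (Segment("hold", 0.0, duration_ms, {"amplitude_pA": 0.0}),)
    return StimulusProtocol(segments=segs, spike_times=spikes)


def build_protocol(spec: dict[str, Any]) -> StimulusProtocol:
    """Build a protocol from a config-style description.

    ``spec["kind"]`` selects the builder:

    - ``step``: amplitude_pA (or amplitudes_pA → raises; use step_family),
      duration_ms, onset_ms, tail_ms
    - ``ramp``: rate_pA_per_s, duration_ms
    - ``chirp``: amplitude_pA, f0_Hz, f1_Hz, duration_ms
    - ``train``: rate_Hz, count, start_ms
    - ``segments``: explicit segment list (same schema as ``to_dict``)
    """
    kind = spec.get("kind")
    opts = {k: v for k, v in spec.items() if k != "kind"}
    if kind == "step":
        return step_protocol(**opts)
    if kind == "ramp":
        return ramp_protocol(**opts)
    if kind == "chirp":
        return chirp_protocol(**opts)
    if kind == "train":
        return train_protocol(**opts)
    if kind == "segments":
        return StimulusProtocol.from_dict(opts)
    raise ValueError(f"unknown protocol kind {kind!r}")
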