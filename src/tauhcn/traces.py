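"""Trace containers and on-disk trace format.

A :class:`Trace` is a uniformly sampled time series of membrane voltage (mV)
or clamp current (pA) together with the stimulation protocol that produced
it.  Traces are written as two-column CSV (``time_ms,value``) with a JSON
sidecar holding units, protocol, seed and any ground-truth annotations, so a
whole synthetic cohort round-trips through plain text.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["StepProtocol", "GAP_FREE", "Trace", "write_trace", "read_trace"]


@dataclass(frozen=True)
class StepProtocol:
    """Square current/voltage step protocol.

    ``holding_target`` is the pre-stimulus membrane voltage (mV) that the
    holding current clamps the cell to; ``step_amp`` is in pA for current
    clamp and mV for voltage clamp.  Voltage-clamp families additionally use
    ``n_steps`` and ``step_increment``.
    """

    holding_target: float = -80.0
    step_amp: float = -100.0
    onset: float = 200.0
    duration: float = 500.0
    n_steps: int = 1
    step_increment: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("step duration must be positive")
        if self.onset < 0:
            raise ValueError("step onset must be non-negative")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


#: Sentinel protocol tag for continuous (gap-free) recordings.
GAP_FREE = "gap-free"


@dataclass
class Trace:
    """Uniformly sampled electrophysiology trace."""

    dt: float
    samples: np.ndarray
    unit: str
    protocol: StepProtocol | str = GAP_FREE
    junction_corrected: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.samples.size < 2:
            raise ValueError("a trace needs at least two samples")
        if self.unit not in ("mV", "pA"):
            raise ValueError(f"unit must be 'mV' or 'pA', got {self.unit!r}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return self.dt * (self.n - 1)

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    def copy_with(self, **changes) -> "Trace":
        return dataclasses.replace(self, **changes)


def _protocol_to_dict(protocol: StepProtocol | str):
    if isinstance(protocol, StepProtocol):
        return dataclasses.asdict(protocol)
    return protocol


def _protocol_from_dict(obj) -> StepProtocol | str:
    if isinstance(obj, dict):
        return StepProtocol(**obj)
    return obj


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write ``path`` (CSV) plus ``path.with_suffix('.json')`` (sidecar)."""
    path = Path(path)
    pd.DataFrame({"time_ms": trace.time_ms, "value": trace.samples}).to_csv(
        path, index=False
    )
    sidecar = {
        "dt_ms": trace.dt,
        "unit": trace.unit,
        "protocol": _protocol_to_dict(trace.protocol),
        "junction_corrected": trace.junction_corrected,
        "meta": _jsonable(trace.meta),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return Trace(
        dt=float(sidecar["dt_ms"]),
        samples=df["value"].to_numpy(),
        unit=sidecar["unit"],
        protocol=_protocol_from_dict(sidecar["protocol"]),
        junction_corrected=bool(sidecar["junction_corrected"]),
        meta=sidecar.get("meta", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
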