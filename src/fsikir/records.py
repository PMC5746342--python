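"""Shared in-memory containers: time series, I–V curves, event series."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TraceRecord", "IVCurve", "EventSeries"]


@dataclass(frozen=True)
class TraceRecord:
    """Uniformly sampled time series.

    ``kind`` is one of ``voltage`` (mV), ``current`` (nA) or ``conductance``
    (µS); ``site`` labels the recording location.
    """

    dt: float  # ms
    samples: np.ndarray
    kind: str = "voltage"
    site: str = "soma"
    t0: float = 0.0  # ms
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be 1-D with length >= 2")
        if self.kind not in ("voltage", "current", "conductance"):
            raise ValueError(f"unknown trace kind {self.kind!r}")

    @property
    def time(self) -> np.ndarray:
        """Sample times, ms."""
        return self.t0 + self.dt * np.arange(self.samples.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.samples.size - 1)

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time *t* (ms)."""
        i = int(round((t - self.t0) / self.dt))
        return min(max(i, 0), self.samples.size - 1)

    def window(self, t_start: float, t_stop: float) -> np.ndarray:
        """Samples with t_start <= t <= t_stop."""
        return self.samples[self.index_at(t_start): self.index_at(t_stop) + 1]


@dataclass(frozen=True)
class IVCurve:
    """Current as a function of command voltage from a ramp protocol."""

    v: np.ndarray  # mV, strictly increasing
    i: np.ndarray  # nA
    condition: str = ""
    ramp_duration: float | None = None  # ms, set by the ramp protocol

    def __post_init__(self) -> None:
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        object.__setattr__(self, "i", np.asarray(self.i, dtype=float))
        if self.v.shape != self.i.shape or self.v.ndim != 1:
            raise ValueError("v and i must be 1-D and the same length")
        if np.any(np.diff(self.v) <= 0):
            raise ValueError("voltage grid must be strictly increasing")


@dataclass(frozen=True)
class EventSeries:
    """Ordered event times (ms) with optional per-event amplitudes."""

    times: np.ndarray
    amplitudes: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if self.amplitudes is not None:
            amp = np.asarray(self.amplitudes, dtype=float)
            if amp.shape != self.times.shape:
                raise ValueError("amplitudes must match times")
            object.__setattr__(self, "amplitudes", amp)

    def __len__(self) -> int:
        return self.times.size

    def intervals(self) -> np.ndarray:
        """Successive inter-event intervals, ms."""
        return np.diff(self.times)
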