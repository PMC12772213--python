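"""Shared in-memory containers for trap recordings, detected events and transients.

Conventions used throughout the package:

* positions in nm, barbed-end-directed motion positive;
* forces in pN, hindering load positive;
* times in seconds; sample ``i`` of a trace lives at ``i / sampling_rate``;
* event intervals are half-open ``[start, stop)`` in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrapTrace",
    "Event",
    "EventSet",
    "CovarianceSeries",
    "CovThresholds",
    "Transient",
]


@dataclass
class TrapTrace:
    """Two-channel bead position record from a three-bead trap assay.

    ``motor_pos`` / ``transducer_pos`` are the barbed-end (motor) and
    pointed-end (transducer) bead positions in nm.  ``force`` is the optional
    motor-bead force channel (pN) recorded under the isometric clamp.
    """

    motor_pos: np.ndarray
    transducer_pos: np.ndarray
    sampling_rate: float
    force: Optional[np.ndarray] = None
    atp: float = float("nan")  # µM
    mode: str = "unloaded"  # "unloaded" | "isometric"
    stiffness: tuple[float, float] = (0.08, 0.08)  # pN/nm per trap

    def __post_init__(self) -> None:
        self.motor_pos = np.asarray(self.motor_pos, dtype=float)
        self.transducer_pos = np.asarray(self.transducer_pos, dtype=float)
        if self.force is not None:
            self.force = np.asarray(self.force, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.motor_pos.shape != self.transducer_pos.shape:
            raise ValueError("position channels must have equal length")
        if self.mode not in ("unloaded", "isometric"):
            raise ValueError(f"unknown trace mode {self.mode!r}")

    @property
    def n_samples(self) -> int:
        return int(self.motor_pos.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Sample index of time ``t`` (floor)."""
        return int(math.floor(t * self.sampling_rate))


@dataclass
class Event:
    """A single actomyosin attachment interval."""

    start: float  # s
    stop: float  # s
    substep1: float = float("nan")  # nm
    substep2: float = float("nan")  # nm
    total_step: float = float("nan")  # nm
    mean_force: float = float("nan")  # pN (isometric mode)
    substep2_time: float = float("nan")  # s, ground truth only

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("event stop must exceed start")

    @property
    def duration(self) -> float:
        return self.stop - self.start


@dataclass
class EventSet:
    """Ordered, non-overlapping attachment events plus detection metadata."""

    events: list[Event]
    dead_time: float = 0.0  # s; durations below this were censored
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in zip(self.events, self.events[1:]):
            if b.start < a.stop:
                raise ValueError("events must be ordered and non-overlapping")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def durations(self) -> np.ndarray:
        return np.array([e.duration for e in self.events])

    @property
    def gaps(self) -> list[float]:
        """stop_i -> start_{i+1} intervals, in order; empty if < 2 events."""
        return [b.start - a.stop for a, b in zip(self.events, self.events[1:])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": [e.start for e in self.events],
                "stop_s": [e.stop for e in self.events],
                "duration_s": [e.duration for e in self.events],
                "substep1_nm": [e.substep1 for e in self.events],
                "substep2_nm": [e.substep2 for e in self.events],
                "total_step_nm": [e.total_step for e in self.events],
                "mean_force_pN": [e.mean_force for e in self.events],
            }
        )


@dataclass
class CovarianceSeries:
    """Sliding-window inter-bead covariance aligned to trace sample indices.

    ``values[i]`` is the sample covariance of the two position channels over
    the trailing window ``[i, i + window_samples)``; length is
    ``n_trace - window_samples + 1`` (valid mode).
    """

    values: np.ndarray
    window: float  # s
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def window_samples(self) -> int:
        return int(round(self.window * self.sampling_rate))


@dataclass
class CovThresholds:
    """Double-Gaussian fit of the covariance histogram.

    The high-covariance component corresponds to unbound actin, the
    low-covariance component to actomyosin attachment.
    """

    mu_high: float  # nm^2
    mu_low: float  # nm^2
    sd_high: float
    sd_low: float
    weight_high: float  # fraction of samples in the detached state

    def __post_init__(self) -> None:
        if not self.mu_low < self.mu_high:
            raise ValueError("mu_low must be below mu_high")
        if not 0.0 < self.weight_high < 1.0:
            raise ValueError("weight_high must lie in (0, 1)")


TRANSIENT_KINDS = ("pyrene", "mant_turnover", "pi_release", "nadh")


@dataclass
class Transient:
    """A stopped-flow or plate-reader time/signal record."""

    time: np.ndarray  # s, strictly increasing
    signal: np.ndarray  # AU
    kind: str = "pyrene"
    split_timebase: Optional[Sequence[int]] = None  # points per segment
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.kind not in TRANSIENT_KINDS:
            raise ValueError(f"unknown transient kind {self.kind!r}")

    @property
    def n_points(self) -> int:
        return int(self.time.size)
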