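"""Core containers and error types shared across the package.

The central object is :class:`EcgSignal`, a uniformly sampled single-lead
voltage series in millivolts.  Everything downstream (filtering, the curve
length transform, beat detection) operates on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DomainError(ValueError):
    """An input violates an operation's stated precondition."""


class EdgeError(DomainError):
    """A candidate lies too close to the signal boundary to analyse."""


class FormatError(ValueError):
    """A serialized artifact (binary package, table file) is malformed."""


class ConfigError(ValueError):
    """A configuration object is internally inconsistent."""


class GenerationError(RuntimeError):
    """A synthetic-data request cannot be satisfied (e.g. empty complement)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


@dataclass
class EcgSignal:
    """Uniformly sampled single-lead ECG.

    Parameters
    ----------
    samples
        Voltage series in mV.
    fs
        Sampling rate in Hz, > 0.
    t0
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise DomainError("ECG samples must be one-dimensional")
        if self.fs <= 0:
            raise DomainError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Per-sample times in seconds."""
        return self.t0 + np.arange(len(self.samples)) / self.fs

    def time_at(self, index: int) -> float:
        return self.t0 + index / self.fs


@dataclass
class LtSignal:
    """Curve length transform of an ECG record.

    Same length as the source signal; ``values[i]`` is the windowed arc
    length ending at sample ``i``.  Carries the sampling rate so that
    downstream candidate picking can convert refractory periods from
    milliseconds to samples.
    """

    values: np.ndarray
    window_w: float
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.window_w <= 0:
            raise DomainError("window_w must be positive")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FiducialPoint:
    """A landmark on a beat: sample index plus amplitude in mV."""

    x: int
    y: float


@dataclass(frozen=True)
class FiducialTriplet:
    """Q/R/S landmarks of one beat, forming the morphology triangle.

    Invariant: ``q_point.x < s_point.x`` (onset precedes end).
    """

    q_point: FiducialPoint
    r_point: FiducialPoint
    s_point: FiducialPoint

    def __post_init__(self) -> None:
        if not self.q_point.x < self.s_point.x:
            raise DomainError("QRS onset must precede QRS end")


@dataclass
class Beat:
    """One detected beat with its validation verdict.

    ``valid`` is true exactly when ``rejection_reasons`` is empty; a beat
    that fails any morphology bound is an artifact, not a heartbeat.
    """

    r_index: int
    fiducials: FiducialTriplet
    valid: bool = True
    rejection_reasons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.valid != (len(self.rejection_reasons) == 0):
            raise DomainError("valid flag inconsistent with rejection_reasons")
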