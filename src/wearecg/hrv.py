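"""Time-domain heart rate variability features.

Operates on series of normal RR intervals (milliseconds).  Features:

* AVNN  — mean RR interval, ms
* SDNN  — sample standard deviation of RR (denominator n-1), ms
* RMSSD — root mean square of the n-1 successive differences, ms
* pNN50 — percentage of successive differences STRICTLY greater than
  50 ms in magnitude (a difference of exactly 50 ms does not count)

"Normality" filtering of the RR stream is upstream: this module expects
intervals derived from morphology-validated beats only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DomainError

__all__ = ["RrSeries", "HrvFeatures", "hrv_features", "bpm_from_rr", "rr_from_beats"]


@dataclass
class RrSeries:
    """An ordered series of RR intervals in milliseconds."""

    intervals: np.ndarray
    window_label: str = ""

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1 or len(self.intervals) < 1:
            raise DomainError("RR series must be a non-empty 1-D sequence")
        if np.any(self.intervals <= 0):
            raise DomainError("RR intervals must be positive")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class HrvFeatures:
    """Time-domain HRV summary of one analysis window."""

    avnn: float   # ms
    sdnn: float   # ms
    rmssd: float  # ms
    pnn50: float  # percent, in [0, 100]

    def as_dict(self) -> dict:
        return {"avnn": self.avnn, "sdnn": self.sdnn, "rmssd": self.rmssd, "pnn50": self.pnn50}


def _as_intervals(rr) -> np.ndarray:
    if isinstance(rr, RrSeries):
        return rr.intervals
    arr = np.asarray(rr, dtype=float)
    if arr.ndim != 1:
        raise DomainError("RR input must be one-dimensional")
    if np.any(arr <= 0):
        raise DomainError("RR intervals must be positive")
    return arr


def hrv_features(rr, nn_threshold_ms: float = 50.0) -> HrvFeatures:
    """Compute AVNN / SDNN / RMSSD / pNN50 for one RR window.

    Requires at least two intervals.  ``nn_threshold_ms`` generalizes the
    50 ms cut of pNN50; the comparison is strict (> threshold).
    """
    x = _as_intervals(rr)
    n = len(x)
    if n < 2:
        raise DomainError(f"need at least 2 RR intervals, got {n}")
    diffs = np.diff(x)
    return HrvFeatures(
        avnn=float(np.mean(x)),
        sdnn=float(np.std(x, ddof=1)),
        rmssd=float(np.sqrt(np.sum(diffs**2) / (n - 1))),
        pnn50=float(100.0 * np.count_nonzero(np.abs(diffs) > nn_threshold_ms) / (n - 1)),
    )


def bpm_from_rr(rr) -> float:
    """Heart rate in beats per minute: 60000 / AVNN(ms)."""
    x = _as_intervals(rr)
    if len(x) == 0:
        raise DomainError("empty RR series")
    return 60000.0 / float(np.mean(x))


def rr_from_beats(beats, fs: float) -> np.ndarray:
    """RR intervals (ms) between consecutive VALID beats of a detector run."""
    r = np.asarray([b.r_index for b in beats if b.valid], dtype=float)
    if len(r) < 2:
        return np.empty(0)
    return np.diff(r) / fs * 1000.0
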