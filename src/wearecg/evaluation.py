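"""Detector and HRV scoring.

Beat-by-beat comparison pairs detected against reference R positions
one-to-one within a tolerance window (default 150 ms, the conventional
beat-matching window).  Pairing is leftmost-feasible greedy over the two
sorted lists, which attains maximum matching cardinality for this
translate-window structure.  Sensitivity = TP/(TP+FN), positive
prediction = TP/(TP+FP), both in percent.

HRV accuracy compares estimated against reference features as the
complement of the relative error, 100*(1 - |est-ref|/ref), clipped at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DomainError
from .hrv import HrvFeatures

__all__ = [
    "MatchReport",
    "HrvAccuracyReport",
    "FeatureAccuracy",
    "beat_by_beat_compare",
    "hrv_accuracy",
]


@dataclass(frozen=True)
class MatchReport:
    """Outcome of beat-by-beat scoring."""

    tp: int
    fp: int
    fn: int
    sensitivity: float          # percent
    positive_prediction: float  # percent
    match_window_ms: float


def beat_by_beat_compare(
    detected, reference, fs: float, match_window_ms: float = 150.0
) -> MatchReport:
    """Score detected against reference beat positions (sample indices).

    Each reference beat is matched to at most one detection within
    ±match_window; unmatched detections are false positives, unmatched
    references false negatives.  Both inputs must be sorted ascending.
    """
    det = np.asarray(detected, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if np.any(np.diff(det) < 0) or np.any(np.diff(ref) < 0):
        raise DomainError("detected and reference lists must be sorted ascending")
    window = match_window_ms / 1000.0 * fs

    tp = 0
    j = 0
    for r in ref:
        while j < len(det) and det[j] < r - window:
            j += 1
        if j < len(det) and abs(det[j] - r) <= window:
            tp += 1
            j += 1
    fp = len(det) - tp
    fn = len(ref) - tp
    sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    ppv = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    return MatchReport(
        tp=tp, fp=fp, fn=fn,
        sensitivity=sens, positive_prediction=ppv,
        match_window_ms=match_window_ms,
    )


@dataclass(frozen=True)
class FeatureAccuracy:
    """Accuracy of one HRV feature; ``accuracy`` is None when the reference
    is zero (undefined relative error)."""

    feature: str
    estimated: float
    reference: float
    accuracy: float | None

    @property
    def undefined(self) -> bool:
        return self.accuracy is None


@dataclass(frozen=True)
class HrvAccuracyReport:
    """Per-feature accuracy of an estimated HRV window vs a reference."""

    features: tuple  # of FeatureAccuracy

    def accuracy_of(self, name: str) -> float | None:
        for f in self.features:
            if f.feature == name:
                return f.accuracy
        raise KeyError(name)


def hrv_accuracy(estimated: HrvFeatures, reference: HrvFeatures) -> HrvAccuracyReport:
    """Relative-error-complement accuracy per feature, in percent."""
    rows = []
    for name in ("avnn", "sdnn", "rmssd", "pnn50"):
        est = getattr(estimated, name)
        ref = getattr(reference, name)
        if ref == 0:
            acc = None
        else:
            acc = max(0.0, 100.0 * (1.0 - abs(est - ref) / ref))
        rows.append(FeatureAccuracy(feature=name, estimated=est, reference=ref, accuracy=acc))
    return HrvAccuracyReport(features=tuple(rows))
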