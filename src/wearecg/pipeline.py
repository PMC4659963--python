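"""End-to-end monitoring pipeline.

signal -> beats -> five-minute HRV windows -> normality gate ->
transmission log + compiled pattern-matcher actions + a daily-efficiency
projection.  The pipeline has no hidden state: each stage output equals
the corresponding module function applied to the previous stage's output,
and errors propagate wrapped with the failing stage's name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DomainError, EcgSignal, StageError
from .hrv import HrvFeatures, hrv_features
from .qrs import DetectorConfig, MorphologyBounds, run_detector
from .rfsm import DOMAIN_MAX, Matcher, default_disease_patterns
from .transmission import (
    DEFAULT_RULE,
    NormalityRule,
    TransmissionConfig,
    classify_window,
    efficacy,
    simulate_session,
)

__all__ = ["PipelineConfig", "PipelineResult", "HrvWindow", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage configurations in one document.

    ``rfsm_features`` names the HRV features (in order) fed to the pattern
    matcher as its attribute tuple; values are clipped into the matcher's
    [0, 65536] domain.
    """

    detector: DetectorConfig = field(default_factory=DetectorConfig)
    bounds: MorphologyBounds = field(default_factory=MorphologyBounds)
    rule: NormalityRule = field(default_factory=lambda: DEFAULT_RULE)
    transmission: TransmissionConfig = field(default_factory=TransmissionConfig)
    patterns: list = field(default_factory=default_disease_patterns)
    rfsm_features: tuple = ("avnn", "sdnn", "rmssd")
    allow_partial_window: bool = False
    seed: int = 0


@dataclass
class HrvWindow:
    """One analysis window: index, verdict, features, interval count."""

    index: int
    start_s: float
    features: HrvFeatures
    verdict: str  # 'normal' | 'abnormal'
    n_intervals: int


@dataclass
class PipelineResult:
    beats: list
    state_trace: list
    hrv_windows: list
    transmission_log: object
    rfsm_actions: list  # per window: tuple of actions
    summary: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("detector")
def _detect(signal: EcgSignal, config: PipelineConfig):
    if len(signal) == 0:
        raise DomainError("empty signal")
    return run_detector(signal, config.detector, config.bounds)


@_stage("hrv")
def _windows(detection, signal: EcgSignal, config: PipelineConfig):
    poll = config.transmission.poll_interval_s
    n_windows = int(signal.duration // poll)
    remainder = signal.duration - n_windows * poll
    if n_windows == 0 and not config.allow_partial_window:
        raise DomainError(
            f"signal shorter than one poll interval ({poll} s); "
            "enable allow_partial_window to analyse it"
        )
    if remainder > 0 and config.allow_partial_window:
        n_windows += 1

    valid = [b for b in detection.beats if b.valid]
    r_times = np.asarray([b.r_index for b in valid], dtype=float) / signal.fs
    rr_ms = np.diff(r_times) * 1000.0
    # an interval belongs to the window containing its ending beat
    ends = r_times[1:]

    windows = []
    for k in range(n_windows):
        lo, hi = k * poll, (k + 1) * poll
        w_rr = rr_ms[(ends >= lo) & (ends < hi)]
        if len(w_rr) >= 2:
            feats = hrv_features(w_rr)
        else:
            # no usable rhythm: all-zero placeholder features, which any
            # lower-bound rule classifies abnormal (raw data is exactly
            # what a clinician wants to see for such a window)
            feats = HrvFeatures(avnn=0.0, sdnn=0.0, rmssd=0.0, pnn50=0.0)
        verdict = classify_window(feats, config.rule)
        windows.append(
            HrvWindow(index=k, start_s=lo, features=feats, verdict=verdict,
                      n_intervals=len(w_rr))
        )
    return windows


@_stage("transmission")
def _transmit(windows, config: PipelineConfig):
    # classify_window is deterministic, so replaying the session from the
    # window features cannot disagree with the verdicts already stored
    return simulate_session(
        [w.features for w in windows], config.rule, config.transmission
    )


@_stage("rfsm")
def _match_windows(windows, config: PipelineConfig):
    matcher = Matcher(config.patterns)
    actions = []
    for w in windows:
        values = tuple(
            float(np.clip(getattr(w.features, name), 0.0, DOMAIN_MAX))
            for name in config.rfsm_features
        )
        actions.append(matcher.match(values).actions)
    return actions


def run_pipeline(signal: EcgSignal, config: PipelineConfig | None = None) -> PipelineResult:
    """Run detection, HRV windowing, the transmission gate and the pattern
    matcher over one record; summarize realized normal ratio and the
    projected 24-hour transmission efficiency."""
    if config is None:
        config = PipelineConfig()
    detection = _detect(signal, config)
    windows = _windows(detection, signal, config)
    log = _transmit(windows, config)
    actions = _match_windows(windows, config)

    n_normal = sum(1 for w in windows if w.verdict == "normal")
    normal_ratio = n_normal / len(windows) if windows else 0.0
    summary = {
        "n_beats": len(detection.beats),
        "n_valid_beats": len(detection.valid_beats),
        "n_windows": len(windows),
        "normal_ratio": normal_ratio,
        "final_state": detection.final_state.value,
        "session_bytes": log.total_bytes,
        "projected_24h": efficacy(normal_ratio, config.transmission),
    }
    return PipelineResult(
        beats=detection.beats,
        state_trace=detection.state_trace,
        hrv_windows=windows,
        transmission_log=log,
        rfsm_actions=actions,
        summary=summary,
    )
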