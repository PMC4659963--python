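"""Ambulatory QRS detection.

The pipeline enhances QRS complexes with a causal low-pass filter followed
by a windowed curve length transform (LT),

    LT(w, i) = sum_{k=i-w_s+1..i} sqrt(c + dy_k^2),   dy_k = x[k] - x[k-1],

whose local maxima mark candidate beats.  A four-state controller
(Initial / Idle / Learning / Detection) gates detection: the detector only
commits to a signal after seeing more than a minimum number of likely beats
inside a learning window, from which it also estimates the LT baseline.
Each candidate is then located precisely (Q/R/S fiducial points) and
validated against morphology bounds — QRS width, QRS height, the Q–S
amplitude difference, and the RR interval to the previous accepted beat.
Candidates failing any bound are kept as annotated artifacts; a run of
consecutive artifacts drops the detector back to Idle and raises a
notification (in a garment, the cue to re-seat the electrodes).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import (
    Beat,
    DomainError,
    EcgSignal,
    EdgeError,
    FiducialPoint,
    FiducialTriplet,
    LtSignal,
)

__all__ = [
    "DetectorConfig",
    "DetectorState",
    "MorphologyBounds",
    "DetectionResult",
    "lowpass_filter",
    "length_transform",
    "detect_candidates",
    "locate_fiducials",
    "morphology_validate",
    "run_detector",
]


class DetectorState(enum.Enum):
    INITIAL = "Initial"
    IDLE = "Idle"
    LEARNING = "Learning"
    DETECTION = "Detection"


#: The only admissible state transitions of the detection controller.
ALLOWED_TRANSITIONS = frozenset(
    {
        (DetectorState.INITIAL, DetectorState.IDLE),
        (DetectorState.INITIAL, DetectorState.LEARNING),
        (DetectorState.IDLE, DetectorState.LEARNING),
        (DetectorState.LEARNING, DetectorState.DETECTION),
        (DetectorState.LEARNING, DetectorState.IDLE),
        (DetectorState.DETECTION, DetectorState.IDLE),
    }
)


@dataclass
class MorphologyBounds:
    """Acceptance ranges (min, max) for the beat morphology indicators.

    Defaults: QRS width 40–160 ms, QRS height 0.05–1.5 mV, Q horizontal
    0–1.5 mV, RR interval 250–1500 ms.  A beat is accepted only if every
    indicator lies inside its inclusive range.
    """

    qrs_width_ms: tuple = (40.0, 160.0)
    qrs_height_mv: tuple = (0.05, 1.5)
    q_horizontal_mv: tuple = (0.0, 1.5)
    rr_interval_ms: tuple = (250.0, 1500.0)

    def __post_init__(self) -> None:
        for name in ("qrs_width_ms", "qrs_height_mv", "q_horizontal_mv", "rr_interval_ms"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise DomainError(f"{name}: min must be below max, got ({lo}, {hi})")


@dataclass
class DetectorConfig:
    """Tunables of the ambulatory detector.

    window_w
        Curve-length window in seconds, ~ the QRS duration (default 0.13 s).
    lowpass_cutoff
        Cutoff of the causal 2nd-order Butterworth pre-filter, Hz.
    learning_window
        Length of the learning phase in seconds.
    learning_min_events
        The learning phase succeeds only with strictly MORE than this many
        candidate events inside the learning window.
    max_consecutive_artifacts
        This many invalid beats in a row aborts Detection back to Idle.
    candidate_threshold_fraction
        Adaptive threshold: baseline + fraction * (running max - baseline).
    refractory_ms
        Minimum candidate spacing, tied to the RR lower bound.
    """

    window_w: float = 0.13
    lowpass_cutoff: float = 16.0
    learning_window: float = 10.0
    learning_min_events: int = 5
    max_consecutive_artifacts: int = 5
    candidate_threshold_fraction: float = 0.3
    refractory_ms: float = 250.0

    def __post_init__(self) -> None:
        if min(
            self.window_w,
            self.lowpass_cutoff,
            self.learning_window,
            self.max_consecutive_artifacts,
            self.candidate_threshold_fraction,
            self.refractory_ms,
        ) <= 0:
            raise DomainError("all detector parameters must be positive")
        if self.learning_min_events < 1:
            raise DomainError("learning_min_events must be >= 1")


@dataclass
class DetectionResult:
    """Output of :func:`run_detector`."""

    beats: list
    state_trace: list  # [(time_s, DetectorState), ...]
    notifications: list = field(default_factory=list)

    @property
    def valid_beats(self) -> list:
        return [b for b in self.beats if b.valid]

    @property
    def final_state(self) -> DetectorState:
        return self.state_trace[-1][1]

    def __iter__(self):
        # allows `beats, trace = run_detector(...)`
        return iter((self.beats, self.state_trace))


def lowpass_filter(signal: EcgSignal, cutoff: float) -> EcgSignal:
    """Causal 2nd-order Butterworth low-pass with unit DC gain."""
    if not 0 < cutoff < signal.fs / 2:
        raise DomainError(
            f"cutoff must lie in (0, fs/2) = (0, {signal.fs / 2}), got {cutoff}"
        )
    b, a = sps.butter(2, cutoff, btype="low", fs=signal.fs)
    filtered = sps.lfilter(b, a, signal.samples)
    return EcgSignal(samples=filtered, fs=signal.fs, t0=signal.t0)


def length_transform(
    signal: EcgSignal, window_w: float = 0.13, scale_c: float | None = None
) -> LtSignal:
    """Windowed curve length transform.

    ``values[i] = sum over k in [i-w_s+1, i] of sqrt(scale_c + dy_k^2)``
    with ``dy_k = samples[k] - samples[k-1]`` and ``w_s = round(window_w*fs)``.
    Leading indices with an incomplete window carry the partial sum.  The
    scale constant defaults to ``(1/fs)^2``, i.e. the squared sampling
    period of the textbook arc-length form; it is exposed because the
    nonlinear scaling of the transform is a free design choice.
    """
    w_s = int(round(window_w * signal.fs))
    if w_s < 2:
        raise DomainError(f"window_w*fs must be >= 2, got {window_w * signal.fs:.3f}")
    n = len(signal)
    if n < w_s:
        raise DomainError(f"signal ({n} samples) shorter than window ({w_s} samples)")
    if scale_c is None:
        scale_c = (1.0 / signal.fs) ** 2
    if scale_c < 0:
        raise DomainError("scale_c must be nonnegative")

    dy = np.diff(signal.samples)
    terms = np.sqrt(scale_c + dy * dy)
    # cs[j] = sum of terms for k = 1..j  (term index k-1 corresponds to dy_k)
    cs = np.zeros(n)
    cs[1:] = np.cumsum(terms)
    idx = np.arange(n)
    lo = np.maximum(0, idx - w_s)
    values = cs[idx] - cs[lo]
    return LtSignal(values=values, window_w=window_w, fs=signal.fs)


def detect_candidates(
    lt: LtSignal, config: DetectorConfig, baseline: float,
    initial_max: float | None = None,
) -> list[int]:
    """Local LT maxima above an adaptive threshold, refractory-filtered.

    The threshold at sample i is ``baseline + f*(running_max_i - baseline)``
    where the running maximum accumulates from the start of ``lt`` (seeded
    with ``initial_max`` when the caller has already seen signal, e.g. the
    learning window).  Of two maxima closer than the refractory period, the
    larger survives.
    """
    if baseline < 0:
        raise DomainError("baseline must be nonnegative")
    values = lt.values
    if len(values) < 3:
        return []
    running_max = np.maximum.accumulate(values)
    if initial_max is not None:
        running_max = np.maximum(running_max, initial_max)
    threshold = baseline + config.candidate_threshold_fraction * (running_max - baseline)
    peaks, _ = sps.find_peaks(values)
    peaks = peaks[values[peaks] > threshold[peaks]]

    refr = int(round(config.refractory_ms / 1000.0 * lt.fs))
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < refr:
            if values[p] > values[kept[-1]]:
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    return kept


def locate_fiducials(
    signal: EcgSignal, candidate: int, window_w: float = 0.13
) -> FiducialTriplet:
    """Locate the Q/R/S landmarks of the beat around an LT candidate.

    R is the extremum of |amplitude - local baseline| within one LT window
    of the candidate (the LT peak lags the R wave by up to the window
    length, so the search spans ``candidate +/- w_s``).  Q and S are the
    nearest turning points (slope sign changes) walking left and right from
    R.  Polarity-agnostic: an inverted QRS yields r_point.y below baseline
    with the triplet still ordered q.x < s.x.
    """
    w_s = int(round(window_w * signal.fs))
    lo, hi = candidate - w_s, candidate + w_s  # inclusive bounds
    if lo < 0 or hi >= len(signal):
        raise EdgeError(
            f"candidate {candidate} within {w_s} samples of the signal edge"
        )
    x = signal.samples
    region = x[lo : hi + 1]
    local_baseline = float(np.median(region))
    r = lo + int(np.argmax(np.abs(region - local_baseline)))
    sgn = 1.0 if x[r] >= local_baseline else -1.0
    dev = sgn * (x - local_baseline)

    # Q/S are the opposite-polarity extrema flanking R.  A sample-by-sample
    # slope walk is noise-fragile (any wiggle halts it at R's shoulder), so
    # instead take, on each side, the index nearest R that comes within a
    # small tolerance of that side's minimum of the polarity-corrected
    # signal: on smooth beats this is the turning point, under noise it
    # stays inside the Q/S trough.
    rel_tol = 0.02

    def _nearest_trough(side: np.ndarray, offset: int, pick_last: bool) -> int | None:
        if len(side) == 0:
            return None
        m = float(np.min(side))
        if dev[r] - m <= 0:
            return None  # plateau: no trough to find
        eligible = np.flatnonzero(side <= m + rel_tol * (dev[r] - m) + 1e-15)
        idx = eligible[-1] if pick_last else eligible[0]
        return offset + int(idx)

    q = _nearest_trough(dev[max(0, r - w_s) : r], max(0, r - w_s), pick_last=True)
    s_off = r + 1
    s = _nearest_trough(dev[s_off : min(len(x), r + w_s + 1)], s_off, pick_last=False)
    if q is None:  # degenerate flat flank; force a 1-sample spread
        q = r - 1
    if s is None:
        s = r + 1
    return FiducialTriplet(
        q_point=FiducialPoint(x=int(q), y=float(x[q])),
        r_point=FiducialPoint(x=int(r), y=float(x[r])),
        s_point=FiducialPoint(x=int(s), y=float(x[s])),
    )


#: names of the morphology indicators, in reporting order
INDICATORS = ("qrs_width", "qrs_height", "q_horizontal", "rr_interval", "r_peak")


def morphology_validate(
    triplet: FiducialTriplet,
    prev_r_index: int | None,
    fs: float,
    bounds: MorphologyBounds | None = None,
) -> Beat:
    """Validate one beat against the morphology bounds.

    Indicators: QRS width |X_S - X_Q| / fs, QRS height |Y_R - Y_S|,
    Q horizontal |Y_Q - Y_S|, RR interval |R_i - R_{i-1}| / fs (skipped when
    there is no previous beat), plus the structural requirement that the R
    peak lies strictly inside (X_Q, X_S).  Always returns a Beat; the
    verdict and the list of violated indicators are on the Beat itself.
    """
    if bounds is None:
        bounds = MorphologyBounds()
    q, r, s = triplet.q_point, triplet.r_point, triplet.s_point
    reasons: list[str] = []

    width_ms = abs(s.x - q.x) / fs * 1000.0
    if not bounds.qrs_width_ms[0] <= width_ms <= bounds.qrs_width_ms[1]:
        reasons.append("qrs_width")

    height_mv = abs(r.y - s.y)
    if not bounds.qrs_height_mv[0] <= height_mv <= bounds.qrs_height_mv[1]:
        reasons.append("qrs_height")

    q_horiz_mv = abs(q.y - s.y)
    if not bounds.q_horizontal_mv[0] <= q_horiz_mv <= bounds.q_horizontal_mv[1]:
        reasons.append("q_horizontal")

    if prev_r_index is not None:
        rr_ms = abs(r.x - prev_r_index) / fs * 1000.0
        if not bounds.rr_interval_ms[0] <= rr_ms <= bounds.rr_interval_ms[1]:
            reasons.append("rr_interval")

    if not (q.x < r.x < s.x):
        reasons.append("r_peak")

    return Beat(
        r_index=r.x,
        fiducials=triplet,
        valid=len(reasons) == 0,
        rejection_reasons=reasons,
    )


def _candidates_from(
    lt: LtSignal,
    config: DetectorConfig,
    baseline: float,
    start: int,
    initial_max: float | None = None,
) -> list[int]:
    """Candidates in lt[start:], indices in the full-signal frame."""
    sub = LtSignal(values=lt.values[start:], window_w=lt.window_w, fs=lt.fs)
    return [start + c for c in detect_candidates(sub, config, baseline, initial_max)]


def run_detector(
    signal: EcgSignal,
    config: DetectorConfig | None = None,
    bounds: MorphologyBounds | None = None,
) -> DetectionResult:
    """Run the four-state ambulatory detector over a full record.

    Controller logic:

    * Initial: look for a likely QRS (bootstrap threshold with baseline 0).
      None in the whole record -> Idle, done.  Otherwise -> Learning.
    * Learning: count candidates in the learning window.  Strictly more
      than ``learning_min_events`` -> compute the LT baseline (median over
      the window) and -> Detection; otherwise -> Idle and keep scanning.
    * Detection: re-scan from the start of the learning window with the
      learned baseline (so warm-up beats are not lost), locate fiducials
      and validate morphology for each candidate.  A run of
      ``max_consecutive_artifacts`` invalid beats -> Idle plus a
      notification, then the controller may re-learn on later signal.
    """
    if config is None:
        config = DetectorConfig()
    if bounds is None:
        bounds = MorphologyBounds()
    if len(signal) == 0:
        raise DomainError("empty signal")

    filtered = lowpass_filter(signal, config.lowpass_cutoff)
    lt = length_transform(filtered, config.window_w)
    fs = signal.fs
    n = len(signal)

    state = DetectorState.INITIAL
    trace: list[tuple[float, DetectorState]] = [(signal.t0, state)]
    beats: list[Beat] = []
    notifications: list[tuple[float, str]] = []
    # RR is measured between successive detected R positions (valid or
    # not): anchoring on the last VALID beat would turn one rejection into
    # a cascade of out-of-range RR intervals for every later beat.
    prev_r: int | None = None
    refr = max(1, int(round(config.refractory_ms / 1000.0 * fs)))
    learn_len = int(round(config.learning_window * fs))

    def goto(new_state: DetectorState, at_sample: int) -> None:
        nonlocal state
        trace.append((signal.time_at(min(at_sample, n - 1)), new_state))
        state = new_state

    cursor = 0
    while cursor < n:
        bootstrap = _candidates_from(lt, config, 0.0, cursor)
        if not bootstrap:
            if state is not DetectorState.IDLE:
                goto(DetectorState.IDLE, n - 1)
            break
        c0 = bootstrap[0]
        goto(DetectorState.LEARNING, c0)
        learn_end = min(c0 + learn_len, n)
        in_window = [c for c in bootstrap if c < learn_end]
        if len(in_window) <= config.learning_min_events:
            goto(DetectorState.IDLE, learn_end - 1)
            cursor = learn_end
            continue

        baseline = float(np.median(lt.values[c0:learn_end]))
        learned_max = float(np.max(lt.values[c0:learn_end]))
        goto(DetectorState.DETECTION, learn_end - 1)
        consecutive = 0
        aborted_at: int | None = None
        det_start = max(cursor, c0 - refr)
        for c in _candidates_from(lt, config, baseline, det_start, learned_max):
            try:
                triplet = locate_fiducials(signal, c, config.window_w)
            except EdgeError:
                continue
            beat = morphology_validate(triplet, prev_r, fs, bounds)
            beats.append(beat)
            prev_r = beat.r_index
            if beat.valid:
                consecutive = 0
            else:
                consecutive += 1
                if consecutive >= config.max_consecutive_artifacts:
                    notifications.append(
                        (signal.time_at(c), "consecutive artifacts: adjust electrodes")
                    )
                    goto(DetectorState.IDLE, c)
                    aborted_at = c
                    break
        if aborted_at is None:
            break
        cursor = aborted_at + refr

    beats.sort(key=lambda b: b.r_index)
    return DetectionResult(beats=beats, state_trace=trace, notifications=notifications)
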