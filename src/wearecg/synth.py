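"""Synthetic fixtures with exact ground truth.

Three generators, all pure functions of (parameters, seed):

* clean lead-II-like ECG built from Gaussian bumps (P/Q/R/S/T) at a set
  heart rate, with optional Gaussian noise, sinusoidal baseline wander,
  RR jitter, and injectable artifacts (spikes, dropouts, EMG bursts);
* RR-interval series with controlled mean/variability (truncated Gaussian);
* labeled attribute-tuple streams with an exact normal/abnormal mix for
  the pattern matcher and the transmission gate.

The beat template is deliberately NOT a physiological dynamical model: a
Gaussian mixture is enough to exercise every morphology bound and makes
the ground truth (R indices, Q/S offsets) exact by construction.

A single global seed fans out to sub-streams by fixed offsets (timing +0,
noise +1, wander +2, artifacts +3, tuples +4) so regenerating one stream
never perturbs the others.  All derived seeds stay below 2**31.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DomainError, EcgSignal, FiducialPoint, FiducialTriplet, GenerationError
from .hrv import RrSeries
from .rfsm import DOMAIN_MAX, AttributeRange, derive_alphabet

__all__ = [
    "BeatTemplate",
    "GeneratedRecord",
    "LabeledTuple",
    "generate_ecg",
    "inject_artifacts",
    "generate_rr_series",
    "generate_attribute_tuples",
]

_SEED_MOD = 2**31 - 1


def _stream_seed(seed: int, offset: int) -> int:
    return (int(seed) + offset) % _SEED_MOD


@dataclass(frozen=True)
class BeatTemplate:
    """Gaussian-bump beat morphology.

    ``components`` are (center offset ms relative to R, sigma ms,
    amplitude mV).  ``qrs_onset_ms``/``qrs_offset_ms`` record where an
    ideal fiducial locator lands: the Q and S extrema offsets.
    """

    components: tuple = (
        (-180.0, 25.0, 0.15),  # P
        (-25.0, 6.0, -0.10),   # Q
        (0.0, 10.0, 1.00),     # R
        (25.0, 6.0, -0.20),    # S
        (280.0, 50.0, 0.30),   # T
    )
    qrs_onset_ms: float = -25.0
    qrs_offset_ms: float = 25.0

    def __post_init__(self) -> None:
        amps = [abs(a) for _, _, a in self.components]
        r_amp = max(abs(a) for off, _, a in self.components if off == 0.0)
        if r_amp < max(amps):
            raise DomainError("R amplitude must dominate the template")
        if not self.qrs_onset_ms < 0 < self.qrs_offset_ms:
            raise DomainError("QRS onset/offset must bracket the R center")

    @property
    def r_amplitude(self) -> float:
        return max(a for off, _, a in self.components if off == 0.0)

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """Template voltage at offsets ``t_ms`` (ms relative to R center)."""
        y = np.zeros_like(t_ms, dtype=float)
        for center, sigma, amp in self.components:
            y += amp * np.exp(-0.5 * ((t_ms - center) / sigma) ** 2)
        return y


@dataclass
class GeneratedRecord:
    """A synthetic record together with its exact ground truth."""

    signal: EcgSignal
    true_r_indices: np.ndarray
    true_fiducials: list
    injected_artifacts: list = field(default_factory=list)  # (sample index, kind)

    @property
    def fs(self) -> float:
        return self.signal.fs


def generate_ecg(
    bpm: float,
    duration: float,
    fs: float = 1000.0,
    template: BeatTemplate | None = None,
    noise_sd: float = 0.0,
    baseline_wander: tuple = (0.0, 0.0),  # (amplitude mV, frequency Hz)
    rr_jitter_sd_ms: float = 0.0,
    seed: int = 0,
) -> GeneratedRecord:
    """Synthesize a single-lead ECG with known beat positions.

    Beats are laid down at a nominal spacing of 60/bpm seconds starting
    0.5 s into the record (plus optional per-beat Gaussian jitter), each a
    copy of the Gaussian-bump template.  Deterministic for a fixed seed;
    with zero noise/wander/jitter the samples equal the template sum
    exactly and the R indices are exact.
    """
    if not 20 <= bpm <= 240:
        raise DomainError(f"bpm must lie in [20, 240], got {bpm}")
    if fs < 100:
        raise DomainError(f"fs must be >= 100 Hz, got {fs}")
    if duration <= 0 or noise_sd < 0 or rr_jitter_sd_ms < 0:
        raise DomainError("duration must be positive, noise/jitter nonnegative")
    if template is None:
        template = BeatTemplate()

    n = int(round(duration * fs))
    t_ms = np.arange(n) / fs * 1000.0

    timing_rng = np.random.default_rng(_stream_seed(seed, 0))
    rr_s = 60.0 / bpm
    margin = 0.5  # keep full T waves inside the record
    beat_times = []
    t = 0.5
    while t < duration - margin:
        beat_times.append(t)
        step = rr_s
        if rr_jitter_sd_ms > 0:
            step += timing_rng.normal(0.0, rr_jitter_sd_ms / 1000.0)
        t += max(step, 0.3)  # never collapse beats onto each other

    samples = np.zeros(n)
    r_indices = []
    fiducials = []
    support_ms = 1000.0  # per-beat template support; tails beyond are < 1e-9 mV
    for bt in beat_times:
        r_idx = int(round(bt * fs))
        r_indices.append(r_idx)
        lo = max(0, int(round((bt - support_ms / 1000.0) * fs)))
        hi = min(n, int(round((bt + support_ms / 1000.0) * fs)))
        samples[lo:hi] += template.evaluate(t_ms[lo:hi] - bt * 1000.0)
        q_idx = r_idx + int(round(template.qrs_onset_ms / 1000.0 * fs))
        s_idx = r_idx + int(round(template.qrs_offset_ms / 1000.0 * fs))
        fiducials.append(
            FiducialTriplet(
                q_point=FiducialPoint(q_idx, float(template.evaluate(np.array([template.qrs_onset_ms]))[0])),
                r_point=FiducialPoint(r_idx, float(template.r_amplitude)),
                s_point=FiducialPoint(s_idx, float(template.evaluate(np.array([template.qrs_offset_ms]))[0])),
            )
        )

    amp_w, freq_w = baseline_wander
    if amp_w and freq_w:
        wander_rng = np.random.default_rng(_stream_seed(seed, 2))
        phase = wander_rng.uniform(0.0, 2.0 * np.pi)
        samples += amp_w * np.sin(2.0 * np.pi * freq_w * np.arange(n) / fs + phase)
    if noise_sd > 0:
        noise_rng = np.random.default_rng(_stream_seed(seed, 1))
        samples += noise_rng.normal(0.0, noise_sd, n)

    return GeneratedRecord(
        signal=EcgSignal(samples=samples, fs=fs),
        true_r_indices=np.asarray(r_indices, dtype=int),
        true_fiducials=fiducials,
    )


def inject_artifacts(
    record: GeneratedRecord, kind: str = "spike", rate_per_min: float = 6.0, seed: int = 0
) -> GeneratedRecord:
    """Superimpose motion-like artifacts, keeping truth lists updated.

    * ``spike``: 20 ms triangular pulse of 2.0 mV — violates both the QRS
      width minimum and the height maximum by construction;
    * ``dropout``: 200 ms of flatline (electrode loss);
    * ``emg``: 300 ms burst of broadband muscle noise (0.3 mV sd).

    Event sites are drawn at least 150 ms away from every true beat.
    """
    if rate_per_min < 0:
        raise DomainError("rate must be nonnegative")
    if kind not in ("spike", "dropout", "emg"):
        raise DomainError(f"unknown artifact kind {kind!r}")
    if rate_per_min == 0:
        return record

    fs = record.fs
    n = len(record.signal)
    duration_min = n / fs / 60.0
    n_events = int(round(rate_per_min * duration_min))
    rng = np.random.default_rng(_stream_seed(seed, 3))
    guard = int(round(0.15 * fs))
    edge = int(round(0.3 * fs))

    samples = record.signal.samples.copy()
    sites: list[int] = []
    attempts = 0
    while len(sites) < n_events and attempts < 200 * max(n_events, 1):
        attempts += 1
        c = int(rng.integers(edge, n - edge))
        if np.all(np.abs(record.true_r_indices - c) >= guard) and all(
            abs(c - s) >= guard for s in sites
        ):
            sites.append(c)
    sites.sort()

    for c in sites:
        if kind == "spike":
            half = max(1, int(round(0.010 * fs)))  # 20 ms base width
            ramp = 2.0 * (1.0 - np.abs(np.arange(-half, half + 1)) / half)
            samples[c - half : c + half + 1] += ramp
        elif kind == "dropout":
            half = int(round(0.1 * fs))
            samples[c - half : c + half] = 0.0
        else:  # emg
            half = int(round(0.15 * fs))
            burst = rng.normal(0.0, 0.3, 2 * half)
            samples[c - half : c + half] += burst

    return GeneratedRecord(
        signal=EcgSignal(samples=samples, fs=fs, t0=record.signal.t0),
        true_r_indices=record.true_r_indices.copy(),
        true_fiducials=list(record.true_fiducials),
        injected_artifacts=record.injected_artifacts + [(c, kind) for c in sites],
    )


def generate_rr_series(
    mean_ms: float, sd_ms: float, n: int, seed: int = 0, window_label: str = ""
) -> RrSeries:
    """I.i.d. Gaussian RR intervals, truncated to stay positive.

    Requires ``mean > 3*sd >= 0`` so that truncation is a rare event and
    the sample statistics recover (mean, sd) to sampling error.
    """
    if not mean_ms > 3 * sd_ms >= 0:
        raise DomainError(f"need mean > 3*sd >= 0, got mean={mean_ms}, sd={sd_ms}")
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(_stream_seed(seed, 0))
    intervals = rng.normal(mean_ms, sd_ms, n) if sd_ms > 0 else np.full(n, float(mean_ms))
    intervals = np.maximum(intervals, 1.0)
    return RrSeries(intervals=intervals, window_label=window_label)


@dataclass(frozen=True)
class LabeledTuple:
    """An attribute tuple with its generation label (truth, not a match)."""

    values: tuple
    abnormal: bool


def _sample_in_range(rng: np.random.Generator, r: AttributeRange) -> float:
    if r.wildcard:
        return float(rng.uniform(0.0, DOMAIN_MAX))
    if r.equality is not None:
        return float(r.equality)
    return float(rng.uniform(r.low, r.high))


def generate_attribute_tuples(
    patterns, abnormal_fraction: float, n: int, seed: int = 0
) -> list:
    """Labeled tuples with an exact abnormal count of ``round(fraction*n)``.

    Abnormal tuples are drawn uniformly inside a uniformly chosen pattern's
    range (verified against the pattern set).  Normal tuples are drawn from
    the complement via the discretization map: a non-matching combination
    of elementary pieces is chosen uniformly and the value sampled within
    it — direct rejection sampling over the raw domain is hopeless when a
    broad pattern covers nearly all of it.
    """
    if not 0 <= abnormal_fraction <= 1:
        raise DomainError("abnormal_fraction must lie in [0, 1]")
    if n < 0:
        raise DomainError("n must be nonnegative")
    patterns = list(patterns)
    n_abnormal = int(round(abnormal_fraction * n))
    rng = np.random.default_rng(_stream_seed(seed, 4))

    if n_abnormal > 0 and not patterns:
        raise GenerationError("cannot draw abnormal tuples from an empty pattern set")

    normal_combos: list = []
    dmap = None
    if n - n_abnormal > 0:
        if patterns:
            dmap = derive_alphabet(patterns)
            combos = [()]
            for attr in dmap.attributes:
                combos = [c + (p,) for c in combos for p in dmap.pieces[attr]]
            for combo in combos:
                rep = tuple(p.representative() for p in combo)
                if not any(pat.matches(rep) for pat in patterns):
                    normal_combos.append(combo)
            if not normal_combos:
                raise GenerationError("pattern set covers the whole domain; no normal region")

    labels = np.zeros(n, dtype=bool)
    labels[:n_abnormal] = True
    rng.shuffle(labels)

    out: list[LabeledTuple] = []
    for abnormal in labels:
        if abnormal:
            for _ in range(100):
                pat = patterns[int(rng.integers(len(patterns)))]
                values = tuple(_sample_in_range(rng, r) for r in pat.ranges)
                if pat.matches(values):
                    break
            else:  # pragma: no cover - open-bound resample never exhausts
                raise GenerationError(f"could not sample inside {pat.id}")
            out.append(LabeledTuple(values=values, abnormal=True))
        else:
            if patterns:
                for _ in range(100):
                    combo = normal_combos[int(rng.integers(len(normal_combos)))]
                    values = tuple(
                        p.lo if p.lo == p.hi else float(rng.uniform(p.lo, p.hi))
                        for p in combo
                    )
                    if not any(pat.matches(values) for pat in patterns):
                        break
                else:  # pragma: no cover - open-bound draw never exhausts
                    raise GenerationError("could not sample a normal tuple")
            else:
                values = tuple(float(rng.uniform(0.0, DOMAIN_MAX)) for _ in range(3))
            out.append(LabeledTuple(values=values, abnormal=False))
    return out
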