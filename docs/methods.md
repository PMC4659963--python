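# Methods

This note records the models implemented in `wearecg`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions a user should know before trusting a result.

## Signal model and QRS detection

The detector operates on a uniformly sampled single-lead voltage series in
mV (`EcgSignal`).  Processing is strictly causal, as on a microcontroller:

1. **Low-pass pre-filter.**  Second-order Butterworth, default cutoff
   16 Hz, applied with `scipy.signal.lfilter` (causal, unit DC gain).  The
   cutoff is a free parameter; 16 Hz matches the classic curve-length
   detector family, attenuating T waves and EMG while keeping enough QRS
   slope energy.  Fiducial points and morphology indicators are measured
   on the **raw** signal — the filter's group delay and amplitude smearing
   would otherwise bias Q/S offsets and QRS height.
2. **Curve length transform.**  `LT(w,i) = Σ sqrt(c + Δy²)` over a
   trailing window of w = 0.13 s (≈ QRS duration).  The scale constant c
   defaults to Δt² (the textbook arc-length form) but is exposed: it
   controls how strongly small slopes are nonlinearly suppressed relative
   to large ones.  Leading indices carry the partial sum; every value is
   ≥ (number of summed terms)·sqrt(c).
3. **Candidate picking.**  Local LT maxima above an adaptive threshold
   `baseline + 0.3·(running max − baseline)`; of two maxima within a
   250 ms refractory period the larger survives.  The 0.3 fraction and the
   use of the RR lower bound (250 ms) as refractory are design choices:
   the threshold tracks signal energy without lookahead, and no two true
   beats can be closer than the RR bound the validator enforces anyway.
4. **Four-state controller.**  Initial → Idle when the record contains no
   candidate at all; Initial/Idle → Learning at the first candidate;
   Learning → Detection iff strictly more than 5 candidates fall in the
   10 s learning window (else → Idle), with the LT baseline taken as the
   **median** of LT over that window (robust to the QRS peaks inside it);
   Detection → Idle after 5 consecutive morphology rejections, with a
   user notification.  On entering Detection the learning window is
   re-scanned with the learned baseline so warm-up beats are kept; the
   adaptive threshold's running max is seeded with the learning-window
   maximum so the scan start is not artificially permissive.
5. **Fiducials.**  R is the extremum of |x − local median| within one LT
   window of the candidate (the LT peak trails the R wave).  Q and S are
   the flanking opposite-polarity troughs: on each side of R the index
   nearest R that comes within 2 % (of the R-to-trough excursion) of that
   side's minimum of the polarity-corrected signal.  A naive slope walk
   halts at the first noise wiggle and collapses the measured QRS width;
   the tolerance form is stable under ~0.02 mV noise while agreeing with
   the turning point on smooth beats.  Inverted complexes are handled by
   the polarity correction.
6. **Morphology validation.**  Inclusive bounds, defaults: QRS width
   40–160 ms, QRS height |Y_R−Y_S| 0.05–1.5 mV, "Q horizontal" |Y_Q−Y_S|
   0–1.5 mV (the name is conventional; the quantity is an amplitude
   difference), RR 250–1500 ms, plus X_Q < X_R < X_S.  The RR interval is
   measured between **successive detected R positions** regardless of
   their verdict: anchoring on the last accepted beat would turn a single
   rejection into a cascade (every later RR measuring ≥ 2 true intervals,
   out of range).  Every rejected indicator is listed on the returned
   beat; `valid` iff the list is empty.

Indexing is 0-based, windows trailing/half-open, times in seconds.  The
detector is sampling-rate agnostic; it is tested at 1000 Hz and 128 Hz.

## HRV

SDNN uses the sample (n−1) standard deviation and RMSSD divides the sum
of squared successive differences by n−1 (the number of differences),
matching standard HRV practice.  pNN50 counts differences **strictly**
greater than 50 ms; a difference of exactly 50 ms does not count.  Ectopic
/ artifact exclusion is upstream: HRV consumes only validated beats.
Units are ms throughout (pNN50 in %).

## Transmission model

Defaults: 300 s poll interval, 12-bit samples at a 128 Hz transmission
rate (the on-air stream; the acquisition ADC may run faster), 20-byte
framing field, 32-byte HRV package, 288 windows per day, Mb = 2²⁰ bytes.
One full window is 12·128·300/8 + 20 + 32 = 57 652 bytes.

The 32-byte package layout is defined by this package (the wire format of
the original platform is not published): big-endian, version and flag
bytes, 16-bit beat count, 64-bit window-start epoch, three 32-bit centi-ms
features, 16-bit centi-percent pNN50, 4 reserved bytes, and a 16-bit byte
sum checksum.  Round-trips are lossless at 0.01 ms / 0.01 % resolution.

`efficacy` reports two efficiency figures.  `efficiency_exact` is the
plain byte ratio (best case ≈ 1802).  `efficiency` reproduces the
published-table convention of dividing volumes at printed precision: the
full-day volume is printed with 2 decimals rounded *up* (15.8347 → 15.84,
a conservative cost figure) and the power-saving volume with 2 rounded
decimals ≥ 10 Mb, 3 rounded decimals in [1, 10) and 3 truncated decimals
below 1 Mb (0.00879 → 0.008).  This is the only convention under which
the canonical row {1, 1.25, 2.50, 4.99, 1980} emerges; the 40 % cell
computes to 1.67 under it.  Note the power-saving mode at normal ratio 0
actually costs 288·32 bytes **more** than full transmission (summaries
ride on top of raw data), so "saving ≤ full" holds only at printed
precision; the exact ratio there is 0.9994.

Window classification is a conjunction of per-feature thresholds; a value
exactly at its cutoff is normal, so "abnormal" always means a strict
violation.  The shipped default rule (SDNN ≥ 100 ms) is illustrative.

## Pattern matcher

Attribute domains are [0, 65536]; printed table bounds are strict
inequalities exactly as written, equality patterns are singletons, `*`
is a wildcard.  The discretization is the **coarsest interval partition
such that every pattern range is an exact union of pieces**: fine
partition at all critical points (singletons + open gaps), then adjacent
pieces indistinguishable to every range are merged.  For the shipped
seven-pattern set this yields 9 X-pieces — e.g. (0,3), (3,4], (4,7), {7},
(7,10], (10,65535) plus boundary singletons — and the per-pattern
decompositions have the expected sizes (P1: 1 symbol, P2: 5, P4: 4).  A
coarser six-symbol alphabet that drops the boundary singletons cannot
represent every range exactly and is not used.

Compilation is subset construction specialised to fixed-length strings
(state = set of still-viable patterns at a depth); the result is a total
transition table with an absorbing dead state.  All matching patterns are
reported in pattern order — no precedence is imposed, because overlapping
patterns (P2 ⊂ P3) are legitimate and the action policy belongs to the
caller.  Tests verify the compiled route against two independent oracles:
direct numeric range checks and Python-`re` matching of the regex view.

Reconfiguration is a full rebuild (alphabet re-derived); determinism of
compilation makes before/after comparison on unaffected tuples exact.
The table exports to flat JSON — the analogue of the downloadable flash
image of a deployed gateway.

## Synthetic data

`generate_ecg` sums Gaussian bumps per beat: P(−180 ms, σ25, 0.15 mV),
Q(−25, σ6, −0.10), R(0, σ10, 1.00), S(+25, σ6, −0.20), T(+280, σ50,
0.30), at nominal spacing 60/bpm s starting 0.5 s into the record,
optional i.i.d. Gaussian noise, sinusoidal baseline wander, and per-beat
RR jitter.  Ground truth (R indices, Q/S extremum offsets) is recorded
exactly.  This emulates a clean lead-II morphology well enough to
exercise every morphology bound and the full state machine; it does
**not** emulate arrhythmia, ectopy, PQRST morphology variation, or
realistic colored noise — so a green detection test establishes correct
mechanics and clean-signal accuracy, not clinical performance on
pathological rhythms.  Artifact injection (20 ms / 2 mV spikes violating
the bounds by construction, dropouts, EMG bursts) is placed ≥ 150 ms from
true beats.

RR series are i.i.d. truncated Gaussians (`mean > 3·sd` enforced, so
truncation is negligible).  Attribute-tuple streams allocate exactly
`round(fraction·n)` abnormal tuples; abnormal tuples are drawn uniformly
inside a uniformly chosen pattern's range, normal ones by sampling a
uniformly chosen non-matching piece combination of the discretization map
(uniform rejection over the raw domain is infeasible: one broad pattern
covers ≈ 99.97 % of it).  Normal combos are chosen uniformly by combo,
not by volume — adequate for exercising the matcher, not a uniform draw
from the complement.

All generators are pure functions of (parameters, seed); one global seed
fans out to per-stream seeds by fixed offsets.

## Scoring

Beat-by-beat comparison uses a ±150 ms window (the conventional
beat-matching tolerance) and leftmost-feasible greedy pairing over the
two sorted lists, which attains maximum matching cardinality for
translate windows (nearest-first greedy does not; equidistant ties resolve
to the earlier detection).  HRV accuracy is the relative-error complement
100·(1 − |est−ref|/ref), clipped at 0, undefined (flagged) for a zero
reference.

## Pipeline

`run_pipeline` composes detection, five-minute HRV windowing (an RR
interval belongs to the window containing its ending beat), the normality
gate, the session replay and the pattern matcher; its stage outputs equal
the member functions applied in sequence (tested), and stage failures
carry the stage name.  Windows with fewer than two RR intervals get
all-zero placeholder features, which any lower-bound rule classifies
abnormal — a window without usable rhythm is precisely one whose raw data
should be uploaded.  The matcher consumes (AVNN, SDNN, RMSSD) clipped to
the attribute domain by default; the mapping is configurable.

## Known limitations

* No WFDB/physiological-database path: evaluation is synthetic-only in
  this build (the I/O layer is CSV/JSON).
* Single lead; no P/T delineation, no frequency-domain or nonlinear HRV.
* The transmission model accounts bytes, not joules; no loss or
  retransmission modeling.  The 65 536-byte raw framing constant is
  carried in the config but the session simulator transmits exact payload
  sizes rather than padded frames.
* The DFA is rebuilt from scratch on reconfiguration; incremental update
  is out of scope.
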