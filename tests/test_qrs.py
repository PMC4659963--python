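"""QRS pipeline: filtering, curve length transform, fiducials, morphology,
and the four-state detector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearecg import (
    DetectorConfig,
    DetectorState,
    DomainError,
    EcgSignal,
    FiducialPoint,
    FiducialTriplet,
    LtSignal,
    MorphologyBounds,
    detect_candidates,
    generate_ecg,
    length_transform,
    locate_fiducials,
    lowpass_filter,
    morphology_validate,
    run_detector,
)
from wearecg.qrs import ALLOWED_TRANSITIONS


def direct_length_transform(samples, fs, window_w, scale_c):
    """Independent double-loop evaluation of the windowed arc length."""
    w_s = int(round(window_w * fs))
    n = len(samples)
    out = np.zeros(n)
    for i in range(n):
        total = 0.0
        for k in range(max(1, i - w_s + 1), i + 1):
            dy = samples[k] - samples[k - 1]
            total += np.sqrt(scale_c + dy * dy)
        out[i] = total
    return out


class TestLowpass:
    def test_dc_gain_unity(self):
        sig = EcgSignal(np.full(2000, 0.7), fs=500)
        out = lowpass_filter(sig, 16.0)
        assert out.samples[-1] == pytest.approx(0.7, rel=1e-6)
        assert len(out) == len(sig) and out.fs == sig.fs

    def test_impulse_response_decays(self):
        x = np.zeros(4000)
        x[0] = 1.0
        out = lowpass_filter(EcgSignal(x, fs=1000), 16.0)
        assert np.all(np.isfinite(out.samples))
        assert np.sum(out.samples**2) < np.inf
        assert np.max(np.abs(out.samples[-100:])) < 1e-6

    def test_stopband_attenuation(self):
        # sine at 5x cutoff attenuated by >= 12 dB in steady state
        fs, cutoff = 1000.0, 16.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 5 * cutoff * t)
        out = lowpass_filter(EcgSignal(x, fs=fs), cutoff)
        steady = out.samples[len(out) // 2 :]
        assert np.max(np.abs(steady)) < 10 ** (-12 / 20)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(DomainError):
            lowpass_filter(EcgSignal(np.zeros(100), fs=100), 60.0)


class TestLengthTransform:
    def test_constant_signal_full_windows(self):
        fs, w = 200.0, 0.1
        w_s = int(round(w * fs))
        sig = EcgSignal(np.full(100, 2.5), fs=fs)
        lt = length_transform(sig, w)  # scale_c defaults to dt^2
        assert np.allclose(lt.values[w_s:], w_s / fs)

    def test_linear_ramp(self):
        a = 0.3  # mV per sample
        sig = EcgSignal(a * np.arange(300), fs=100.0)
        w_s = int(round(0.13 * 100))
        lt = length_transform(sig, 0.13, scale_c=1.0)
        assert np.allclose(lt.values[w_s:], w_s * np.sqrt(1 + a * a))

    def test_gaussian_peak_location(self):
        # LT maximum lies within half a window of the R wave, by the
        # brute-force argmax of the directly summed definition
        fs = 250.0
        t = np.arange(int(2 * fs)) / fs
        r_true = int(1.0 * fs)
        x = np.exp(-0.5 * ((t - 1.0) / 0.01) ** 2)
        lt = length_transform(EcgSignal(x, fs=fs), 0.13)
        direct = direct_length_transform(x, fs, 0.13, (1 / fs) ** 2)
        w_s = int(round(0.13 * fs))
        assert abs(int(np.argmax(direct)) - r_true) <= w_s
        assert abs(int(np.argmax(lt.values)) - int(np.argmax(direct))) <= 1

    def test_matches_direct_summation(self, rng):
        fs = 500.0
        x = rng.normal(0, 0.3, 2000)
        lt = length_transform(EcgSignal(x, fs=fs), 0.13, scale_c=(1 / fs) ** 2)
        direct = direct_length_transform(x, fs, 0.13, (1 / fs) ** 2)
        np.testing.assert_allclose(lt.values, direct, rtol=1e-12, atol=1e-15)

    def test_floor_value(self, rng):
        fs, w = 100.0, 0.1
        x = rng.normal(0, 1, 400)
        lt = length_transform(EcgSignal(x, fs=fs), w, scale_c=4.0)
        w_s = int(round(w * fs))
        assert np.all(lt.values[w_s:] >= w_s * 2.0 - 1e-12)

    def test_monotone_in_increment_magnitude(self, rng):
        # pointwise increase of |dy| can only grow every summand
        fs = 100.0
        x = np.cumsum(rng.normal(0, 0.1, 500))
        small = length_transform(EcgSignal(x, fs=fs), 0.13).values
        big = length_transform(EcgSignal(3 * x, fs=fs), 0.13).values
        assert np.all(big >= small - 1e-15)

    def test_window_longer_than_signal(self):
        with pytest.raises(DomainError):
            length_transform(EcgSignal(np.zeros(10), fs=100.0), 0.5)


class TestCandidates:
    def _lt(self, values, fs=1000.0):
        return LtSignal(values=np.asarray(values, float), window_w=0.13, fs=fs)

    def test_flat_lt_no_candidates(self):
        cfg = DetectorConfig()
        assert detect_candidates(self._lt(np.ones(1000)), cfg, 0.0) == []

    def test_two_peaks_clear_refractory(self):
        v = np.zeros(1000)
        v[300], v[700] = 5.0, 5.0  # 400 ms apart at 1 kHz
        cands = detect_candidates(self._lt(v), DetectorConfig(), 0.0)
        assert cands == [300, 700]

    def test_close_peaks_keep_larger(self):
        v = np.zeros(1000)
        v[300], v[450] = 4.0, 6.0  # 150 ms apart, refractory 250 ms
        cands = detect_candidates(self._lt(v), DetectorConfig(), 0.0)
        assert cands == [450]

    def test_brute_force_suppression_rule(self, rng):
        # enumerate maxima and apply the stated keep-the-larger rule directly
        v = np.abs(rng.normal(0, 1, 3000))
        cfg = DetectorConfig()
        lt = self._lt(v)
        got = detect_candidates(lt, cfg, 0.0)
        run_max = np.maximum.accumulate(v)
        thr = cfg.candidate_threshold_fraction * run_max
        maxima = [
            i for i in range(1, len(v) - 1)
            if v[i - 1] < v[i] and v[i] > v[i + 1] and v[i] > thr[i]
        ]
        refr = int(round(cfg.refractory_ms / 1000 * lt.fs))
        expected = []
        for p in maxima:
            if expected and p - expected[-1] < refr:
                if v[p] > v[expected[-1]]:
                    expected[-1] = p
            else:
                expected.append(p)
        assert got == expected


class TestFiducials:
    def test_symmetric_triangle(self):
        fs = 1000.0
        x = np.zeros(1000)
        c, half = 500, 40
        x[c - half : c + half + 1] = 1.0 - np.abs(np.arange(-half, half + 1)) / half
        trip = locate_fiducials(EcgSignal(x, fs=fs), c, 0.13)
        assert trip.r_point.x == c
        assert c - trip.q_point.x == pytest.approx(trip.s_point.x - c, abs=1)
        assert trip.q_point.x < c < trip.s_point.x

    def test_known_template_onset_offset(self):
        rec = generate_ecg(bpm=60, duration=10, fs=1000, seed=3)
        truth = rec.true_fiducials[3]
        trip = locate_fiducials(rec.signal, truth.r_point.x + 60, 0.13)
        fs = rec.fs
        assert abs(trip.q_point.x - truth.q_point.x) / fs <= 0.020
        assert abs(trip.s_point.x - truth.s_point.x) / fs <= 0.020
        assert abs(trip.r_point.x - truth.r_point.x) <= 2

    def test_inverted_r_wave(self):
        fs = 1000.0
        t = np.arange(2000) / fs
        x = -1.0 * np.exp(-0.5 * ((t - 1.0) / 0.01) ** 2)
        trip = locate_fiducials(EcgSignal(x, fs=fs), 1000, 0.13)
        assert trip.r_point.y < np.median(x)
        assert trip.q_point.x < trip.r_point.x < trip.s_point.x

    def test_edge_candidate_rejected(self):
        sig = EcgSignal(np.zeros(500), fs=1000.0)
        with pytest.raises(DomainError):
            locate_fiducials(sig, 10, 0.13)


def make_triplet(width_ms=100.0, height_mv=1.0, q_horiz_mv=0.3, fs=1000.0, r_inside=True):
    w = int(width_ms / 1000 * fs)
    q_x, s_x = 1000, 1000 + w
    r_x = q_x + w // 2 if r_inside else s_x + 5
    y_s = -0.2
    return FiducialTriplet(
        q_point=FiducialPoint(q_x, y_s + q_horiz_mv),
        r_point=FiducialPoint(r_x, y_s + height_mv),
        s_point=FiducialPoint(s_x, y_s),
    )


class TestMorphology:
    FS = 1000.0

    def test_all_within_bounds(self):
        trip = make_triplet()
        beat = morphology_validate(trip, trip.r_point.x - 800, self.FS)
        assert beat.valid and beat.rejection_reasons == []

    @pytest.mark.parametrize(
        "kwargs,prev_offset,expected",
        [
            ({"width_ms": 30.0}, 800, ["qrs_width"]),
            ({"width_ms": 200.0}, 800, ["qrs_width"]),
            ({"height_mv": 0.01}, 800, ["qrs_height"]),
            ({"height_mv": 2.0}, 800, ["qrs_height"]),
            ({"q_horiz_mv": 1.8}, 800, ["q_horizontal"]),
            ({}, 200, ["rr_interval"]),
            ({}, 1800, ["rr_interval"]),
            ({"height_mv": 2.0}, 200, ["qrs_height", "rr_interval"]),
        ],
    )
    def test_each_bound_triggers_its_reason(self, kwargs, prev_offset, expected):
        trip = make_triplet(**kwargs)
        beat = morphology_validate(trip, trip.r_point.x - prev_offset, self.FS)
        assert not beat.valid
        assert beat.rejection_reasons == expected

    def test_rr_skipped_without_previous_beat(self):
        beat = morphology_validate(make_triplet(), None, self.FS)
        assert beat.valid

    def test_r_outside_qs_rejected(self):
        beat = morphology_validate(make_triplet(r_inside=False), None, self.FS)
        assert "r_peak" in beat.rejection_reasons

    def test_boundary_values_accepted(self):
        # bounds are inclusive: exactly 40 ms wide and exactly 250 ms RR pass
        trip = make_triplet(width_ms=40.0)
        beat = morphology_validate(trip, trip.r_point.x - 250, self.FS)
        assert beat.valid

    @settings(derandomize=True, max_examples=200)
    @given(
        width=st.floats(1.0, 400.0),
        height=st.floats(0.0, 3.0),
        qh=st.floats(0.0, 3.0),
        prev=st.integers(50, 3000),
    )
    def test_valid_iff_no_reasons(self, width, height, qh, prev):
        trip = make_triplet(width_ms=width, height_mv=height, q_horiz_mv=qh)
        beat = morphology_validate(trip, trip.r_point.x - prev, self.FS)
        assert beat.valid == (len(beat.rejection_reasons) == 0)


class TestDetector:
    def test_flatline_goes_idle(self):
        sig = EcgSignal(np.zeros(10_000), fs=1000.0)
        res = run_detector(sig)
        assert res.final_state is DetectorState.IDLE
        assert res.beats == []

    def test_empty_signal_rejected(self):
        with pytest.raises(DomainError):
            run_detector(EcgSignal(np.empty(0), fs=1000.0))

    def test_clean_minute_reaches_detection(self, clean_record, clean_detection):
        res = clean_detection
        assert res.final_state is DetectorState.DETECTION
        assert abs(len(res.beats) - len(clean_record.true_r_indices)) <= 1
        assert all(b.valid for b in res.beats)
        assert [b.r_index for b in res.beats] == sorted(b.r_index for b in res.beats)

    def test_too_few_beats_learning_fails(self):
        # 3 beats in the first 10 s, then flatline: learning must fail
        rec = generate_ecg(bpm=60, duration=10, fs=500, seed=5)
        sig = np.concatenate([rec.signal.samples[: 4 * 500], np.zeros(60 * 500)])
        res = run_detector(EcgSignal(sig, fs=500.0))
        assert res.final_state is DetectorState.IDLE
        states = [s for _, s in res.state_trace]
        assert DetectorState.DETECTION not in states

    def test_state_trace_uses_only_allowed_edges(self, clean_detection):
        states = [s for _, s in clean_detection.state_trace]
        for a, b in zip(states, states[1:]):
            assert (a, b) in ALLOWED_TRANSITIONS

    def test_trace_edges_on_artifact_heavy_signal(self):
        # noise burst after clean ECG exercises Detection -> Idle -> relearn
        rng = np.random.default_rng(11)
        rec = generate_ecg(bpm=60, duration=30, fs=500, seed=9)
        noisy = np.concatenate(
            [rec.signal.samples, rng.normal(0, 2.0, 20 * 500), rec.signal.samples]
        )
        res = run_detector(EcgSignal(noisy, fs=500.0))
        states = [s for _, s in res.state_trace]
        for a, b in zip(states, states[1:]):
            assert (a, b) in ALLOWED_TRANSITIONS

    def test_rate_agnostic_at_128hz(self):
        rec = generate_ecg(bpm=80, duration=60, fs=128, seed=13)
        res = run_detector(rec.signal)
        assert res.final_state is DetectorState.DETECTION
        assert abs(len(res.valid_beats) - len(rec.true_r_indices)) <= 1
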