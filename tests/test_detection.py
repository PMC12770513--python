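"""SVM computation, filtering, envelope extraction and burst detection."""

import numpy as np
import pytest

from noctomap.detection import (DetectionMetrics, SvmSeries, bandpass,
                                compute_svm, detect_bursts, extract_envelopes,
                                match_and_score, mean_f1_table,
                                optimize_threshold)
from .conftest import make_recording


class TestComputeSvm:
    def test_pythagorean_triple(self):
        rec = make_recording([0.003] * 4, [0.004] * 4, [0.0] * 4)
        assert compute_svm(rec).v == pytest.approx([5.0] * 4)

    def test_unit_gravity(self):
        rec = make_recording([1.0] * 4, [0.0] * 4, [0.0] * 4)
        assert compute_svm(rec).v == pytest.approx([1000.0] * 4)

    def test_brute_force_norm(self, rng):
        a = rng.normal(size=(3, 100))
        rec = make_recording(*a)
        expected = np.array([np.sqrt(x * x + y * y + z * z) * 1000
                             for x, y, z in a.T])
        np.testing.assert_allclose(compute_svm(rec).v, expected, atol=1e-12)


def _svm(v, fs=100.0):
    return SvmSeries(t=np.arange(len(v)) / fs, v=np.asarray(v, float), fs=fs)


class TestBandpass:
    def test_dc_rejected(self):
        out = bandpass(_svm(np.full(6000, 1000.0)))
        trimmed = out.v[500:-500]
        assert np.abs(trimmed).max() < 1.0

    def test_passband_gain_near_unity(self):
        # long record and generous edge trim: the 0.1 Hz band edge has a
        # multi-second transient under zero-phase filtering
        t = np.arange(0, 300, 0.01)
        out = bandpass(_svm(np.sin(2 * np.pi * 1.0 * t)))
        amp = np.abs(out.v[10000:-10000]).max()
        assert 0.95 <= amp <= 1.05

    def test_stopband_attenuates(self):
        t = np.arange(0, 120, 0.01)
        out = bandpass(_svm(np.sin(2 * np.pi * 40.0 * t)))
        assert np.abs(out.v[4000:-4000]).max() < 0.1

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            bandpass(_svm(np.zeros(100), fs=15.0))


class TestEnvelopes:
    def test_null_signal(self):
        env = extract_envelopes(_svm(np.zeros(500)))
        assert np.all(env.upper == 0) and np.all(env.lower == 0)
        assert np.all(env.diff == 0)

    def test_sinusoid_diff_is_peak_to_peak(self):
        t = np.arange(0, 60, 0.01)
        env = extract_envelopes(_svm(50.0 * np.sin(2 * np.pi * 3.0 * t)))
        med = np.median(env.diff[200:-200])
        assert 0.9 * 100 <= med <= 1.1 * 100

    def test_negation_swaps_envelopes(self, rng):
        v = rng.normal(size=2000).cumsum()
        e1 = extract_envelopes(_svm(v))
        e2 = extract_envelopes(_svm(-v))
        np.testing.assert_allclose(e2.upper, -e1.lower, atol=1e-12)
        np.testing.assert_allclose(e2.lower, -e1.upper, atol=1e-12)

    def test_envelope_brackets_signal_extremes(self, rng):
        v = rng.normal(size=3000)
        env = extract_envelopes(_svm(v))
        assert env.upper.max() == pytest.approx(v.max())
        assert env.lower.min() == pytest.approx(v.min())
        assert np.all(env.diff >= 0)


def _burst_trace(rng, amp_mg=100.0, onset=10.0, dur=3.0, total=60.0,
                 noise_mg=2.0, fs=100.0):
    n = int(total * fs)
    v = rng.normal(0, noise_mg, n)
    i0, k = int(onset * fs), int(dur * fs)
    taper = np.ones(k)
    e = int(0.5 * fs)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(e) / e))
    taper[:e], taper[-e:] = ramp, ramp[::-1]
    v[i0:i0 + k] += (amp_mg / 2) * taper * np.sin(2 * np.pi * 4 * np.arange(k) / fs)
    return _svm(v, fs)


class TestDetectBursts:
    def test_flat_envelope_no_bursts(self):
        env = extract_envelopes(_svm(np.zeros(1000)))
        assert detect_bursts(env, 20.0) == []

    def test_single_injected_burst_recovered(self, rng):
        env = extract_envelopes(_burst_trace(rng))
        bursts = detect_bursts(env, 20.0)
        assert len(bursts) == 1
        b = bursts[0]
        assert b.onset == pytest.approx(10.0, abs=0.25)
        assert b.offset == pytest.approx(13.0, abs=0.25)
        assert b.magnitude == pytest.approx(100.0, rel=0.15)

    def test_burst_count_non_increasing_with_threshold(self, rng):
        # three well-separated bursts of graded amplitude on a quiet floor
        v = _burst_trace(rng, amp_mg=150.0, onset=10.0, noise_mg=0.5).v
        v += _burst_trace(rng, amp_mg=60.0, onset=25.0, noise_mg=0.0).v
        v += _burst_trace(rng, amp_mg=30.0, onset=40.0, noise_mg=0.0).v
        env = extract_envelopes(_svm(v))
        counts = [len(detect_bursts(env, thr)) for thr in range(5, 76, 5)]
        assert counts[0] == 3
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_nearby_crossings_merged(self):
        # two supra-threshold islands 0.3 s apart merge into one burst
        fs = 100.0
        diff = np.zeros(2000)
        diff[500:600] = 50.0
        diff[630:700] = 40.0
        from noctomap.detection import EnvelopePair
        env = EnvelopePair(t=np.arange(2000) / fs, upper=diff,
                           lower=np.zeros(2000), fs=fs)
        bursts = detect_bursts(env, 20.0)
        assert len(bursts) == 1
        assert bursts[0].magnitude == pytest.approx(50.0)


class TestMatchAndScore:
    def test_perfect_match(self):
        iv = [(float(i), i + 0.5) for i in range(0, 100, 10)]
        m = match_and_score(iv, iv)
        assert (m.sensitivity, m.precision, m.f1) == (1.0, 1.0, 1.0)

    def test_formula_9_1_1(self):
        m = DetectionMetrics(tp=9, fp=1, fn=1)
        assert m.sensitivity == pytest.approx(0.9)
        assert m.precision == pytest.approx(0.9)
        assert m.f1 == pytest.approx(0.9)

    def test_disjoint_all_zero(self):
        m = match_and_score([(0.0, 1.0)], [(5.0, 6.0)])
        assert m.tp == 0 and m.fp == 1 and m.fn == 1
        assert m.f1 == 0.0

    def test_partial_overlap_counts(self):
        # one detection straddling two annotations: 1 TP, both annotations hit
        m = match_and_score([(0.0, 10.0)], [(1.0, 2.0), (8.0, 9.0)])
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError):
            match_and_score([(0.0, 2.0), (1.0, 3.0)], [])


class TestOptimizeThreshold:
    def _cohort(self, rng, n_subjects=3):
        # annotated 100 mg movements plus unannotated ~12 mg twitches: low
        # thresholds pick up the twitches as false positives, very high ones
        # miss the movements
        subs = []
        for _ in range(n_subjects):
            v = _burst_trace(rng, amp_mg=100.0, onset=10.0, noise_mg=0.5).v
            v += _burst_trace(rng, amp_mg=100.0, onset=40.0, noise_mg=0.0).v
            for onset in (20.0, 30.0, 50.0):
                v += _burst_trace(rng, amp_mg=12.0, onset=onset, noise_mg=0.0).v
            env = extract_envelopes(_svm(v))
            subs.append({"envelope": env,
                         "annotations": [(10.0, 13.0), (40.0, 43.0)]})
        return subs

    def test_single_candidate_returned(self, rng):
        subs = self._cohort(rng, 1)
        assert optimize_threshold([42.0], subs) == 42.0

    def test_separable_cohort_threshold_between_noise_and_signal(self, rng):
        subs = self._cohort(rng)
        thr = optimize_threshold(list(range(5, 101, 5)), subs)
        assert 10.0 < thr < 100.0

    def test_internal_table_matches_brute_force(self, rng):
        subs = self._cohort(rng)
        cands = [10.0, 30.0, 60.0]
        table = mean_f1_table(cands, subs)
        for thr in cands:
            f1s = []
            for sub in subs:
                bursts = detect_bursts(sub["envelope"], thr)
                det = [(b.onset, b.offset) for b in bursts]
                ann = sub["annotations"]
                tp = sum(1 for d in det
                         if any(d[0] <= a1 and a0 <= d[1] for a0, a1 in ann))
                fp = len(det) - tp
                fn = sum(1 for a in ann
                         if not any(a[0] <= d1 and d0 <= a[1] for d0, d1 in det))
                f1s.append(tp / (tp + (fp + fn) / 2) if tp + fp + fn else 0.0)
            assert table[thr] == pytest.approx(np.mean(f1s))

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            optimize_threshold([], self._cohort(rng, 1))
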