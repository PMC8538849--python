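"""Feature suite: detection, HRV arithmetic, morphology, family semantics."""

import numpy as np
import pytest

from densecg import synthetic
from densecg.errors import InsufficientBeatsError, TooShortError
from densecg.features import (build_average_beat, classify_beats, detect_beats,
                              hrv_features)
from densecg.features.beats import beat_amplitudes
from densecg.features.hrv import poincare_sd
from densecg.features.morphology import morphology_features
from densecg.features.pca import pca_deviation_stds
from densecg.features.rhythm import af_probability, rhythm_features
from densecg.features.tq_time import segment_leakage
from densecg.features.tq_freq import window_spectrum_stats
from densecg.types import BeatSet, ECGRecord


class TestDetectBeats:
    def test_clean_sinus_all_beats_within_10_ms(self, normal_record):
        rec, gt = normal_record
        beats = detect_beats(rec)
        assert not beats.detector_failed
        tol = int(0.010 * rec.fs)
        for r in gt.r_peaks:
            assert np.min(np.abs(beats.r_peaks - r)) <= tol
        assert len(beats) == len(gt.r_peaks)

    def test_flat_signal_flags_failure(self):
        rec = ECGRecord(np.zeros(3000), 300.0)
        beats = detect_beats(rec)
        assert beats.detector_failed
        assert len(beats) <= 1

    def test_too_short_record_rejected(self):
        with pytest.raises(TooShortError):
            detect_beats(ECGRecord(np.zeros(300), 300.0))

    def test_deterministic(self, af_record):
        rec, _ = af_record
        b1, b2 = detect_beats(rec), detect_beats(rec)
        assert np.array_equal(b1.r_peaks, b2.r_peaks)


class TestAverageBeat:
    def test_identical_beats_average_equals_beat(self, normal_record):
        rec, _ = normal_record
        beats = detect_beats(rec)
        avg = build_average_beat(rec, beats)
        r = beats.r_peaks[len(beats) // 2]
        seg = rec.samples[r - avg.pre: r + avg.post]
        # near-identical template beats: average within a few percent
        assert np.corrcoef(seg, avg.waveform)[0, 1] > 0.99

    def test_amplitude_outlier_rejected(self):
        fs = 300.0
        n = int(12 * fs)
        x = np.zeros(n)
        rr = int(0.8 * fs)
        peaks = np.arange(int(0.5 * fs), n - int(0.5 * fs), rr)[:10]
        t = np.arange(-60, 61) / fs
        bump = np.exp(-0.5 * (t / 0.012) ** 2)
        for i, p in enumerate(peaks):
            amp = 3.0 if i == 4 else 1.0
            x[p - 60: p + 61] += amp * bump
        rec = ECGRecord(x, fs)
        beats = BeatSet(peaks)
        avg = build_average_beat(rec, beats)
        rej = 100.0 * (~avg.included_mask).sum() / len(beats)
        assert not avg.included_mask[4]
        assert rej == pytest.approx(10.0)

    def test_zero_std_band_keeps_all(self):
        fs = 300.0
        x = np.zeros(int(12 * fs))
        peaks = np.arange(150, len(x) - 150, 240)
        x[peaks] = 1.0
        avg = build_average_beat(ECGRecord(x, fs), BeatSet(peaks))
        assert avg.included_mask[[i for i, r in enumerate(peaks)
                                  if r > 75 and r + 135 < len(x)]].all()

    def test_insufficient_beats_raises(self, normal_record):
        rec, _ = normal_record
        with pytest.raises(InsufficientBeatsError):
            build_average_beat(rec, BeatSet(np.array([500, 900])))


class TestHRV:
    def test_constant_series_degenerates(self):
        f = hrv_features(np.array([800.0] * 4))
        assert f["RRstd"] == 0 and f["PNN50%"] == 0 and f["RMSSD"] == 0
        assert np.isnan(f["corRR"])

    def test_hand_arithmetic(self):
        f = hrv_features(np.array([800.0, 860.0, 820.0, 900.0]))
        assert f["PNN50%"] == pytest.approx(66.6667, abs=1e-3)
        assert f["RMSSD"] == pytest.approx(np.sqrt((60**2 + 40**2 + 80**2) / 3),
                                           abs=1e-9)
        assert f["RRmean"] == pytest.approx(845.0)
        assert f["dRRmean"] == pytest.approx(60.0)

    def test_alternating_series_poincare_degenerate(self):
        rr = np.array([700.0, 900.0] * 6)
        sd1, sd2 = poincare_sd(rr)
        assert sd2 == pytest.approx(0.0, abs=1e-9)
        f = hrv_features(rr)
        assert np.isnan(f["SD1/SD2"])  # divide-by-zero guard -> missing

    def test_pnn50_per_minute_normalization(self):
        # 3 of 4 diffs exceed 50 ms; total |dRR| = 260 ms
        rr = np.array([800.0, 900.0, 820.0, 880.0, 860.0])
        f = hrv_features(rr)
        assert f["PNN50"] == pytest.approx(3 / (260.0 / 60000.0))

    def test_fewer_than_two_rr_all_missing(self):
        f = hrv_features(np.array([800.0]))
        assert all(np.isnan(v) for v in f.values())


class TestMorphology:
    def test_self_correlation_unity(self, normal_record):
        rec, _ = normal_record
        beats = detect_beats(rec)
        avg = build_average_beat(rec, beats)
        f = morphology_features(rec, beats, avg)
        assert 0.97 <= f["corBeat(25%)"] <= f["corBeat(50%)"] <= 1.0
        assert f["corBeat(mean)"] <= 1.0

    def test_p_wave_present_in_sinus_absent_in_af(self, normal_record, af_record):
        for (rec, _), expect in ((normal_record, 1.0), (af_record, 0.0)):
            beats = detect_beats(rec)
            avg = build_average_beat(rec, beats)
            f = morphology_features(rec, beats, avg)
            assert f["P-wave presence"] == expect

    def test_wide_inverted_beat_triggers_lbbb_pattern(self):
        """QRS-width > 140 ms with a deep discordant T marks the
        bundle-branch-block morphology test."""
        fs = 300.0
        n = int(12 * fs)
        x = np.zeros(n)
        peaks = np.arange(int(0.6 * fs), n - int(0.6 * fs), int(0.9 * fs))
        tt = np.arange(-int(0.3 * fs), int(0.46 * fs)) / fs
        beat = (np.exp(-0.5 * (tt / 0.040) ** 2)          # broad R
                - 0.5 * np.exp(-0.5 * ((tt - 0.10) / 0.030) ** 2)  # deep S late
                - 0.55 * np.exp(-0.5 * ((tt - 0.30) / 0.05) ** 2))  # inverted T
        for p in peaks:
            x[p - int(0.3 * fs): p + int(0.46 * fs)] += beat
        rec = ECGRecord(x, fs)
        beats = BeatSet(peaks)
        avg = build_average_beat(rec, beats)
        f = morphology_features(rec, beats, avg)
        assert f["Inverted QRS-T"] == 1.0
        assert f["QRS-width"] > 140.0
        assert f["LBBB"] == 1.0

    def test_straight_line_has_zero_curvature(self):
        from densecg.features.morphology import _curvature_max
        w = np.linspace(0.0, 1.0, 200)
        assert _curvature_max(w, 10, 150) == pytest.approx(0.0, abs=1e-12)


class TestRhythmFamily:
    def test_all_normal_beats(self, normal_record):
        rec, _ = normal_record
        beats = detect_beats(rec)
        avg = build_average_beat(rec, beats)
        beats = classify_beats(rec, beats, avg)
        f = rhythm_features(rec, beats)
        assert f["NBeats%"] == pytest.approx(100.0)
        assert np.isnan(f["MeanAmpVB"])

    def test_bigeminy_near_half_normal(self):
        rec, gt = synthetic.generate_ecg(synthetic.RhythmSpec(
            "O", ectopy_pattern="bigeminy", seed=21))
        beats = detect_beats(rec)
        avg = build_average_beat(rec, beats)
        beats = classify_beats(rec, beats, avg)
        f = rhythm_features(rec, beats)
        truth_pct = 100.0 * np.mean(gt.beat_class == "normal")
        assert f["NBeats%"] == pytest.approx(truth_pct, abs=15.0)

    def test_constant_rr_minimizes_af_probability(self, rng):
        base = af_probability(np.full(20, 800.0))
        for _ in range(5):
            rr = 800.0 + rng.normal(0, 120, size=20).cumsum() * 0.2
            assert af_probability(np.abs(rr)) >= base - 1e-9


class TestSegmentFamilies:
    def test_pca_identical_segments_zero_deviation(self, rng):
        seg = rng.normal(size=64)
        dev = pca_deviation_stds([seg] * 5)
        assert np.allclose(dev, 0.0, atol=1e-12)

    def test_pca_noise_level_recovered(self, rng):
        sigma = 0.05
        template = np.sin(np.linspace(0, 3 * np.pi, 128))
        segs = [template + rng.normal(0, sigma, 128) for _ in range(40)]
        dev = pca_deviation_stds(segs)
        assert dev.mean() == pytest.approx(sigma, rel=0.2)

    def test_pca_scaled_segment_widens_range(self, rng):
        template = np.sin(np.linspace(0, 3 * np.pi, 64))
        segs = [template.copy() for _ in range(6)] + [2 * template]
        dev = pca_deviation_stds(segs)
        assert dev.max() - dev.min() > 0

    def test_leakage_pure_tone_near_zero(self):
        fs = 300.0
        t = np.arange(int(1.0 * fs)) / fs
        leak, period = segment_leakage(0.1 * np.sin(2 * np.pi * 6.0 * t), fs)
        assert leak < 0.05
        assert period == pytest.approx(1000.0 / 6.0, rel=0.06)

    def test_leakage_white_noise_high(self, rng):
        leak, _ = segment_leakage(rng.normal(size=300), 300.0)
        assert leak > 0.5

    def test_spectrum_stats_single_tone(self):
        fs = 300.0
        t = np.arange(int(4 * fs)) / fs
        st = window_spectrum_stats(np.sin(2 * np.pi * 6.0 * t), fs)
        assert st["DF"] == pytest.approx(6.0, abs=0.1)
        assert st["RI"] > 0.9

    def test_two_tone_width_at_low_level(self):
        fs = 300.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 8 * t)
        st = window_spectrum_stats(x, fs)
        # the enclosing span at the 0.2 level covers both tones
        assert st["SpecWidth_02"] >= 3.0
        assert st["SpecArea_02"] > st["SpecArea_08"]

    def test_noise_regularity_below_tone_regularity(self, rng):
        fs = 300.0
        t = np.arange(int(4 * fs)) / fs
        tone = window_spectrum_stats(np.sin(2 * np.pi * 6 * t), fs)
        noise = window_spectrum_stats(rng.normal(size=len(t)), fs)
        assert noise["RI"] < tone["RI"]
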