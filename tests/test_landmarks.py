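import numpy as np
import pytest

from breathkin.core import TimeSeries
from breathkin.errors import LandmarkValidationError
from breathkin.landmarks import (MANUALLY_CORRECTED, NO_INHALATION,
                                 BreathingLandmarks, DetectionConfig,
                                 UtteranceRecord, apply_corrections,
                                 detect_landmarks, screen_utterances,
                                 velocity_profile)
from breathkin.synthetic import CycleSpec, breathing_kernel
from conftest import make_ts
from oracle import oracle_landmarks


class TestVelocityProfile:
    def test_linear_ramp_slope(self):
        ts = make_ts(2.0 * np.arange(100) / 100.0, rate_hz=100.0)
        v = velocity_profile(ts)
        np.testing.assert_allclose(v.values[1:-1], 2.0, atol=1e-9)
        assert len(v) == len(ts)

    def test_constant_gives_zero(self):
        v = velocity_profile(make_ts(np.full(50, 7.0)))
        np.testing.assert_allclose(v.values, 0.0, atol=1e-12)

    def test_sinusoid_matches_analytic_derivative(self):
        f, rate = 2.0, 1000.0
        t = np.arange(2000) / rate
        v = velocity_profile(make_ts(np.sin(2 * np.pi * f * t), rate_hz=rate))
        assert v.values.max() == pytest.approx(2 * np.pi * f, rel=1e-3)
        # maximum occurs at a rising zero crossing of the sinusoid
        t_max = t[np.argmax(v.values)]
        assert min(t_max % (1 / f), (1 / f) - t_max % (1 / f)) < 2 / rate


def analytic_cycle_signal():
    """Flat 0 until t=1.0, raised-cosine rise to 1.0 at t=1.6, smooth decay
    back to 0 at t=5.0, sampled densely at 100 Hz (no filtering)."""
    cyc = CycleSpec(1.0, 0.6, 3.4, 1.0)
    t = np.arange(0.0, 6.0, 0.01)
    return make_ts(breathing_kernel(cyc, t), rate_hz=100.0)


class TestDetectLandmarks:
    def test_analytic_cycle_all_landmarks_within_one_sample(self):
        # on an unfiltered analytic waveform the strict zero-crossing rule
        # applies (the velocity floor exists to counter filter leak)
        ts = analytic_cycle_signal()
        cfg = DetectionConfig(zero_frac=0.0)
        lm = detect_landmarks(ts, acoustic_onset_s=2.1, acoustic_offset_s=4.6,
                              cfg=cfg)
        assert lm.inhalation_onset_s == pytest.approx(1.00, abs=0.0101)
        assert lm.inhalation_offset_s == pytest.approx(1.60, abs=0.0101)
        assert lm.exhalation_offset_s == pytest.approx(5.00, abs=0.0101)
        assert lm.ordered() and not lm.flagged

    def test_monotone_decreasing_signal_flagged_no_inhalation(self):
        ts = make_ts(np.linspace(1.0, 0.0, 600), rate_hz=100.0)
        lm = detect_landmarks(ts, 3.0, 5.0, DetectionConfig())
        assert NO_INHALATION in lm.qc_flags
        assert np.isnan(lm.inhalation_onset_s)

    def test_larger_of_two_velocity_peaks_selected(self):
        # two rises in the window; the second is steeper -> larger velocity
        t = np.arange(0.0, 6.0, 0.01)
        small = breathing_kernel(CycleSpec(1.0, 0.8, 1.0, 0.5), t)
        large = breathing_kernel(CycleSpec(3.0, 0.4, 1.5, 1.0), t)
        ts = make_ts(small + large, rate_hz=100.0)
        cfg = DetectionConfig(peak_window_s=6.0, zero_frac=0.0)
        lm = detect_landmarks(ts, 3.2, 5.0, cfg)
        assert 3.0 < lm.velocity_peak_s < 3.4

    def test_equal_peaks_tie_break_to_earlier(self):
        # velocity plateau: a linear ramp has constant velocity; argmax must
        # take the first sample of the plateau
        vals = np.concatenate([np.zeros(100), np.linspace(0, 1, 200), np.ones(100)])
        ts = make_ts(vals, rate_hz=100.0)
        cfg = DetectionConfig(peak_window_s=2.0, zero_frac=0.0,
                              min_velocity_peak=0.01)
        lm = detect_landmarks(ts, 2.0, 3.5, cfg)
        v = velocity_profile(ts).values
        w0, w1 = 100, 300
        expected = (w0 + int(np.argmax(v[w0:w1 + 1]))) / 100.0
        assert lm.velocity_peak_s == pytest.approx(expected)

    def test_oracle_equivalence_on_random_smooth_signals(self, rng):
        cfg = DetectionConfig(min_velocity_peak=0.05, zero_frac=0.1)
        from scipy.ndimage import gaussian_filter1d

        for _ in range(25):
            n = int(rng.integers(400, 1500))
            vals = gaussian_filter1d(rng.normal(size=n), 8.0)
            ts = make_ts(vals, rate_hz=100.0)
            onset = float(rng.uniform(ts.start_s + 1.2, ts.end_s - 1.2))
            offset = float(rng.uniform(onset, ts.end_s))
            got = detect_landmarks(ts, onset, offset, cfg)
            want = oracle_landmarks(ts, onset, offset, cfg)
            assert got.qc_flags == want.qc_flags
            if not got.flagged:
                assert got == want


class TestApplyCorrections:
    LM = BreathingLandmarks(1.0, 1.6, 5.0, 1.3)

    def test_single_override_sets_flag_keeps_others(self):
        out = apply_corrections(self.LM, {"inhalation_onset_s": 0.9})
        assert out.inhalation_onset_s == 0.9
        assert out.inhalation_offset_s == 1.6
        assert MANUALLY_CORRECTED in out.qc_flags

    def test_empty_overrides_identity_no_flag(self):
        out = apply_corrections(self.LM, {})
        assert out == self.LM
        assert not out.qc_flags

    def test_ordering_violation_rejected(self):
        with pytest.raises(LandmarkValidationError):
            apply_corrections(self.LM, {"inhalation_onset_s": 2.0})

    def test_unknown_field_rejected(self):
        with pytest.raises(LandmarkValidationError):
            apply_corrections(self.LM, {"bogus": 1.0})


def _record(i, speaker, flagged):
    lm = (BreathingLandmarks(np.nan, np.nan, np.nan, 0.0,
                             qc_flags=frozenset({NO_INHALATION}))
          if flagged else BreathingLandmarks(1.0, 1.6, 5.0, 1.3))
    return UtteranceRecord(f"u{i}", speaker, "short_simple", 1, {"rip": lm})


class TestScreening:
    def test_one_of_ten_flagged(self):
        utts = [_record(i, f"P{i % 5}", flagged=(i == 3)) for i in range(10)]
        res = screen_utterances(utts)
        assert len(res.kept) == 9
        assert res.n_excluded_utterances == 1
        assert res.exclusion_fraction == pytest.approx(0.1)
        assert res.removed_speakers == []

    def test_none_flagged_all_kept(self):
        utts = [_record(i, f"P{i % 3}", False) for i in range(6)]
        res = screen_utterances(utts)
        assert len(res.kept) == 6 and not res.excluded

    def test_all_flagged_speaker_removed_entirely(self):
        utts = [_record(i, "P1", True) for i in range(4)]
        utts += [_record(10 + i, "P2", flagged=(i == 0)) for i in range(4)]
        res = screen_utterances(utts)
        assert res.removed_speakers == ["P1"]
        assert res.n_after_speaker_removal == 4
        assert res.n_excluded_utterances == 1
        assert len(res.kept) == 3

    def test_study_scale_accounting(self):
        # 18 speakers x 8 utterances; 2 speakers never inhale; 14 further
        # flagged -> 14/128 = 10.9 % and 114 kept
        utts = []
        k = 0
        flagged_extra = 0
        for s in range(18):
            for u in range(8):
                if s >= 16:
                    flag = True
                else:
                    flag = flagged_extra < 14 and (s * 8 + u) % 9 == 0
                    flagged_extra += int(flag)
                utts.append(_record(k, f"P{s:02d}", flag))
                k += 1
        res = screen_utterances(utts)
        assert res.n_recorded == 144
        assert len(res.removed_speakers) == 2
        assert res.n_after_speaker_removal == 128
        assert res.n_excluded_utterances == 14
        assert 100 * res.exclusion_fraction == pytest.approx(10.9, abs=0.05)
        assert len(res.kept) == 114
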