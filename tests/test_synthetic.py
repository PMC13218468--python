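import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathkin.errors import SpecError
from breathkin.landmarks import DetectionConfig, detect_landmarks
from breathkin.pipeline import analyze_session
from breathkin.synthetic import (CycleSpec, SessionSpec, breathing_kernel,
                                 generate_session, latent_trajectory,
                                 speech_session, tidal_session)


class TestBreathingKernel:
    CYCLE = CycleSpec(onset_s=1.0, inhale_dur_s=0.6, exhale_dur_s=3.4, amplitude=2.0)

    def test_endpoint_values(self):
        c = self.CYCLE
        assert breathing_kernel(c, c.onset_s) == pytest.approx(0.0)
        assert breathing_kernel(c, c.onset_s + c.inhale_dur_s) == pytest.approx(2.0)
        assert breathing_kernel(c, c.onset_s - 0.5) == 0.0
        assert breathing_kernel(c, c.end_s + 0.01) == 0.0

    def test_raised_cosine_midpoint_is_half_amplitude(self):
        c = self.CYCLE
        mid = c.onset_s + c.inhale_dur_s / 2
        assert breathing_kernel(c, mid) == pytest.approx(c.amplitude / 2)

    def test_maximum_at_inhalation_offset_by_grid_scan(self):
        c = self.CYCLE
        t = np.arange(0.0, c.end_s + 1.0, 1e-4)
        vals = breathing_kernel(c, t)
        t_max = t[np.argmax(vals)]
        assert abs(t_max - c.peak_s) <= 1e-4

    @given(st.floats(-1.0, 7.0))
    @settings(deadline=None, max_examples=200)
    def test_bounded_and_nonnegative(self, t):
        v = breathing_kernel(self.CYCLE, t)
        assert 0.0 <= v <= self.CYCLE.amplitude + 1e-12

    def test_continuity_at_phase_boundaries(self):
        c = self.CYCLE
        eps = 1e-9
        for edge in (c.onset_s, c.peak_s, c.end_s):
            lo = breathing_kernel(c, edge - eps)
            hi = breathing_kernel(c, edge + eps)
            assert abs(hi - lo) < 1e-6


class TestGenerateSession:
    def test_noiseless_rip_is_gain_times_kernel(self):
        cyc = CycleSpec(0.5, 0.5, 2.0, 1.0)
        spec = SessionSpec(cycles=(cyc,), rip_gain=2.5, rip_noise_sd=0.0,
                           rip_rate_hz=1000.0, ema_rate_hz=250.0, seed=0)
        session = generate_session(spec)
        t = session.rip.times()
        np.testing.assert_allclose(session.rip.values,
                                   2.5 * breathing_kernel(cyc, t), atol=1e-12)

    def test_same_seed_bit_identical(self):
        spec = speech_session(n_cycles=2, rip_noise_sd=0.05, sensor_noise_sd=0.2,
                              rip_rate_hz=2000.0, ema_rate_hz=250.0, seed=11)
        s1, s2 = generate_session(spec), generate_session(spec)
        np.testing.assert_array_equal(s1.rip.values, s2.rip.values)
        np.testing.assert_array_equal(
            s1.sensors.coord("chestmid", "x").values,
            s2.sensors.coord("chestmid", "x").values,
        )

    def test_overlapping_cycles_rejected(self):
        with pytest.raises(SpecError, match="overlap"):
            SessionSpec(cycles=(CycleSpec(0.0, 1.0, 2.0), CycleSpec(2.5, 1.0, 2.0)))

    def test_audio_tracks_carry_one_impulse_at_known_offset(self):
        spec = speech_session(n_cycles=1, sync_offset_s=0.4,
                              rip_rate_hz=2000.0, ema_rate_hz=250.0, seed=0)
        s = generate_session(spec)
        t_rip = np.argmax(np.abs(s.audio_rip.values) > 0.5) / spec.rip_rate_hz
        t_ema = np.argmax(np.abs(s.audio_ema.values) > 0.5) / spec.rip_rate_hz
        assert t_rip == pytest.approx(spec.clap_time_s, abs=1e-3)
        assert t_ema - t_rip == pytest.approx(0.4, abs=1e-3)

    def test_truth_landmarks_strictly_ordered(self):
        s = generate_session(speech_session(n_cycles=3, rip_rate_hz=2000.0,
                                            ema_rate_hz=250.0))
        for lm in s.truth:
            assert lm.inhalation_onset_s < lm.velocity_peak_s \
                < lm.inhalation_offset_s < lm.exhalation_offset_s

    def test_one_sonja_interval_per_cycle_after_its_onset(self):
        spec = speech_session(n_cycles=3, rip_rate_hz=2000.0, ema_rate_hz=250.0)
        s = generate_session(spec)
        assert len(s.annotations) == 3
        for iv, lm in zip(s.annotations, s.truth):
            assert iv.start_s == pytest.approx(
                lm.inhalation_onset_s + spec.sonja_lag_s)


class TestNoiselessRecovery:
    def test_full_pipeline_recovers_truth_landmarks(self, noiseless_session):
        """End to end: noiseless session through sync, conditioning and
        detection recovers every truth landmark within 2 samples at 100 Hz."""
        session = noiseless_session
        ana = analyze_session(session)
        truth = session.truth_aligned()
        intervals = session.annotations.shifted(-session.spec.clap_time_s).intervals
        tol = 2 / 100.0
        for channel in ("rip", "chestmid_x", "midpoint_x", "sternum_x"):
            for iv, lm_t in zip(intervals[:2], truth[:2]):
                lm = detect_landmarks(ana.channels[channel], iv.start_s, iv.end_s,
                                      DetectionConfig())
                assert not lm.flagged
                assert lm.inhalation_onset_s == pytest.approx(
                    lm_t.inhalation_onset_s, abs=tol)
                assert lm.inhalation_offset_s == pytest.approx(
                    lm_t.inhalation_offset_s, abs=tol)
                assert lm.exhalation_offset_s == pytest.approx(
                    lm_t.exhalation_offset_s, abs=tol)


class TestTidalSession:
    def test_latent_has_n_maxima_and_no_annotations(self):
        s = tidal_session(n_cycles=3, period_s=4.0, rip_rate_hz=1000.0,
                          ema_rate_hz=250.0)
        t = s.rip.times()
        lat = latent_trajectory(s.spec.cycles, t)
        interior = (lat[1:-1] > lat[:-2]) & (lat[1:-1] >= lat[2:])
        # count well-separated local maxima
        peaks = np.flatnonzero(interior) + 1
        groups = 1 + int(np.sum(np.diff(peaks) > 100)) if len(peaks) else 0
        assert groups == 3
        assert len(s.annotations) == 0

    def test_noiseless_latent_periodicity(self):
        period = 4.0
        s = tidal_session(n_cycles=5, period_s=period, rip_rate_hz=500.0,
                          ema_rate_hz=250.0)
        # autocorrelate over the cyclic span (pre-roll and tail are flat)
        i0 = int(s.spec.cycles[0].onset_s * 500)
        i1 = int(s.spec.cycles[-1].end_s * 500)
        x = s.rip.values[i0:i1]
        lag = int(period * 500)
        a, b = x[:-lag], x[lag:]
        a = a - a.mean()
        b = b - b.mean()
        r = float(a @ b / np.sqrt((a @ a) * (b @ b)))
        assert r >= 0.99
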