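import numpy as np
import pytest

from breathkin.core import TimeSeries
from breathkin.errors import AlignmentError, DegenerateInputError, DetectionError
from breathkin.preprocess import (align_streams, detect_sync_impulse,
                                  gaussian_smooth, normalize_amplitude, resample)
from conftest import make_ts


class TestNormalize:
    def test_divides_by_max_abs(self):
        out = normalize_amplitude(make_ts([2.0, -4.0, 1.0]))
        np.testing.assert_allclose(out.values, [0.5, -1.0, 0.25])
        assert out.units == "norm"

    def test_idempotent(self, rng):
        ts = make_ts(rng.normal(size=200))
        once = normalize_amplitude(ts)
        twice = normalize_amplitude(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-15)
        assert np.max(np.abs(once.values)) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_amplitude(make_ts([0.0, 0.0, 0.0]))


class TestResample:
    def test_constant_stays_constant(self):
        ts = make_ts(np.full(1250, 3.25), rate_hz=1250.0)
        out = resample(ts, 100.0)
        assert out.rate_hz == pytest.approx(100.0)
        # constant preserved up to the FIR passband ripple
        np.testing.assert_allclose(out.values, 3.25, atol=1e-4)

    def test_length_contract_one_second(self):
        ts = make_ts(np.zeros(1250), rate_hz=1250.0)
        out = resample(ts, 100.0)
        assert abs(len(out) - 100) <= 1

    def test_sinusoid_accuracy_heavy_downsampling(self):
        # 5 Hz sinusoid, 44.1 kHz -> 100 Hz; compare against the analytic
        # waveform away from the edges
        rate_in = 44100.0
        t = np.arange(int(rate_in)) / rate_in
        ts = make_ts(np.sin(2 * np.pi * 5.0 * t), rate_hz=rate_in)
        out = resample(ts, 100.0)
        t_out = out.times()
        ref = np.sin(2 * np.pi * 5.0 * t_out)
        err = np.abs(out.values - ref)[5:-5]
        assert err.max() < 0.01

    def test_identity_when_rate_matches(self):
        ts = make_ts([1.0, 2.0, 3.0], rate_hz=100.0)
        assert resample(ts, 100.0) is ts


class TestGaussianSmooth:
    def test_unit_dc_gain_on_constant(self):
        ts = make_ts(np.full(100, 3.0))
        out = gaussian_smooth(ts, 5.0)
        np.testing.assert_allclose(out.values, 3.0, atol=1e-12)
        assert len(out) == len(ts)

    def test_sigma_zero_is_identity(self, rng):
        ts = make_ts(rng.normal(size=64))
        out = gaussian_smooth(ts, 0.0)
        np.testing.assert_array_equal(out.values, ts.values)

    def test_white_noise_variance_reduction(self, rng):
        # sum of squared kernel weights at sigma=5 is ~1/(2*sqrt(pi)*5) ~ 0.056,
        # so the output variance must fall well below a quarter of the input's
        noise = rng.normal(size=20000)
        out = gaussian_smooth(make_ts(noise), 5.0)
        ratio = np.var(out.values[100:-100]) / np.var(noise)
        assert ratio < 0.25

    def test_linearity(self, rng):
        a = rng.normal(size=300)
        b = rng.normal(size=300)
        sa = gaussian_smooth(make_ts(a), 5.0).values
        sb = gaussian_smooth(make_ts(b), 5.0).values
        sab = gaussian_smooth(make_ts(a + b), 5.0).values
        np.testing.assert_allclose(sab, sa + sb, atol=1e-9)


class TestSyncDetection:
    def test_single_spike_time(self):
        audio = np.zeros(44100)
        audio[2205] = 0.9
        t = detect_sync_impulse(make_ts(audio, rate_hz=44100.0), 0.8)
        assert t == pytest.approx(0.05)

    def test_leading_window_ignores_later_speech(self):
        # quiet clap at 0.5 s, much louder "speech" at 8 s: restricting the
        # search to the leading window must still return the clap
        rate = 8000.0
        audio = np.zeros(int(10 * rate))
        audio[int(0.5 * rate)] = 0.3
        audio[int(8.0 * rate) :] = 0.95
        ts = make_ts(audio, rate_hz=rate)
        t = detect_sync_impulse(ts, 0.8, search_window_s=5.0)
        assert t == pytest.approx(0.5)

    def test_silent_track_rejected(self):
        with pytest.raises(DetectionError):
            detect_sync_impulse(make_ts(np.zeros(1000), rate_hz=1000.0), 0.8)


class TestAlignStreams:
    def test_identical_signals_with_offsets(self, rng):
        vals = rng.normal(size=500)
        a = make_ts(vals, rate_hz=100.0, start_s=0.0)
        b = make_ts(vals, rate_hz=100.0, start_s=2.0)
        a2, b2 = align_streams(a, b, t_sync_a=1.0, t_sync_b=3.0)
        np.testing.assert_allclose(a2.values, b2.values)
        assert a2.start_s == pytest.approx(b2.start_s)

    def test_zero_offsets_identity(self, rng):
        vals = rng.normal(size=100)
        a = make_ts(vals, rate_hz=100.0)
        b = make_ts(vals, rate_hz=100.0)
        a2, b2 = align_streams(a, b, 0.0, 0.0)
        np.testing.assert_allclose(a2.values, vals)
        np.testing.assert_allclose(b2.values, vals)

    def test_impulse_trains_align_to_zero_lag(self):
        from breathkin.trajectories import max_cross_correlation

        rate = 100.0
        base = np.zeros(1000)
        base[::100] = 1.0
        a = make_ts(base, rate_hz=rate, start_s=0.0)
        b = make_ts(base, rate_hz=rate, start_s=0.25)
        a2, b2 = align_streams(a, b, t_sync_a=1.0, t_sync_b=1.25)
        r, lag = max_cross_correlation(a2, b2, max_lag_s=0.5)
        assert r == pytest.approx(1.0)
        assert abs(lag) <= 1.0 / rate

    def test_no_overlap_rejected(self):
        a = make_ts(np.zeros(10) + 1, rate_hz=10.0, start_s=0.0)
        b = make_ts(np.zeros(10) + 1, rate_hz=10.0, start_s=0.0)
        with pytest.raises(AlignmentError):
            align_streams(a, b, t_sync_a=0.0, t_sync_b=0.9)
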