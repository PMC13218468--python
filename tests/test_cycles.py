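import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathkin.core import TimeSeries
from breathkin.cycles import (distribution_distance, inhalation_amplitude,
                              summarize_by_group, temporal_parameters)
from breathkin.errors import DegenerateInputError
from breathkin.landmarks import NO_INHALATION, BreathingLandmarks
from conftest import make_ts

LM = BreathingLandmarks(1.00, 1.60, 5.00, 1.30)


class TestTemporalParameters:
    def test_subtraction_example(self):
        inh, exh, delta = temporal_parameters(LM, acoustic_onset_s=2.10)
        assert inh == pytest.approx(600.0)
        assert exh == pytest.approx(3400.0)
        assert delta == pytest.approx(1100.0)

    def test_delta_zero_when_acoustics_at_onset(self):
        assert temporal_parameters(LM, 1.00)[2] == pytest.approx(0.0)

    @given(st.floats(0.1, 2.0), st.floats(0.1, 5.0), st.floats(0.0, 10.0))
    @settings(deadline=None, max_examples=100)
    def test_phases_telescope_to_full_cycle(self, d_in, d_ex, onset):
        lm = BreathingLandmarks(onset, onset + d_in, onset + d_in + d_ex,
                                onset + d_in / 2)
        inh, exh, _ = temporal_parameters(lm, onset + 0.5)
        assert inh + exh == pytest.approx(
            (lm.exhalation_offset_s - lm.inhalation_onset_s) * 1000.0)

    def test_flagged_landmarks_rejected(self):
        lm = BreathingLandmarks(np.nan, np.nan, np.nan, 0.0,
                                qc_flags=frozenset({NO_INHALATION}))
        with pytest.raises(DegenerateInputError):
            temporal_parameters(lm, 1.0)


class TestInhalationAmplitude:
    def test_small_cycle_against_independent_zscore(self):
        # cycle [0, 0.5, 1.0, 0.6, 0.2]: onset index 0, inhalation offset
        # index 2, exhalation offset index 4; sample SD (ddof=1)
        vals = np.array([0.0, 0.5, 1.0, 0.6, 0.2])
        expected = (vals[2] - vals[0]) / np.std(vals, ddof=1)
        ts = make_ts(vals, rate_hz=100.0)
        lm = BreathingLandmarks(0.00, 0.02, 0.04, 0.01)
        amp = inhalation_amplitude(ts, lm)
        assert amp == pytest.approx(expected)
        assert amp == pytest.approx(2.60, abs=0.005)

    @given(st.floats(0.01, 100.0), st.floats(-50.0, 50.0))
    @settings(deadline=None, max_examples=50)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(3)
        vals = np.cumsum(rng.normal(size=200))
        lm = BreathingLandmarks(0.2, 0.8, 1.9, 0.5)
        amp1 = inhalation_amplitude(make_ts(vals), lm)
        amp2 = inhalation_amplitude(make_ts(a * vals + b), lm)
        assert amp2 == pytest.approx(amp1, rel=1e-9)

    def test_rip_and_mm_scaled_copy_agree(self):
        from breathkin.synthetic import CycleSpec, breathing_kernel

        t = np.arange(0.0, 6.0, 0.01)
        latent = breathing_kernel(CycleSpec(1.0, 0.6, 3.4, 1.0), t)
        rip = make_ts(latent, rate_hz=100.0, units="norm")
        ema = make_ts(35.0 + 6.0 * latent, rate_hz=100.0, units="mm")
        lm = BreathingLandmarks(1.00, 1.60, 5.00, 1.30)
        assert inhalation_amplitude(ema, lm) == pytest.approx(
            inhalation_amplitude(rip, lm), rel=1e-9)

    def test_zero_variance_cycle_rejected(self):
        ts = make_ts(np.full(100, 2.0))
        with pytest.raises(DegenerateInputError):
            inhalation_amplitude(ts, BreathingLandmarks(0.1, 0.3, 0.8, 0.2))


def brute_force_percentile(sorted_vals, q):
    """Linear-interpolation percentile recomputed from first principles."""
    n = len(sorted_vals)
    h = (n - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


class TestSummaries:
    def test_median_and_iqr_of_small_sample(self):
        (row,) = summarize_by_group([1, 2, 3, 4, 5])
        assert (row.median, row.iqr_low, row.iqr_high) == (3.0, 2.0, 4.0)

    def test_single_value_collapses(self):
        (row,) = summarize_by_group([7.5])
        assert row.median == row.iqr_low == row.iqr_high == 7.5

    def test_percentiles_match_brute_force_on_seven_element_sets(self, rng):
        base = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3]
        for perm in itertools.islice(itertools.permutations(base), 0, 5040, 101):
            (row,) = summarize_by_group(list(perm))
            sv = sorted(perm)
            assert row.iqr_low == pytest.approx(brute_force_percentile(sv, 25))
            assert row.median == pytest.approx(brute_force_percentile(sv, 50))
            assert row.iqr_high == pytest.approx(brute_force_percentile(sv, 75))

    def test_grouped_rows(self):
        vals = [1, 2, 3, 10, 20, 30]
        groups = [("rip", "short")] * 3 + [("rip", "long")] * 3
        rows = summarize_by_group(vals, groups)
        assert len(rows) == 2
        assert rows[0].median == 2.0 and rows[1].median == 20.0


class TestDistributionDistance:
    def test_identical_samples_give_zero(self, rng):
        s = rng.normal(size=300)
        assert distribution_distance(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_give_one(self, rng):
        a = rng.normal(0.0, 1.0, 300)
        assert distribution_distance(a, a + 1000.0) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self, rng):
        a = rng.normal(0.0, 1.0, 150)
        b = rng.normal(0.7, 1.3, 220)
        assert distribution_distance(a, b) == pytest.approx(
            distribution_distance(b, a), abs=1e-12)

    def test_same_generator_low_separated_generators_high(self):
        # calibration: two n=100 draws from one normal stay well below the
        # distance of generators separated by three SDs
        same, far = [], []
        for k in range(50):
            r = np.random.default_rng(1000 + k)
            same.append(distribution_distance(r.normal(size=100),
                                              r.normal(size=100)))
            far.append(distribution_distance(r.normal(0, 1, 100),
                                             r.normal(3, 1, 100)))
        assert np.median(same) < 0.25
        assert np.median(far) > 0.6
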