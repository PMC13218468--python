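import numpy as np
import pytest

from breathkin.bayes import (CorrelationPriorSpec, GpModelSpec, McmcConfig,
                             fit_gp_trajectory_model, fit_pairwise_correlation,
                             hdi)
from breathkin.trajectories import CycleTrajectory

FAST = McmcConfig(chains=4, tune=500, draws=500, seed=0)


class TestHdi:
    def test_standard_normal_quantiles(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        lo, hi = hdi(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_point_mass_zero_width(self):
        lo, hi = hdi(np.full(500, 3.3), 0.95)
        assert lo == hi == 3.3

    def test_uniform_width_matches_mass(self):
        x = np.random.default_rng(1).uniform(0, 1, 100_000)
        lo, hi = hdi(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)


class TestPairwiseCorrelation:
    def test_near_perfect_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = x + rng.normal(0, 1e-6, 50)
        post = fit_pairwise_correlation(x, y, mcmc=FAST)
        assert post.rho_mean > 0.95
        assert post.pr_gt_zero == pytest.approx(1.0, abs=1e-3)

    def test_posterior_mean_tracks_pearson(self):
        rng = np.random.default_rng(3)
        z = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=500)
        post = fit_pairwise_correlation(z[:, 0], z[:, 1], mcmc=FAST)
        r = np.corrcoef(z[:, 0], z[:, 1])[0, 1]
        assert post.rho_mean == pytest.approx(r, abs=0.05)
        assert post.hdi_low < r < post.hdi_high

    def test_null_correlation_monte_carlo(self):
        # true rho = 0, n = 500: Pr(>0) should hover around 1/2 and the HDI
        # should contain 0 in nearly every replicate
        prs, contains = [], 0
        n_seeds = 20
        for k in range(n_seeds):
            rng = np.random.default_rng(100 + k)
            z = rng.multivariate_normal([0, 0], np.eye(2), size=500)
            post = fit_pairwise_correlation(
                z[:, 0], z[:, 1],
                mcmc=McmcConfig(chains=4, tune=500, draws=500, seed=k))
            prs.append(post.pr_gt_zero)
            contains += int(post.hdi_low <= 0.0 <= post.hdi_high)
        assert 0.3 <= float(np.median(prs)) <= 0.7
        assert contains >= n_seeds - 2

    def test_scale_invariance_after_standardization(self):
        rng = np.random.default_rng(4)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=200)
        a = fit_pairwise_correlation(z[:, 0], z[:, 1], mcmc=FAST)
        b = fit_pairwise_correlation(1000.0 * z[:, 0], z[:, 1], mcmc=FAST)
        assert a.rho_mean == pytest.approx(b.rho_mean, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(Exception):
            fit_pairwise_correlation(np.ones(50), np.arange(50.0), mcmc=FAST)

    def test_bounds_and_diagnostics_well_formed(self):
        rng = np.random.default_rng(5)
        z = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], size=80)
        post = fit_pairwise_correlation(z[:, 0], z[:, 1], mcmc=FAST)
        assert -1 <= post.hdi_low <= post.rho_mean <= post.hdi_high <= 1
        div, rhat = post.diagnostics
        assert div == 0 and np.isfinite(rhat)


def _sine_channel(rng, channel, n, noise=0.01, n_speakers=4):
    t = np.linspace(0, 1, 50)
    curve = np.sin(2 * np.pi * t)
    return [
        CycleTrajectory(curve + rng.normal(0, noise, 50),
                        channel=channel, utterance_id=f"u{i}",
                        speaker=f"S{i % n_speakers}")
        for i in range(n)
    ]


class TestGpTrajectoryModel:
    """The null/offset checks pair the channels the way the study does:
    both channels observe the same breathing cycle per utterance and differ
    only by measurement noise (see evaluation.matched_trajectory_pair)."""

    MC = McmcConfig(chains=4, tune=300, draws=300, seed=1)

    def test_same_cycles_difference_band_contains_zero(self):
        from breathkin.evaluation import matched_trajectory_pair

        rng = np.random.default_rng(6)
        contrast = fit_gp_trajectory_model(
            *matched_trajectory_pair(rng, 10),
            mcmc=self.MC, n_band_draws=300)
        assert int(contrast.band_excludes_zero().sum()) == 0
        assert contrast.nonzero_ranges == []

    def test_constant_offset_recovered(self):
        from breathkin.evaluation import matched_trajectory_pair

        rng = np.random.default_rng(7)
        contrast = fit_gp_trajectory_model(
            *matched_trajectory_pair(rng, 10, shift_a=0.5),
            mcmc=self.MC, n_band_draws=300)
        interior = contrast.mean_diff[5:45]
        assert np.max(np.abs(interior - 0.5)) < 0.1
        # the flagged nonzero ranges must cover most interior steps
        flagged = contrast.band_excludes_zero()
        assert flagged[5:45].mean() > 0.8

    def test_low_noise_sine_recovered_pointwise(self):
        rng = np.random.default_rng(8)
        t = np.linspace(0, 1, 50)
        curve = np.sin(2 * np.pi * t)
        contrast = fit_gp_trajectory_model(
            _sine_channel(rng, "a", 10), _sine_channel(rng, "b", 10),
            mcmc=self.MC, n_band_draws=300)
        assert np.max(np.abs(contrast.mean_a - curve)) < 0.05
        assert np.max(np.abs(contrast.mean_b - curve)) < 0.05

    def test_single_speaker_drops_intercept_with_warning(self, caplog):
        import logging

        rng = np.random.default_rng(9)
        with caplog.at_level(logging.WARNING):
            contrast = fit_gp_trajectory_model(
                _sine_channel(rng, "a", 6, noise=0.05, n_speakers=1),
                _sine_channel(rng, "b", 6, noise=0.05, n_speakers=1),
                mcmc=self.MC, n_band_draws=200)
        assert any("intercept" in r.message for r in caplog.records)
        assert len(contrast.mean_diff) == 50

    def test_band_ordering_invariant(self):
        from breathkin.evaluation import matched_trajectory_pair

        rng = np.random.default_rng(10)
        contrast = fit_gp_trajectory_model(
            *matched_trajectory_pair(rng, 8),
            mcmc=self.MC, n_band_draws=200)
        for mean, (lo, hi) in ((contrast.mean_a, contrast.band_a),
                               (contrast.mean_b, contrast.band_b),
                               (contrast.mean_diff, contrast.band_diff)):
            assert np.all(lo <= hi)
            assert np.all((mean >= lo - 1e-9) & (mean <= hi + 1e-9))
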