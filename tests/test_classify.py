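"""Density estimation, peak finding, robust refinement, threshold placement."""

import numpy as np
import pytest
from scipy import stats

from dropstat.classify import (
    DegenerateInputError,
    PopulationModel,
    bound_multiplier,
    classify_droplets,
    estimate_density,
    find_density_peaks,
    initial_population_estimates,
    refine_population,
    set_threshold,
)
from dropstat.synth import SyntheticSpec, generate_reaction


class TestDensity:
    def test_single_mode_near_true_center(self, rng):
        x = rng.normal(1000, 100, size=10000)
        density = estimate_density(x)
        mode = density.grid[np.argmax(density.density)]
        assert abs(mode - 1000) <= 2 * density.step + 10

    def test_bandwidth_floor(self, rng):
        # tight data would get a tiny rule-of-thumb bandwidth; the floor holds
        tight = rng.normal(1000, 5, size=1000)
        assert estimate_density(tight).bandwidth == 50.0
        wide = np.concatenate([rng.normal(1000, 300, 5000), rng.normal(9000, 300, 5000)])
        assert estimate_density(wide).bandwidth >= 50.0

    def test_density_integrates_to_one(self, clean_bimodal):
        _, table, _ = clean_bimodal
        density = estimate_density(table)
        integral = np.trapezoid(density.density, density.grid)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            estimate_density(np.full(10, 1000.0))


class TestPeaks:
    def test_bimodal_two_peaks_near_centers(self, clean_bimodal):
        spec, table, _ = clean_bimodal
        density = estimate_density(table)
        locations, heights = find_density_peaks(density)
        assert locations.size == 2
        assert abs(locations[0] - spec.neg_center) < 3 * spec.neg_scale
        assert abs(locations[1] - spec.pos_center) < 3 * spec.pos_scale
        assert np.all(np.diff(locations) > 0)

    def test_unimodal_one_peak(self, rng):
        density = estimate_density(rng.normal(1000, 100, size=5000))
        locations, _ = find_density_peaks(density)
        assert locations.size == 1

    def test_trimodal_three_peaks(self, trimodal_reaction):
        _, table, _ = trimodal_reaction
        density = estimate_density(table)
        locations, _ = find_density_peaks(density)
        assert locations.size == 3


class TestInitialEstimates:
    def test_gaussian_width_rule_recovers_scale(self, rng):
        # at 60.65% of peak height a Gaussian is one sigma from its mode;
        # KDE convolution widens the estimate by the bandwidth in quadrature
        scale = 120.0
        x = rng.normal(1000, scale, size=20000)
        density = estimate_density(x)
        (mu0, sigma0, fallback), = initial_population_estimates(
            density, find_density_peaks(density)
        )
        assert not fallback
        expected = np.hypot(scale, density.bandwidth)
        assert sigma0 == pytest.approx(expected, rel=0.10)

    def test_bimodal_scales_recovered(self, clean_bimodal):
        spec, table, _ = clean_bimodal
        density = estimate_density(table)
        seeds = initial_population_estimates(density, find_density_peaks(density))
        assert len(seeds) == 2
        for (mu0, sigma0, _), center, scale in zip(
            seeds, (spec.neg_center, spec.pos_center), (spec.neg_scale, spec.pos_scale)
        ):
            assert mu0 == pytest.approx(center, abs=3 * scale)
            assert sigma0 == pytest.approx(np.hypot(scale, density.bandwidth), rel=0.15)


class TestRefinement:
    def test_bound_multiplier_at_normal_kurtosis(self):
        assert bound_multiplier(3.0) == pytest.approx(4.989, abs=1e-3)

    def test_bound_multiplier_monotone(self):
        ks = np.linspace(1.1, 30, 50)
        values = [bound_multiplier(k) for k in ks]
        assert np.all(np.diff(values) > 0)

    def test_multiplier_covers_99pct_of_normal_population(self, rng):
        # a*sigma at k=3 should cover ~99% of a normal population
        x = rng.normal(0, 1, size=200000)
        a = bound_multiplier(3.0)
        mad_sigma = 1.4826 * np.median(np.abs(x - np.median(x)))
        coverage = np.mean(np.abs(x) <= a * mad_sigma)
        assert coverage > 0.99

    def test_symmetric_members_keep_location(self):
        x = 1000.0 + np.concatenate([-np.arange(1, 50), [0], np.arange(1, 50)])
        model = refine_population(x, mu0=1000.0, sigma0=30.0)
        assert model.mu == 1000.0

    def test_heavy_tails_widen_bounds(self):
        clean = SyntheticSpec(n_droplets=20000, lambda_true=0.0, seed=41)
        heavy = SyntheticSpec(n_droplets=20000, lambda_true=0.0, tail_weight=0.10, seed=41)
        models = {}
        for name, spec in (("clean", clean), ("heavy", heavy)):
            table, _ = generate_reaction(spec)
            models[name] = refine_population(table.amplitudes, spec.neg_center, spec.neg_scale)
        assert models["heavy"].k > models["clean"].k
        assert models["heavy"].a > models["clean"].a

    def test_too_few_members_flags_fallback(self):
        x = np.concatenate([np.full(3, 1000.0), np.full(500, 9000.0)])
        model = refine_population(x, mu0=1000.0, sigma0=1.0)
        assert model.fallback


class TestThreshold:
    def test_arithmetic(self):
        neg = PopulationModel(mu=1000.0, sigma=100.0, k=3.0, a=4.0, n_members=100)
        assert set_threshold(neg) == pytest.approx(1600.0)

    @pytest.mark.parametrize("mu,sigma,a", [(1000, 100, 4.0), (2000, 50, 5.2), (500, 300, 4.6)])
    def test_threshold_above_population_upper_bound(self, mu, sigma, a):
        neg = PopulationModel(mu=mu, sigma=sigma, k=3.0, a=a, n_members=100)
        assert set_threshold(neg) > neg.upper


class TestPipeline:
    def test_clean_bimodal_high_accuracy(self, clean_bimodal):
        _, table, truth = clean_bimodal
        result = classify_droplets(table)
        assert result.n_populations == 2
        assert not result.fallback_used
        predicted_positive = table.amplitudes > result.theta
        truly_occupied = truth.occupancy > 0
        accuracy = np.mean(predicted_positive == truly_occupied)
        assert accuracy >= 0.999
        assert result.n_neg + result.n_pos == result.n_total

    def test_population_order_and_threshold_placement(self, clean_bimodal):
        _, table, _ = clean_bimodal
        result = classify_droplets(table)
        neg, pos = result.negative, result.positive
        assert neg.upper < result.theta < pos.lower

    def test_rain_fraction_recovered(self, rainy_reaction):
        _, table, truth = rainy_reaction
        result = classify_droplets(table)
        true_rain = np.mean(truth.labels == "rain")
        assert result.n_rain / result.n_total == pytest.approx(true_rain, abs=0.005)

    def test_all_negative_well(self):
        spec = SyntheticSpec(n_droplets=5000, lambda_true=0.0, seed=4)
        table, _ = generate_reaction(spec)
        result = classify_droplets(table)
        assert result.n_pos == 0
        assert result.single_population
        assert result.n_populations == 1

    def test_affine_invariance(self, clean_bimodal):
        _, table, _ = clean_bimodal
        base = classify_droplets(table)
        scaled = classify_droplets(2.0 * table.amplitudes + 500.0)
        np.testing.assert_array_equal(base.labels, scaled.labels)
        assert scaled.theta == pytest.approx(2.0 * base.theta + 500.0, rel=0.02)

    def test_negative_misclassification_rate_tiny(self, clean_bimodal):
        # the threshold exists to keep empty droplets out of the positives
        _, table, truth = clean_bimodal
        result = classify_droplets(table)
        empties = truth.occupancy == 0
        false_pos = np.sum(table.amplitudes[empties] > result.theta)
        assert false_pos / empties.sum() < 0.001

    def test_minimum_droplet_floor(self):
        with pytest.raises(ValueError, match="at least"):
            classify_droplets(np.r_[np.full(30, 1000.0), np.full(30, 5000.0)])

    def test_lambda_recovery_within_poisson_error(self, clean_bimodal):
        spec, table, _ = clean_bimodal
        result = classify_droplets(table)
        lam_hat = -np.log(result.n_neg / result.n_total)
        se = np.sqrt((result.n_total - result.n_neg) / (result.n_total * result.n_neg))
        assert abs(lam_hat - spec.lambda_true) < 3 * se
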