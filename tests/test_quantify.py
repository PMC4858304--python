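"""Poisson estimation, merging, Fieller ratio CIs, replicate statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dropstat.quantify import (
    SaturatedReactionError,
    coverage_assessment,
    copies_to_mass,
    estimate_poisson,
    gm_ratio,
    mass_to_copies,
    merge_reactions,
    replicate_ci,
)


class TestPoissonEstimate:
    def test_half_occupancy_gives_ln2(self):
        est = estimate_poisson(10000, 20000)
        assert est.lambda_hat == pytest.approx(np.log(2), abs=1e-12)
        assert est.p0_hat == 0.5

    def test_confidence_half_width_closed_form(self):
        # hand-evaluated: 1.96 * sqrt(16000 / (20000 * 4000)) = 0.027719
        est = estimate_poisson(4000, 20000)
        assert est.lambda_hat == pytest.approx(1.6094, abs=1e-4)
        assert est.half_width == pytest.approx(0.027719, abs=1e-5)
        assert est.cb_low <= est.lambda_hat <= est.cb_high

    def test_half_width_matches_monte_carlo_sd(self, rng):
        # the closed form approximates 1.96 * sd(lambda_hat) over resamples
        n, lam = 20000, 1.6094
        n_neg = rng.binomial(n, np.exp(-lam), size=100000)
        mc_sd = (-np.log(n_neg / n)).std()
        est = estimate_poisson(int(round(n * np.exp(-lam))), n)
        assert est.half_width == pytest.approx(1.96 * mc_sd, rel=0.02)

    def test_copies_per_ul_at_optimal_load(self):
        est = estimate_poisson(4075, 20000, partition_volume_ul=0.85e-3)
        # lambda ~ 1.59 in 0.85 nl partitions -> ~1870 copies/ul
        assert est.lambda_hat == pytest.approx(1.5909, abs=1e-4)
        assert est.copies_per_ul == pytest.approx(1872, rel=0.005)

    def test_saturated_reaction_raises(self):
        with pytest.raises(SaturatedReactionError, match="merge"):
            estimate_poisson(0, 20000)

    def test_all_negative_one_sided(self):
        est = estimate_poisson(1000, 1000)
        assert est.lambda_hat == 0.0
        assert est.one_sided
        assert est.cb_high > 0

    def test_lambda_monotone_decreasing_in_n_neg(self):
        lams = [estimate_poisson(n_neg, 20000).lambda_hat for n_neg in range(1000, 20000, 1000)]
        assert np.all(np.diff(lams) < 0)


class TestMerging:
    def test_merge_equals_pooled_counts(self):
        merged = merge_reactions([(5000, 10000), (5000, 10000)])
        pooled = estimate_poisson(10000, 20000)
        assert merged.lambda_hat == pooled.lambda_hat
        assert merged.cb_low == pooled.cb_low

    def test_merge_associativity(self):
        counts = [(3000, 9000), (2500, 8000), (4000, 11000)]
        a = merge_reactions(counts)
        b = merge_reactions([(5500, 17000), (4000, 11000)])
        assert a.lambda_hat == b.lambda_hat

    def test_merging_narrows_interval(self):
        single = estimate_poisson(5000, 10000)
        merged = merge_reactions([(5000, 10000)] * 4)
        assert merged.half_width < single.half_width

    def test_merged_replicates_recover_truth(self):
        lam = 0.7
        rng = np.random.default_rng(77)
        counts = [(int(rng.binomial(20000, np.exp(-lam))), 20000) for _ in range(4)]
        est = merge_reactions(counts)
        assert abs(est.lambda_hat - lam) < 3 * est.half_width / 1.96

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            merge_reactions([])


class TestGMRatio:
    def test_point_ratio(self):
        tr = estimate_poisson(int(20000 * np.exp(-0.15)), 20000)
        en = estimate_poisson(int(20000 * np.exp(-3.0)), 20000)
        ratio = gm_ratio(tr, en)
        assert ratio.r_gm == pytest.approx(0.05, rel=0.01)
        assert ratio.ci_low <= ratio.r_gm <= ratio.ci_high

    def test_zero_variance_collapses_to_point(self):
        tr = estimate_poisson(10000, 20000)
        en = estimate_poisson(5000, 20000)
        tr.cb_low = tr.cb_high = tr.lambda_hat
        en.cb_low = en.cb_high = en.lambda_hat
        ratio = gm_ratio(tr, en)
        assert ratio.ci_low == pytest.approx(ratio.r_gm)
        assert ratio.ci_high == pytest.approx(ratio.r_gm)

    def test_fieller_converges_to_delta_method(self):
        tr = estimate_poisson(12000, 200000)
        en = estimate_poisson(100000, 200000)
        ratio = gm_ratio(tr, en)
        r = ratio.r_gm
        se = r * np.sqrt(
            (tr.half_width / 1.96 / tr.lambda_hat) ** 2
            + (en.half_width / 1.96 / en.lambda_hat) ** 2
        )
        assert ratio.ci_high - ratio.ci_low == pytest.approx(2 * 1.96 * se, rel=0.01)

    def test_denominator_interval_reaching_zero_flags_unbounded(self):
        tr = estimate_poisson(10000, 20000)
        en = estimate_poisson(199, 200)  # lambda tiny, CI includes 0
        ratio = gm_ratio(tr, en)
        assert ratio.unbounded
        assert np.isinf(ratio.ci_high)


class TestReplicateCI:
    def test_hand_computed_example(self):
        stats = replicate_ci([9, 10, 11, 10])
        assert stats.mean == 10.0
        assert stats.sd == pytest.approx(np.sqrt(2 / 3), abs=1e-12)
        assert stats.ci_low == pytest.approx(10 - 1.96 * np.sqrt(2 / 3))
        assert stats.ci_high == pytest.approx(10 + 1.96 * np.sqrt(2 / 3))

    def test_identical_values_zero_width(self):
        stats = replicate_ci([2.5, 2.5, 2.5])
        assert stats.ci_low == stats.ci_high == 2.5

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            replicate_ci([1.0])


class TestCoverage:
    def test_trivial_cases(self):
        whole_line = [(-np.inf, np.inf)] * 5
        assert coverage_assessment(whole_line, 0.7) == 1.0
        misses = [(0.0, 0.1), (0.2, 0.3)]
        assert coverage_assessment(misses, 0.7) == 0.0

    def test_nominal_intervals_cover_at_rate(self, rng):
        lam, n = 1.0, 20000
        intervals = []
        for _ in range(800):
            n_neg = rng.binomial(n, np.exp(-lam))
            est = estimate_poisson(n_neg, n)
            intervals.append((est.cb_low, est.cb_high))
        cov = coverage_assessment(intervals, lam)
        se = np.sqrt(0.95 * 0.05 / 800)
        assert abs(cov - 0.95) < 4 * se


class TestMassConversion:
    def test_unit_case(self):
        assert mass_to_copies(1.0, 1.0) == 1000.0

    def test_soy_order_of_magnitude(self):
        # 30 ng at a soy 1C value of ~1.13 pg is ~26500 haploid copies
        assert mass_to_copies(30.0, 1.13) == pytest.approx(26549, rel=1e-3)

    @given(
        mass=st.floats(1e-3, 1e3, allow_nan=False),
        c_value=st.floats(0.1, 40.0, allow_nan=False),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_round_trip(self, mass, c_value):
        assert copies_to_mass(mass_to_copies(mass, c_value), c_value) == pytest.approx(
            mass, rel=1e-12
        )


@given(
    n_total=st.integers(100, 50000),
    frac=st.floats(0.01, 0.99),
)
@settings(deadline=None, max_examples=100, derandomize=True)
def test_poisson_estimate_invariants(n_total, frac):
    n_neg = max(1, int(frac * n_total))
    est = estimate_poisson(n_neg, n_total)
    assert est.p0_hat == pytest.approx(n_neg / n_total)
    assert est.cb_low <= est.lambda_hat <= est.cb_high
    assert est.lambda_hat == pytest.approx(-np.log(est.p0_hat))
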