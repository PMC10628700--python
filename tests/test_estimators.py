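"""Univariable estimators against closed-form and search oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from cismr.estimators import (
    egger,
    ivw,
    leave_one_out,
    max_likelihood,
    ratio_estimates,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)


def random_set(make_harmonized, seed, j=6, theta=0.1):
    rng = np.random.default_rng(seed)
    bx = rng.normal(0.3, 0.08, j)
    sx = np.full(j, 0.01)
    sy = rng.uniform(0.005, 0.02, j)
    by = theta * bx + rng.normal(0, sy)
    return make_harmonized(bx, sx, by, sy)


class TestRatios:
    def test_direct_formula(self, make_harmonized):
        h = make_harmonized([0.1, 0.2], [0.01, 0.01], [0.02, 0.04], [0.01, 0.01])
        r = ratio_estimates(h)
        np.testing.assert_allclose(r.ratio, [0.2, 0.2])
        np.testing.assert_allclose(r.ratio_se, [0.1, 0.05])
        np.testing.assert_allclose(r.weight, [100.0, 400.0])

    def test_single_snp_wald_ratio(self, make_harmonized):
        h = make_harmonized([0.3], [0.01], [0.06], [0.02])
        e = wald_ratio(h)
        assert e.beta == pytest.approx(0.2)
        assert e.se == pytest.approx(0.0667, abs=1e-4)

    @given(st.integers(0, 1000))
    def test_weight_times_se_squared_is_one(self, seed):
        rng = np.random.default_rng(seed)
        j = int(rng.integers(2, 12))
        from cismr.sumstats import HarmonizedSet

        bx = rng.uniform(0.05, 0.6, j) * rng.choice([-1, 1], j)
        h = HarmonizedSet(
            variants=[f"v{i}" for i in range(j)],
            exposure_betas=bx,
            exposure_ses=np.full(j, 0.01),
            outcome_betas=rng.normal(0, 0.05, j),
            outcome_ses=rng.uniform(0.001, 0.05, j),
        )
        r = ratio_estimates(h)
        np.testing.assert_allclose(r.weight * r.ratio_se**2, 1.0, rtol=1e-12)

    def test_zero_exposure_beta_names_variant(self, make_harmonized):
        h = make_harmonized([0.1, 0.0], [0.01, 0.01], [0.01, 0.01], [0.01, 0.01])
        with pytest.raises(ValueError, match="rs2"):
            ratio_estimates(h)


class TestIVW:
    # frozen oracle values computed from an independent weighted-least-squares
    # solve of the 3-SNP example (weights (bx/sy)^2)
    def test_three_snp_example(self, make_harmonized):
        h = make_harmonized([0.30, 0.25, 0.20], [0.01] * 3, [0.030, 0.020, 0.024], [0.02, 0.02, 0.04])
        e = ivw(h, "multiplicative_random")
        assert e.beta == pytest.approx(0.0935385, abs=1e-6)
        assert e.se == pytest.approx(0.0496139, abs=1e-6)  # phi floored at 1
        assert e.q_stat == pytest.approx(0.0555, abs=2e-4)
        assert e.overdispersion_phi == 1.0

    def test_identical_ratios_give_exact_estimate(self, make_harmonized):
        h = make_harmonized([0.1, 0.2, 0.4], [0.01] * 3, [0.02, 0.04, 0.08], [0.01] * 3)
        e = ivw(h)
        assert e.beta == pytest.approx(0.2, abs=1e-14)
        assert e.q_stat == pytest.approx(0.0, abs=1e-18)

    def test_duplicating_snps_keeps_beta_doubles_q(self, make_harmonized):
        h1 = random_set(make_harmonized, 7)
        h2 = make_harmonized(
            np.tile(h1.exposure_betas, 2),
            np.tile(h1.exposure_ses, 2),
            np.tile(h1.outcome_betas, 2),
            np.tile(h1.outcome_ses, 2),
        )
        e1, e2 = ivw(h1), ivw(h2)
        assert e2.beta == pytest.approx(e1.beta, rel=1e-12)
        assert e2.q_stat == pytest.approx(2 * e1.q_stat, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_ratio_form_equals_zero_intercept_wls(self, make_harmonized, seed):
        h = random_set(make_harmonized, seed)
        e = ivw(h, "fixed")
        wls = sm.WLS(h.outcome_betas, h.exposure_betas, weights=1 / h.outcome_ses**2).fit()
        assert e.beta == pytest.approx(wls.params[0], abs=1e-10)

    def test_mre_se_never_below_fixed(self, make_harmonized):
        h = random_set(make_harmonized, 3)
        assert ivw(h, "multiplicative_random").se >= ivw(h, "fixed").se

    def test_single_snp_rejected(self, make_harmonized):
        with pytest.raises(ValueError, match="[Ww]ald"):
            ivw(make_harmonized([0.3], [0.01], [0.03], [0.01]))


class TestMaximumLikelihood:
    def test_vanishing_exposure_noise_equals_fixed_ivw(self, make_harmonized):
        h = make_harmonized([0.30, 0.25, 0.20], [1e-6] * 3, [0.030, 0.020, 0.024], [0.02, 0.02, 0.04])
        assert max_likelihood(h).beta == pytest.approx(ivw(h, "fixed").beta, abs=1e-4)

    def test_matches_grid_search_oracle(self, make_harmonized):
        h = make_harmonized([0.30, 0.25, 0.20], [0.01] * 3, [0.030, 0.020, 0.024], [0.02, 0.02, 0.04])
        grid = np.linspace(-0.5, 0.7, 240_001)
        bx, sx = h.exposure_betas, h.exposure_ses
        by, sy = h.outcome_betas, h.outcome_ses
        nll = 0.5 * np.sum(
            (by[None, :] - grid[:, None] * bx[None, :]) ** 2
            / (sy[None, :] ** 2 + grid[:, None] ** 2 * sx[None, :] ** 2),
            axis=1,
        )
        assert max_likelihood(h).beta == pytest.approx(grid[np.argmin(nll)], abs=1e-4)

    def test_exact_line_recovers_theta(self, make_harmonized):
        bx = np.array([0.2, 0.3, 0.4])
        h = make_harmonized(bx, [1e-5] * 3, 0.25 * bx, [1e-5] * 3)
        assert max_likelihood(h).beta == pytest.approx(0.25, abs=1e-6)


class TestWeightedMedian:
    def test_hand_interpolated_example(self, make_harmonized):
        # ratios [0.08, 0.10, 0.12], weights [156.25, 225, 25]:
        # cumulative standardized weights 0.1923, 0.6615 bracket 0.5
        est = weighted_median_point(np.array([0.08, 0.10, 0.12]), np.array([156.25, 225.0, 25.0]))
        assert est == pytest.approx(0.0931, abs=1e-4)

    def test_equal_weights_take_middle_ratio(self, make_harmonized):
        est = weighted_median_point(np.array([0.1, 0.2, 0.9]), np.ones(3))
        assert est == pytest.approx(0.2)

    def test_bootstrap_se_deterministic_per_seed(self, make_harmonized):
        h = random_set(make_harmonized, 2)
        e1 = weighted_median(h, n_boot=200, seed=9)
        e2 = weighted_median(h, n_boot=200, seed=9)
        e3 = weighted_median(h, n_boot=200, seed=10)
        assert e1.se == e2.se and e1.beta == e2.beta
        assert e3.se != e1.se
        assert e3.se == pytest.approx(e1.se, rel=0.5)  # same order of magnitude

    def test_requires_seed_and_minimum_j(self, make_harmonized):
        h = random_set(make_harmonized, 2)
        with pytest.raises(ValueError, match="seed"):
            weighted_median(h, n_boot=10)
        with pytest.raises(ValueError, match="J >= 3"):
            weighted_median(make_harmonized([0.1, 0.2], [0.01] * 2, [0.01, 0.02], [0.01] * 2), seed=1)


class TestEgger:
    def test_exact_line_with_intercept(self, make_harmonized):
        bx = np.array([0.2, 0.3, 0.4, 0.5])
        by = 0.05 + 0.2 * bx
        h = make_harmonized(bx, [0.01] * 4, by, [0.01, 0.02, 0.01, 0.02])
        e = egger(h)
        assert e.beta == pytest.approx(0.2, abs=1e-12)
        assert e.egger_intercept == pytest.approx(0.05, abs=1e-12)
        assert e.q_stat == pytest.approx(0.0, abs=1e-18)

    def test_no_pleiotropy_gives_null_intercept(self, make_harmonized):
        bx = np.array([0.2, 0.3, 0.4])
        h = make_harmonized(bx, [0.01] * 3, 0.2 * bx, [0.01] * 3)
        e = egger(h)
        assert e.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert e.egger_intercept_pvalue == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_statsmodels_wls(self, make_harmonized, seed):
        h = random_set(make_harmonized, seed)
        sign = np.sign(h.exposure_betas)
        x = sm.add_constant(h.exposure_betas * sign)
        wls = sm.WLS(h.outcome_betas * sign, x, weights=1 / h.outcome_ses**2).fit()
        e = egger(h)
        assert e.egger_intercept == pytest.approx(wls.params[0], abs=1e-10)
        assert e.beta == pytest.approx(wls.params[1], abs=1e-10)

    def test_orientation_invariance(self, make_harmonized):
        h = random_set(make_harmonized, 11)
        flipped = make_harmonized(-h.exposure_betas, h.exposure_ses, -h.outcome_betas, h.outcome_ses)
        assert egger(flipped).beta == pytest.approx(egger(h).beta, abs=1e-12)

    def test_constant_exposure_rejected(self, make_harmonized):
        h = make_harmonized([0.3, 0.3, 0.3], [0.01] * 3, [0.03, 0.02, 0.04], [0.01] * 3)
        with pytest.raises(ValueError, match="variance"):
            egger(h)


class TestLeaveOneOut:
    def test_identical_ratios_leave_estimate_unchanged(self, make_harmonized):
        h = make_harmonized([0.1, 0.2, 0.4], [0.01] * 3, [0.02, 0.04, 0.08], [0.01] * 3)
        full = ivw(h).beta
        for _, e in leave_one_out(h):
            assert e.beta == pytest.approx(full, abs=1e-14)

    def test_entry_count_and_sizes(self, make_harmonized):
        h = random_set(make_harmonized, 5, j=3)
        entries = leave_one_out(h)
        assert len(entries) == 3
        assert all(e.n_snps == 2 for _, e in entries)

    def test_outlier_shows_largest_shift(self, make_harmonized):
        rng = np.random.default_rng(12)
        bx = rng.normal(0.3, 0.03, 8)
        by = 0.1 * bx + rng.normal(0, 0.002, 8)
        by[4] = 1.0 * bx[4]  # gross outlier
        h = make_harmonized(bx, np.full(8, 0.002), by, np.full(8, 0.002))
        full = ivw(h).beta
        shifts = {v: abs(e.beta - full) for v, e in leave_one_out(h)}
        assert max(shifts, key=shifts.get) == h.variants[4]


class TestOddsRatio:
    def test_null_effect_is_or_one(self, make_harmonized):
        h = make_harmonized([0.3, 0.2], [0.01] * 2, [0.0, 0.0], [0.01] * 2)
        orv, lo, hi = to_odds_ratio(ivw(h))
        assert orv == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_closed_form(self, make_harmonized):
        from cismr.estimators import MREstimate

        e = MREstimate("ivw_mre", 0.0862, 0.02, 0.0862 - 1.96 * 0.02, 0.0862 + 1.96 * 0.02, 0.01, 5)
        orv, lo, hi = to_odds_ratio(e)
        assert orv == pytest.approx(1.090, abs=1e-3)
        assert lo == pytest.approx(1.048, abs=1e-3)
        assert hi == pytest.approx(1.133, abs=1e-3)

    def test_negative_beta_maps_below_one(self, make_harmonized):
        from cismr.estimators import MREstimate

        e = MREstimate("ivw_mre", -0.1, 0.02, -0.1392, -0.0608, 0.01, 5)
        orv, lo, hi = to_odds_ratio(e)
        assert orv < 1.0 and lo < orv < hi


class TestEquivariance:
    @pytest.mark.parametrize("c", [0.5, 2.0, -1.5])
    def test_exposure_scaling(self, make_harmonized, c):
        h = random_set(make_harmonized, 21)
        scaled = make_harmonized(c * h.exposure_betas, abs(c) * h.exposure_ses, h.outcome_betas, h.outcome_ses)
        assert ivw(scaled).beta == pytest.approx(ivw(h).beta / c, rel=1e-10)
        assert max_likelihood(scaled).beta == pytest.approx(max_likelihood(h).beta / c, rel=1e-5)
        assert weighted_median(scaled, 50, seed=1).beta == pytest.approx(
            weighted_median(h, 50, seed=1).beta / c, rel=1e-10
        )

    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_outcome_scaling(self, make_harmonized, c):
        h = random_set(make_harmonized, 22)
        scaled = make_harmonized(h.exposure_betas, h.exposure_ses, c * h.outcome_betas, c * h.outcome_ses)
        assert ivw(scaled).beta == pytest.approx(c * ivw(h).beta, rel=1e-10)
        assert egger(scaled).beta == pytest.approx(c * egger(h).beta, rel=1e-10)

    def test_permutation_invariance(self, make_harmonized):
        h = random_set(make_harmonized, 23)
        perm = np.random.default_rng(0).permutation(h.n_snps)
        hp = make_harmonized(
            h.exposure_betas[perm], h.exposure_ses[perm], h.outcome_betas[perm], h.outcome_ses[perm]
        )
        assert ivw(hp).beta == pytest.approx(ivw(h).beta, rel=1e-12)
        assert egger(hp).beta == pytest.approx(egger(h).beta, rel=1e-12)
        assert weighted_median_point(
            ratio_estimates(hp).ratio, ratio_estimates(hp).weight
        ) == pytest.approx(weighted_median_point(ratio_estimates(h).ratio, ratio_estimates(h).weight), rel=1e-12)
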