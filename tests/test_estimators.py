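"""Causal estimators: hand-computed oracles, invariances, seeded resampling."""

import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm

from gutmr import (
    EstimatorConfig,
    HarmonizedInstrumentSet,
    InsufficientInstrumentsError,
    SyntheticConfig,
    build_instrument_set,
    ivw,
    mr_egger,
    mr_presso,
    simulate_pair,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from gutmr.estimators import _weighted_median_core, _weighted_mode_core
from gutmr.exceptions import ConfigError, DegenerateInstrumentError

from conftest import make_stats, make_variant


class TestWaldRatio:
    def test_direct_formula(self):
        h = HarmonizedInstrumentSet.from_arrays([0.1], [0.02], [0.05], [0.01])
        r = wald_ratio(h.records[0])
        assert r.beta_ratio == pytest.approx(0.5)
        assert r.se_ratio == pytest.approx(0.1)
        assert r.weight == pytest.approx(100.0)

    def test_zero_outcome_effect(self):
        h = HarmonizedInstrumentSet.from_arrays([0.1], [0.02], [0.0], [0.01])
        assert wald_ratio(h.records[0]).beta_ratio == 0.0

    def test_zero_gamma_is_degenerate(self):
        rec = dataclasses.replace(
            HarmonizedInstrumentSet.from_arrays([0.1], [0.02], [0.0], [0.01]).records[0],
            gamma=0.0,
        )
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(rec)

    def test_second_order_se_exceeds_first_order(self):
        h = HarmonizedInstrumentSet.from_arrays([0.1], [0.02], [0.05], [0.01])
        first = wald_ratio(h.records[0], se_order=1).se_ratio
        second = wald_ratio(h.records[0], se_order=2).se_ratio
        assert second > first


class TestIvw:
    def test_hand_computed_weighted_mean(self, ivw_worked_set):
        est = ivw(ivw_worked_set, model="fixed")
        assert est.beta == pytest.approx(0.46, abs=1e-12)
        assert est.se == pytest.approx(125 ** -0.5, abs=1e-12)

    def test_single_record_rejected(self):
        h = HarmonizedInstrumentSet.from_arrays([0.1], [0.02], [0.05], [0.01])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(h)

    def test_one_dominant_weight_approaches_wald(self):
        # J = 2 with one weight -> infinity: the IVW limit is that SNP's ratio
        h = HarmonizedInstrumentSet.from_arrays(
            [1.0, 1.0], [0.01, 0.01], [0.5, 0.3], [1e-7, 10.0]
        )
        est = ivw(h, model="fixed")
        assert est.beta == pytest.approx(0.5, abs=1e-9)

    def test_order_and_signflip_invariance(self, simulated_hset):
        base = ivw(simulated_hset, model="fixed").beta
        rev = HarmonizedInstrumentSet(
            "e", "o", records=list(reversed(simulated_hset.records))
        )
        assert ivw(rev, model="fixed").beta == pytest.approx(base, abs=1e-12)
        flipped_records = [
            dataclasses.replace(r, gamma=-r.gamma, Gamma=-r.Gamma) if i % 2 else r
            for i, r in enumerate(simulated_hset.records)
        ]
        flipped = HarmonizedInstrumentSet("e", "o", records=flipped_records)
        assert ivw(flipped, model="fixed").beta == pytest.approx(base, abs=1e-12)

    def test_random_model_never_shrinks_se(self, simulated_hset):
        fixed = ivw(simulated_hset, model="fixed")
        random = ivw(simulated_hset, model="random")
        assert random.se >= fixed.se
        assert random.beta == pytest.approx(fixed.beta)

    def test_auto_picks_fixed_without_heterogeneity(self):
        h = HarmonizedInstrumentSet.from_arrays(
            [1.0, 1.0, 1.0], [0.01] * 3, [0.30, 0.31, 0.29], [0.1] * 3
        )
        assert ivw(h, model="auto").method == "IVW_fixed"


class TestEgger:
    def test_closed_form_wls(self, egger_worked_set):
        slope, intercept = mr_egger(egger_worked_set)
        assert slope.beta == pytest.approx(0.2, abs=1e-12)
        assert intercept.intercept == pytest.approx(0.01, abs=1e-12)

    def test_exact_proportionality_gives_zero_intercept(self):
        gamma = np.array([0.05, 0.1, 0.2, 0.4])
        h = HarmonizedInstrumentSet.from_arrays(
            gamma, [0.01] * 4, 0.3 * gamma, [0.02, 0.01, 0.03, 0.02]
        )
        slope, intercept = mr_egger(h)
        assert slope.beta == pytest.approx(0.3, abs=1e-10)
        assert intercept.intercept == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels_wls(self, simulated_hset):
        """Independent cross-check of the WLS normal equations."""
        slope, intercept = mr_egger(simulated_hset)
        sign = np.where(simulated_hset.gamma < 0, -1.0, 1.0)
        g, G = simulated_hset.gamma * sign, simulated_hset.Gamma * sign
        w = 1.0 / simulated_hset.sigma_y ** 2
        fit = sm.WLS(G, sm.add_constant(g), weights=w).fit()
        assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert intercept.intercept == pytest.approx(fit.params[0], abs=1e-10)
        # SE equals the statsmodels SE with the multiplicative scale floored at 1
        scale = max(1.0, np.sqrt(fit.mse_resid))
        assert slope.se == pytest.approx(fit.bse[1] / np.sqrt(fit.mse_resid) * scale, rel=1e-9)

    def test_slope_equals_ivw_with_intercept_constrained_to_zero(self, simulated_hset):
        # constrained-fit oracle: no-intercept WLS of Gamma on gamma IS the IVW slope
        g, G = simulated_hset.gamma, simulated_hset.Gamma
        w = 1.0 / simulated_hset.sigma_y ** 2
        constrained = sm.WLS(G, g, weights=w).fit().params[0]
        assert ivw(simulated_hset, model="fixed").beta == pytest.approx(constrained, abs=1e-12)

    def test_requires_three(self, ivw_worked_set):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(ivw_worked_set)


class TestWeightedMedian:
    def test_breakpoint_interpolation(self, median_worked_set, estimator_config):
        est = weighted_median(median_worked_set, estimator_config)
        # breakpoints 0.10, 0.35, 0.75 -> interpolate 0.5 between 0.5 and 0.9
        assert est.beta == pytest.approx(0.65, abs=1e-12)

    def test_equal_weights_match_interpolated_simple_median(self):
        rng = np.random.default_rng(2)
        b = rng.normal(0.3, 0.1, size=9)
        est = _weighted_median_core(b, np.ones_like(b))[0]
        # with equal weights the 0.5 point falls on the middle order statistic
        assert est == pytest.approx(np.median(b), abs=1e-12)

    def test_identical_ratios_small_bootstrap_se(self, estimator_config):
        h = HarmonizedInstrumentSet.from_arrays(
            [0.1, 0.2, 0.3], [1e-5] * 3, [0.05, 0.10, 0.15], [1e-5] * 3
        )
        est = weighted_median(h, estimator_config)
        assert est.beta == pytest.approx(0.5, abs=1e-9)
        assert est.se < 1e-3

    def test_bootstrap_reproducible_under_seed(self, simulated_hset):
        a = weighted_median(simulated_hset, EstimatorConfig(seed=5))
        b = weighted_median(simulated_hset, EstimatorConfig(seed=5))
        c = weighted_median(simulated_hset, EstimatorConfig(seed=6))
        assert a.se == b.se
        assert a.se != c.se


class TestWeightedMode:
    def test_dominant_cluster_wins(self, estimator_config):
        # three ratios at 0.5 carrying 90% of weight, one at 2.0
        w = np.array([3.0, 3.0, 3.0, 1.0])
        sy = 1.0 / np.sqrt(w)
        h = HarmonizedInstrumentSet.from_arrays(
            [1.0] * 4, [0.01] * 4, [0.5, 0.5, 0.5, 2.0], sy
        )
        est = weighted_mode(h, estimator_config)
        b = np.array([0.5, 0.5, 0.5, 2.0])
        grid_oracle = _weighted_mode_core(b, w, 1.0)[0]
        assert est.beta == pytest.approx(grid_oracle, abs=1e-12)
        assert abs(est.beta - 0.5) < 0.1

    def test_all_equal_returns_common_ratio(self, estimator_config):
        h = HarmonizedInstrumentSet.from_arrays(
            [0.1, 0.2, 0.4], [0.01] * 3, [0.07, 0.14, 0.28], [0.01, 0.02, 0.01]
        )
        est = weighted_mode(h, estimator_config)
        assert est.beta == pytest.approx(0.7, abs=1e-12)

    def test_bandwidth_scales_with_phi(self, simulated_hset):
        narrow = weighted_mode(simulated_hset, EstimatorConfig(seed=1, phi=0.5))
        wide = weighted_mode(simulated_hset, EstimatorConfig(seed=1, phi=2.0))
        assert narrow.beta != wide.beta or narrow.se != wide.se


class TestPresso:
    def test_null_global_p_not_extreme(self, estimator_config):
        exposure, outcome, _ = simulate_pair(SyntheticConfig(J=20, beta0=0.3, seed=314))
        hset = build_instrument_set(exposure, outcome)
        res = mr_presso(hset, estimator_config)
        assert res.global_pvalue > 0.05
        assert res.outlier_snps == []
        assert res.estimate_corrected is None
        assert res.estimate.beta == res.estimate_all.beta

    def test_injected_outlier_flagged_and_corrected(self, estimator_config):
        exposure, outcome, _ = simulate_pair(SyntheticConfig(J=20, beta0=0.3, seed=218))
        hset = build_instrument_set(exposure, outcome)
        recs = list(hset.records)
        target = recs[3]
        recs[3] = dataclasses.replace(target, Gamma=target.Gamma + 10 * target.sigma_y)
        contaminated = HarmonizedInstrumentSet("e", "o", records=recs)
        res = mr_presso(contaminated, estimator_config)
        assert target.snp_id in res.outlier_snps
        assert res.global_pvalue < 0.05
        assert res.estimate_corrected is not None
        clean_beta = ivw(hset, model="fixed").beta
        assert abs(res.estimate_corrected.beta - clean_beta) < abs(res.estimate_all.beta - clean_beta)
        assert res.distortion_pct is not None and res.distortion_pvalue is not None

    def test_p_values_never_zero(self, estimator_config):
        exposure, outcome, _ = simulate_pair(SyntheticConfig(J=10, beta0=0.0, seed=5))
        hset = build_instrument_set(exposure, outcome)
        res = mr_presso(hset, estimator_config)
        assert res.global_pvalue >= 1.0 / (estimator_config.presso_k + 1)
        assert all(p > 0 for p in res.outlier_pvalues.values())

    def test_reproducible_under_seed(self, simulated_hset):
        a = mr_presso(simulated_hset, EstimatorConfig(seed=8))
        b = mr_presso(simulated_hset, EstimatorConfig(seed=8))
        assert a.global_pvalue == b.global_pvalue and a.rss_obs == b.rss_obs

    def test_requires_four(self, egger_worked_set, estimator_config):
        with pytest.raises(InsufficientInstrumentsError):
            mr_presso(egger_worked_set, estimator_config)


class TestOddsRatio:
    def test_null_beta(self):
        orr, lo, hi = to_odds_ratio(0.0, 0.1)
        assert orr == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_published_style_transform(self):
        orr, lo, hi = to_odds_ratio(-0.4780, 0.1359)
        assert (round(orr, 3), round(lo, 3), round(hi, 3)) == (0.620, 0.475, 0.809)

    def test_se_recovered_from_ci_inversion(self):
        # inversion oracle: se implied by a printed (OR, CI) triple
        beta = np.log(0.746)
        implied_se = (np.log(0.891) - np.log(0.624)) / (2 * 1.959964)
        orr, lo, hi = to_odds_ratio(beta, implied_se)
        assert round(lo, 3) == 0.624 and round(hi, 3) == 0.891

    def test_negative_se_rejected(self):
        with pytest.raises(ConfigError):
            to_odds_ratio(0.1, -0.5)


def test_estimator_config_validation():
    with pytest.raises(ConfigError):
        EstimatorConfig(n_boot=10)
    with pytest.raises(ConfigError):
        EstimatorConfig(presso_k=10)
    with pytest.raises(ConfigError):
        EstimatorConfig(ivw_model="bayesian")
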