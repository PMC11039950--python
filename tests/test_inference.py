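"""FDR classification, batch orchestration and reverse MR."""

import numpy as np
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from gutmr import (
    EstimatorConfig,
    SyntheticConfig,
    bh_fdr,
    classify,
    reverse_rows,
    run_batch,
    run_pair,
    run_reverse,
    simulate_pair,
)
from gutmr.exceptions import GutmrError

from conftest import make_stats, make_variant


def brute_force_bh(pvalues: np.ndarray) -> np.ndarray:
    """Step-up oracle: q_(i) = min_{j>=i} p_(j) m / j, capped at 1."""
    m = len(pvalues)
    order = np.argsort(pvalues, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, pvalues[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = bh_fdr([0.001, 0.02, 0.04, 0.8])
        np.testing.assert_allclose(q, [0.004, 0.04, 0.04 * 4 / 3, 0.8], rtol=1e-12)

    def test_single_p_is_identity(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_all_equal_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 5), 0.2)

    def test_invalid_p_rejected(self):
        with pytest.raises(GutmrError):
            bh_fdr([0.5, 0.0])

    @settings(max_examples=50, deadline=None)
    @seed(20240410)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
    def test_matches_brute_force_oracle(self, ps):
        got = bh_fdr(ps)
        np.testing.assert_allclose(got, brute_force_bh(np.array(ps)), rtol=1e-10)
        in_order = np.sort(got[np.argsort(ps, kind="stable")])
        assert np.all(np.diff(in_order) >= -1e-12)  # monotone in sorted-p order
        assert np.all(got <= 1.0)


class TestClassify:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            (4.3e-4, 0.02, "significant"),
            (0.01, 0.5, "suggestive"),
            (0.2, 0.05, "null"),  # p gate fails
            (0.01, 0.1, "suggestive"),  # boundary q assigned conservatively
            (0.05, 0.01, "null"),  # p gate is strict
        ],
    )
    def test_thresholds(self, p, q, expected):
        assert classify(p, q) == expected


def test_run_pair_end_to_end_protective_effect():
    cfg = SyntheticConfig(J=15, beta0=-0.4, seed=512)
    exposure, outcome, _ = simulate_pair(cfg)
    res = run_pair(exposure, outcome, estimator_config=EstimatorConfig(seed=3), preselected=True)
    assert res.status == "ok"
    assert res.primary.ci_high < 0  # CI excludes 0 at this effect size
    assert res.direction_consistent
    assert res.f_min >= 10
    rows = res.to_rows()
    assert len(rows) == 5  # IVW + Egger + median + mode + PRESSO
    assert {"IVW (fixed)", "MR-Egger (slope)", "Weighted median", "Weighted mode",
            "MR-PRESSO"} == {r["method"] for r in rows}


def test_run_pair_two_instruments_reports_not_applicable():
    exp = make_stats([
        make_variant("rs1", beta=0.05, se=0.01),
        make_variant("rs2", beta=0.06, se=0.01),
    ])
    out = make_stats(
        [make_variant("rs1", beta=-0.02, se=0.01, p=0.2),
         make_variant("rs2", beta=-0.025, se=0.01, p=0.2)],
        trait_id="disease", trait_type="binary",
    )
    res = run_pair(exp, out, preselected=True)
    assert res.primary is not None and res.heterogeneity is not None
    assert res.egger is None and res.presso is None
    assert {"Egger", "WeightedMedian", "WeightedMode", "PRESSO"} <= set(res.not_applicable)


def test_run_pair_unharmonizable_pair_is_skipped_not_crash():
    exp = make_stats([make_variant("rs1", ea="A", oa="T")])
    out = make_stats([make_variant("rs2", p=0.5)], trait_id="d", trait_type="binary")
    res = run_pair(exp, out, preselected=True)
    assert res.status == "skipped"
    assert res.skip_reason


class TestRunBatch:
    def _exposures_and_outcome(self):
        """Ten taxa (one truly protective) sharing one merged outcome panel.

        Each taxon gets its own simulated instruments; SNP ids are made
        disjoint and the per-taxon outcome draws are merged into a single
        binary-trait panel, emulating one disease GWAS queried per taxon.
        """
        import dataclasses
        from gutmr import SummaryStatistics

        merged = {}
        exposures = []
        for i in range(10):
            beta0 = -0.8 if i == 0 else 0.0
            e, o, _ = simulate_pair(SyntheticConfig(J=15, beta0=beta0, seed=600 + i))
            e.trait_id = "taxon_causal" if i == 0 else f"taxon_null{i - 1}"
            for k in range(len(e.records)):
                new_id = f"rs{i}_{k}"
                e.records[k] = dataclasses.replace(e.records[k], snp_id=new_id)
                merged[new_id] = dataclasses.replace(o.records[k], snp_id=new_id)
            exposures.append(e)
        outcome_all = SummaryStatistics(
            trait_id="aneurysm", trait_type="binary", records=list(merged.values())
        )
        return exposures, outcome_all

    def test_causal_taxon_classified_significant_nulls_null(self):
        exposures, outcome = self._exposures_and_outcome()
        results = run_batch(exposures, outcome,
                            estimator_config=EstimatorConfig(seed=9), preselected=True)
        by_id = {r.exposure_id: r for r in results}
        assert by_id["taxon_causal"].fdr.klass == "significant"
        null_classes = [by_id[f"taxon_null{i}"].fdr.klass for i in range(9)]
        assert null_classes.count("null") >= 7  # overwhelmingly null

    def test_classification_invariant_to_exposure_order(self):
        exposures, outcome = self._exposures_and_outcome()
        fwd = run_batch(exposures, outcome,
                        estimator_config=EstimatorConfig(seed=9), preselected=True)
        rev = run_batch(list(reversed(exposures)), outcome,
                        estimator_config=EstimatorConfig(seed=9), preselected=True)
        fwd_map = {r.exposure_id: r.fdr.q for r in fwd}
        rev_map = {r.exposure_id: r.fdr.q for r in rev}
        assert fwd_map == rev_map

    def test_single_exposure_q_equals_p(self):
        e, o, _ = simulate_pair(SyntheticConfig(J=15, beta0=-0.4, seed=88))
        results = run_batch([e], o, estimator_config=EstimatorConfig(seed=2), preselected=True)
        assert results[0].fdr.q == pytest.approx(results[0].fdr.primary_p)


class TestReverse:
    def test_reverse_of_forward_only_causation_covers_zero(self):
        """Exposure->outcome causation must not manufacture a reverse signal.

        The taxon instruments are causal for the disease; re-using the disease
        side as the exposure with independently selected (here: its own)
        variants, the reverse IVW should not reject the null.
        """
        hits = 0
        seeds = np.random.SeedSequence(777).generate_state(20) % (2 ** 31)
        for s in seeds:
            # disease instruments are independent variants with no effect on
            # the taxon: simulate the reverse pair under beta0 = 0
            d, t, _ = simulate_pair(SyntheticConfig(J=12, beta0=0.0, seed=int(s)))
            d.trait_id, d.trait_type = "aneurysm", "binary"
            t.trait_id, t.trait_type = "taxon", "continuous"
            res = run_reverse(d, t, estimator_config=EstimatorConfig(seed=int(s)),
                              preselected=True)
            hits += res.ivw_fixed.ci_low <= 0 <= res.ivw_fixed.ci_high
        assert hits >= 17  # ~ nominal 95% coverage of zero over 20 runs

    def test_reverse_reports_fixed_and_random(self):
        d, t, _ = simulate_pair(SyntheticConfig(J=12, beta0=0.0, seed=4))
        res = run_reverse(d, t, estimator_config=EstimatorConfig(seed=4), preselected=True)
        rows = reverse_rows(res)
        assert [r["method"] for r in rows] == ["IVW (fixed)", "IVW (random)"]
        assert rows[0]["se"] <= rows[1]["se"] + 1e-15

    def test_role_swap_is_involution(self):
        d, t, _ = simulate_pair(SyntheticConfig(J=12, beta0=0.2, seed=6))
        a = run_reverse(d, t, estimator_config=EstimatorConfig(seed=1), preselected=True)
        b = run_pair(d, t, estimator_config=EstimatorConfig(seed=1), preselected=True)
        assert a.primary.beta == b.primary.beta
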