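import numpy as np
import pytest
from _oracles import exact_ranksum_p, logrank_chi2, pair_count_auc
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import kstest

from cartqsp import (
    ccs,
    cohort_ccs_table,
    cox_hr,
    group_compare,
    hr_to_risk_reduction,
    kinetic_metrics,
    km_logrank,
    pearson_r,
    roc_cutoff,
)


class TestKineticMetrics:
    def test_hand_trapezoid(self):
        m = kinetic_metrics([0, 7, 14, 28], [0.4, 5, 10, 2], basis="observed")
        assert m.cmax == 10.0
        assert m.tmax == 14.0
        assert m.auc_0_28 == pytest.approx(155.4)

    def test_anchored_at_imputed_dose(self):
        m = kinetic_metrics([7, 14, 28], [5, 10, 2], basis="observed")
        assert m.auc_0_28 == pytest.approx(155.4)

    def test_constant_series(self):
        t = np.linspace(0, 28, 57)
        m = kinetic_metrics(t, np.full_like(t, 3.0), basis="model")
        assert m.auc_0_28 == pytest.approx(28 * 3.0)
        assert m.tmax == 0.0  # earliest argmax

    def test_model_and_observed_agree_on_same_grid(self):
        t = np.linspace(0, 40, 401)
        c = 5 * np.exp(-((t - 12.0) ** 2) / 30.0) + 0.4
        mo = kinetic_metrics(t, c, basis="model")
        ob = kinetic_metrics(t, c, basis="observed")
        assert ob.auc_0_28 == pytest.approx(mo.auc_0_28, rel=1e-3)
        assert ob.cmax == mo.cmax and ob.tmax == mo.tmax

    def test_truncation_beyond_horizon(self):
        m = kinetic_metrics([0, 14, 56], [1.0, 1.0, 1.0], basis="model")
        assert m.auc_0_28 == pytest.approx(28.0)

    def test_cmax_over_mtv(self):
        m = kinetic_metrics([0, 14], [0.4, 10.0], basis="observed", baseline_mtv=100.0)
        assert m.cmax_over_mtv == pytest.approx(0.1)

    def test_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            kinetic_metrics([], [])
        with pytest.raises(ValueError):
            kinetic_metrics([0, 1], [1.0, -2.0])


class TestCcs:
    def test_basic_ratio(self):
        assert ccs(10.0, 100.0).score == pytest.approx(0.1)
        assert ccs(0.0, 100.0).score == 0.0

    def test_cutoff_flag(self):
        res = ccs(0.002 * 50, 50.0, cutoff=0.00136)
        assert res.score == pytest.approx(0.002)
        assert res.exceeds_cutoff is True

    def test_rejects_nonpositive_mtv(self):
        with pytest.raises(ValueError):
            ccs(1.0, 0.0)

    @given(st.floats(0.01, 100.0), st.floats(0.1, 1000.0), st.floats(0.1, 10.0))
    def test_homogeneity_degrees(self, cmax, mtv, k):
        base = ccs(cmax, mtv).score
        assert ccs(k * cmax, mtv).score == pytest.approx(k * base, rel=1e-12)
        assert ccs(cmax, k * mtv).score == pytest.approx(base / k, rel=1e-12)


class TestRocCutoff:
    def test_perfect_separation(self):
        res = roc_cutoff([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert 3 < res.cutoff <= 10

    def test_null_scores_auc_half(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        res = roc_cutoff(scores, labels)
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_toy_auc_equals_pair_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.65, 0.2]
        labels = [0, 0, 1, 1, 1, 0]
        res = roc_cutoff(scores, labels)
        assert res.auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_trapezoid_equals_pair_counting_tie_free(self, rng):
        for _ in range(10):
            scores = rng.normal(size=12)
            labels = rng.permutation([0] * 6 + [1] * 6)
            res = roc_cutoff(scores, labels)
            assert res.auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_youden_at_reported_operating_point(self):
        scores = [1, 2, 3, 4, 10, 11, 12, 13]
        labels = [0, 0, 0, 1, 1, 1, 1, 1]
        res = roc_cutoff(scores, labels)
        fpr = 1 - res.specificity
        assert res.sensitivity - fpr == pytest.approx(1.0)

    def test_rejects_single_class(self):
        with pytest.raises(ValueError):
            roc_cutoff([1, 2, 3], [1, 1, 1])


class TestKmLogrank:
    def test_no_events_survival_one_median_not_reached(self):
        res = km_logrank([5, 6, 7, 8], [0, 0, 0, 0], ["A", "A", "B", "B"])
        for g in res.groups:
            assert g.median is None
            assert np.allclose(g.survival, 1.0)

    def test_six_subject_hand_oracle(self):
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 1, 1, 1, 1, 1]
        groups = ["A", "B", "A", "B", "A", "B"]
        res = km_logrank(times, events, groups)
        assert res.statistic == pytest.approx(logrank_chi2(times, events, groups), rel=1e-9)

    def test_km_equals_empirical_survival_without_censoring(self):
        times = [2.0, 4.0, 4.0, 7.0, 9.0]
        res = km_logrank(times + [1.0], [1] * 5 + [1], ["A"] * 5 + ["B"])
        g = next(g for g in res.groups if g.label == "A")
        for t, s in zip(g.times, g.survival):
            emp = np.mean(np.asarray(times) > t)
            assert s == pytest.approx(emp, abs=1e-12)

    def test_null_p_uniform_under_random_splits(self, rng):
        pvals = []
        for _ in range(200):
            t = rng.exponential(10.0, size=40)
            groups = rng.permutation([0] * 20 + [1] * 20)
            res = km_logrank(t, np.ones(40, dtype=int), groups)
            pvals.append(res.pvalue)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_three_groups_pairwise(self):
        times = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        groups = ["A", "B", "C"] * 3
        res = km_logrank(times, [1] * 9, groups)
        assert res.pairwise is not None
        assert len(res.pairwise) == 3

    def test_rejects_single_group(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2], [1, 1], ["A", "A"])


class TestCoxHr:
    def test_null_covariate_hr_near_one(self, rng):
        t = rng.exponential(10.0, size=400)
        x = rng.integers(0, 2, size=400)
        res = cox_hr(t, np.ones(400, dtype=int), x)
        assert 0.8 < res.hr < 1.25

    def test_known_rate_ratio_recovered(self, rng):
        n = 500
        x = np.repeat([0, 1], n // 2)
        t = np.where(x == 1, rng.exponential(1 / 4.0, n), rng.exponential(1.0, n))
        res = cox_hr(t, np.ones(n, dtype=int), x)
        assert 3.0 <= res.hr <= 5.3
        assert res.ci_low < 4.0 < res.ci_high

    def test_relabeling_inverts_hr(self, rng):
        t = rng.exponential(5.0, size=100)
        x = rng.integers(0, 2, size=100)
        e = np.ones(100, dtype=int)
        a = cox_hr(t, e, x)
        b = cox_hr(t, e, 1 - x)
        assert a.hr == pytest.approx(1.0 / b.hr, rel=1e-6)

    def test_separation_flagged(self):
        t = [1, 2, 3, 10, 11, 12]
        e = [1, 1, 1, 0, 0, 0]
        x = [0, 0, 0, 1, 1, 1]
        res = cox_hr(t, e, x)
        assert res.separation_flag


class TestHrToRiskReduction:
    @pytest.mark.parametrize("hr,expected", [(1.0, 0), (0.17, 83), (0.12, 88)])
    def test_values(self, hr, expected):
        assert hr_to_risk_reduction(hr) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            hr_to_risk_reduction(0.0)


class TestGroupCompareAndCorrelation:
    def test_identical_groups_p_near_one(self):
        _, p = group_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.8

    def test_four_vs_four_matches_enumeration(self, rng):
        for _ in range(5):
            a = rng.normal(size=4)
            b = rng.normal(loc=0.5, size=4)
            _, p = group_compare(a, b)
            assert p == pytest.approx(exact_ranksum_p(a, b), abs=1e-12)

    def test_exact_linear_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, _ = pearson_r(x, [2 * v for v in x])
        assert r == pytest.approx(1.0)

    def test_log_scale_power_law(self):
        x = np.array([1.0, 10.0, 100.0, 1000.0])
        r, _ = pearson_r(x, x**2.0, log_scale=True)
        assert r == pytest.approx(1.0)

    def test_rejects_constant_input(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestEndToEndChain:
    """CCS computed from observed Cmax separates the expansion subpopulations
    and its Youden cut-off stratifies survival — the qualitative prediction
    chain, on synthetic data with known truth."""

    def test_ccs_separates_subpopulations(self, chain_cohort):
        tab = cohort_ccs_table(chain_cohort, "TN")
        labels = np.array(
            [1 if chain_cohort.truth[p]["subpop"] == "low" else 0 for p in tab.patient_id]
        )
        res = roc_cutoff(-tab.ccs.to_numpy(), labels)  # low CCS marks low expansion
        assert res.auc > 0.8

    def test_youden_cutoff_stratifies_survival(self, chain_cohort):
        tab = cohort_ccs_table(chain_cohort, "TN")
        labels = np.array(
            [1 if chain_cohort.truth[p]["subpop"] == "low" else 0 for p in tab.patient_id]
        )
        res = roc_cutoff(-tab.ccs.to_numpy(), labels)
        cutoff = -res.cutoff
        surv = chain_cohort.survival.set_index("patient_id").loc[tab.patient_id]
        above = (tab.ccs.to_numpy() > cutoff).astype(int)
        cox = cox_hr(surv.time_months, surv.event, above)
        assert cox.hr < 1.0

    def test_ccs_correlates_with_expansion_capacity(self, chain_cohort):
        tab = cohort_ccs_table(chain_cohort, "TN")
        vmax1 = np.array([chain_cohort.truth[p]["Vmax1_i"] for p in tab.patient_id])
        r, p = pearson_r(vmax1, tab.ccs.to_numpy(), log_scale=True)
        assert r > 0.5 and p < 1e-6
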