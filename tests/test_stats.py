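"""Statistical battery: exact oracles, printed-table anchors, survival."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from periscore.stats import (
    _cox_loglik, chi_square_test, cox_fit, expected_counts, fisher_exact_test,
    kaplan_meier, kruskal_wallis, log_offset_transform, log_rank_test,
    median_follow_up, paired_t_test, pearson_log_correlation,
    run_association_battery, select_association_test, two_sample_t_test)
from periscore.types import SurvivalRecord


def _fisher_2x2_enumeration(a, b, c, d):
    """Independent oracle: two-sided Fisher p by direct hypergeometric
    enumeration over the support of the top-left cell."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1, exact=True)
    probs = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[k] = comb(r1, k, exact=True) * comb(r2, c1 - k, exact=True) / denom
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestContingency:
    # 2x2 cross-tabulations printed in the study's clinicopathological
    # association tables (marker low/high x feature level)
    PRINTED = [
        ([[52, 62], [16, 6]], 0.036),   # GZMB x pT3/pT4, validation cohort
        ([[36, 44], [13, 4]], 0.037),   # GZMB x cM
        ([[19, 32], [26, 11]], 0.004),  # GZMB x venous invasion
        ([[32, 41], [13, 2]], 0.006),   # GZMB x perineural invasion
        ([[17, 33], [27, 11]], 0.001),  # CD8 x lymphatic invasion
    ]

    @pytest.mark.parametrize("table,expected_p", PRINTED)
    def test_yates_chi_square_reproduces_printed_p(self, table, expected_p):
        res = chi_square_test(table)
        assert res.continuity_correction
        assert round(res.p_value, 3) == expected_p

    def test_yates_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = rng.integers(1, 40, size=(2, 2)).astype(float)
            e = expected_counts(t)
            # correction is clamped so it never overshoots past zero
            stat = np.sum(np.maximum(np.abs(t - e) - 0.5, 0.0) ** 2 / e)
            assert chi_square_test(t).statistic == pytest.approx(stat, abs=1e-10)

    def test_perfect_independence(self):
        res = chi_square_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_uncorrected_for_larger_tables(self):
        res = chi_square_test([[10, 20], [30, 10], [15, 15]])
        assert not res.continuity_correction
        assert res.degrees_of_freedom == 2

    def test_zero_margin_degenerate(self):
        with pytest.warns(UserWarning):
            res = chi_square_test([[0, 0], [10, 10]])
        assert res.p_value == 1.0 and "zero_margin" in res.flags

    def test_fisher_small_table_exact_fraction(self):
        res = fisher_exact_test([[3, 1], [1, 3]])
        assert res.p_value == pytest.approx(34 / 70, abs=1e-12)

    def test_fisher_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            t = rng.integers(0, 25, size=4)
            if t[:2].sum() == 0 or t[2:].sum() == 0:
                continue
            p_pkg = fisher_exact_test(t.reshape(2, 2)).p_value
            p_ora = _fisher_2x2_enumeration(*t)
            assert p_pkg == pytest.approx(p_ora, rel=1e-9)

    def test_fisher_all_zero_row(self):
        res = fisher_exact_test([[0, 0], [5, 7]])
        assert res.p_value == 1.0

    def test_fisher_rxc_matches_R(self):
        # fisher.test(matrix(c(25,16,7,36,9,2),nrow=3))$p.value in R 4.3.3
        res = fisher_exact_test([[25, 36], [16, 9], [7, 2]])
        assert res.p_value == pytest.approx(0.03788267, abs=5e-8)

    def test_selection_rule(self):
        assert select_association_test([[52, 62], [16, 6]]).method == "chi_square"
        assert np.min(expected_counts([[2, 8], [9, 1]])) < 5
        assert select_association_test([[2, 8], [9, 1]]).method == "fisher_exact"
        with pytest.raises(ValueError):
            select_association_test([[3], [4]])


class TestScaleComparisons:
    def test_log_offset_values(self):
        assert log_offset_transform(0.0) == pytest.approx(0.0)
        assert log_offset_transform(math.e - 1) == pytest.approx(1.0)
        x = np.linspace(0, 50, 100)
        assert np.all(np.diff(log_offset_transform(x)) > 0)
        with pytest.raises(ValueError):
            log_offset_transform(-1.0)

    def test_paired_t_identical(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_paired_t_constant_shift_degenerate(self):
        res = paired_t_test([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert res.p_value == 0.0
        assert "zero_variance_nonzero_mean" in res.flags

    def test_paired_t_power_under_shift(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            paired_t_test(rng.normal(1.0, 1.0, 50), rng.normal(0.0, 1.0, 50)).p_value < 0.05
            for _ in range(200))
        assert rejections >= 198  # power > 99% at delta = 1 sd, n = 50

    def test_pearson_log_extremes(self):
        a = np.array([0.0, 10.0, 100.0, 5.0, 60.0])
        r, _ = pearson_log_correlation(a, a)
        assert r == pytest.approx(1.0)
        # b >= 0 with log(b+1) = C - log(a+1): perfectly anti-correlated
        C = np.log(a.max() + 1.0)
        b = np.exp(C - np.log(a + 1.0)) - 1.0
        r2, _ = pearson_log_correlation(a, b)
        assert r2 == pytest.approx(-1.0, abs=1e-9)

    def test_pearson_null_small(self):
        rng = np.random.default_rng(3)
        r, _ = pearson_log_correlation(rng.uniform(0, 100, 1000),
                                       rng.uniform(0, 100, 1000))
        assert abs(r) < 0.1

    def test_two_sample_t_symmetric(self):
        res = two_sample_t_test([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert res.statistic == 0.0

    def test_kruskal_wallis_matches_permutation_oracle(self):
        from itertools import combinations

        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = kruskal_wallis(a, b)
        pooled = a + b
        h_obs = res.statistic
        # permutation oracle: all 3-subsets as group A
        count = total = 0
        for idx in combinations(range(6), 3):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(6) if i not in idx]
            h = kruskal_wallis(ga, gb).statistic
            total += 1
            count += h >= h_obs - 1e-12
        # chi2 approximation is anti-conservative here; exact p = 2/20
        assert count / total == pytest.approx(0.1)
        assert res.p_value < 0.06

    def test_identical_groups_null(self):
        assert two_sample_t_test([1.0, 2.0], [1.0, 2.0]).p_value == 1.0
        res = kruskal_wallis([2.0, 2.0], [2.0, 2.0])
        assert res.statistic == 0.0 and res.p_value == 1.0
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0])


def _recs(times, events):
    return [SurvivalRecord(f"P{i}", float(t), int(e))
            for i, (t, e) in enumerate(zip(times, events))]


class TestSurvival:
    def test_km_no_events(self):
        kmf = kaplan_meier(_recs([5, 10, 15], [0, 0, 0]))
        assert float(kmf.survival_function_at_times(15.0).iloc[0]) == 1.0

    def test_km_product_limit_by_hand(self):
        kmf = kaplan_meier(_recs([1, 2], [1, 1]))
        assert float(kmf.survival_function_at_times(1.0).iloc[0]) == pytest.approx(0.5)
        assert float(kmf.survival_function_at_times(2.0).iloc[0]) == pytest.approx(0.0)

    def test_km_censoring_before_event(self):
        # early censoring shrinks the risk set but leaves S unchanged
        kmf = kaplan_meier(_recs([1, 2, 3], [0, 0, 1]))
        assert float(kmf.survival_function_at_times(2.5).iloc[0]) == 1.0
        assert float(kmf.survival_function_at_times(3.0).iloc[0]) == 0.0

    def test_km_monotone_non_increasing(self):
        rng = np.random.default_rng(2)
        recs = _recs(rng.exponential(10, 40), rng.integers(0, 2, 40))
        if not any(r.event for r in recs):
            recs[0].event = 1
        s = kaplan_meier(recs).survival_function_["KM_estimate"].to_numpy()
        assert np.all(np.diff(s) <= 1e-12)
        assert s[0] <= 1.0

    def test_median_follow_up_reverse_km(self):
        # all censored at t: follow-up median is t
        assert median_follow_up(_recs([49, 49, 49], [0, 0, 0])) == pytest.approx(49)

    def test_logrank_symmetry_and_relabel(self):
        recs = _recs([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        g = ["a"] * 3 + ["b"] * 3
        res = log_rank_test(recs, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        res2 = log_rank_test(recs, ["b"] * 3 + ["a"] * 3)
        assert res2.statistic == pytest.approx(res.statistic, abs=1e-12)

    def test_logrank_hand_computation(self):
        # group A events at 1,2; group B at 3,4; no censoring
        # O_A - E_A = (1-1/2) + (1-1/3) = 7/6; Var = 1/4 + 2/9 = 17/36
        recs = _recs([1, 2, 3, 4], [1, 1, 1, 1])
        res = log_rank_test(recs, ["A", "A", "B", "B"])
        expected = (7 / 6) ** 2 / (17 / 36)
        assert res.statistic == pytest.approx(expected, rel=1e-9)

    def test_logrank_equals_cox_score_test(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(10, 60)  # continuous: no ties
        e = np.ones(60, dtype=int)
        x = rng.integers(0, 2, 60)
        recs = _recs(t, e)
        lr = log_rank_test(recs, x)
        _, grad, hess = _cox_loglik(np.zeros(1), t, e,
                                    x.reshape(-1, 1).astype(float), "efron")
        score_stat = float(grad @ np.linalg.solve(-hess, grad))
        assert score_stat == pytest.approx(lr.statistic, abs=1e-6)

    def test_cox_matches_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 200
        x = rng.integers(0, 2, n)
        age = rng.normal(0, 1, n)
        t = rng.exponential(1 / (0.02 * np.exp(np.log(0.25) * x + 0.2 * age)))
        c = rng.exponential(80, n)
        obs, ev = np.minimum(t, c), (t <= c).astype(int)
        recs = [SurvivalRecord(f"P{i}", float(max(obs[i], 1e-3)), int(ev[i]),
                               covariates={"x": int(x[i]), "age": float(age[i])})
                for i in range(n)]
        fit = cox_fit(recs, ["x", "age"])
        ref = CoxPHFitter().fit(
            pd.DataFrame({"T": obs, "E": ev, "x": x, "age": age}), "T", "E")
        assert fit.converged
        np.testing.assert_allclose(fit.coef, ref.params_[["x", "age"]], atol=1e-3)
        np.testing.assert_allclose(fit.se, ref.standard_errors_[["x", "age"]], atol=1e-3)
        lo, hi = fit.conf_int[0]
        assert lo <= fit.hazard_ratios[0] <= hi

    @pytest.mark.parametrize("ties,beta_ref,se_ref", [
        # R 4.3.3 survival::coxph on the data below:
        # coxph(Surv(t,e) ~ x, ties=...)
        ("breslow", -1.63764686, 0.55858509),
        ("efron", -1.69648468, 0.56704828),
    ])
    def test_cox_tie_handling_matches_R(self, ties, beta_ref, se_ref):
        t = [11, 19, 22, 12, 6, 79, 22, 10, 19, 2, 1, 6, 132, 12, 34,
             15, 2, 11, 14, 7, 34, 4, 25, 8, 3, 11, 11, 13, 42, 6]
        e = [0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0,
             1, 1, 1, 1, 0, 1, 1, 1, 1, 0, 1, 1, 1, 1, 0]
        x = [0, 0, 1, 1, 0, 1, 1, 1, 1, 0, 0, 0, 1, 0, 1,
             0, 1, 1, 0, 1, 1, 0, 1, 0, 0, 0, 0, 0, 1, 0]
        recs = [SurvivalRecord(f"P{i}", float(ti), ei, covariates={"x": xi})
                for i, (ti, ei, xi) in enumerate(zip(t, e, x))]
        fit = cox_fit(recs, ["x"], ties_method=ties)
        assert fit.coef[0] == pytest.approx(beta_ref, abs=1e-6)
        assert fit.se[0] == pytest.approx(se_ref, abs=1e-6)

    def test_cox_null_covariate(self):
        rng = np.random.default_rng(9)
        inside = 0
        for s in range(20):
            r2 = np.random.default_rng(100 + s)
            n = 150
            x = r2.integers(0, 2, n)
            t = r2.exponential(50, n)
            recs = [SurvivalRecord(f"P{i}", float(t[i]), 1,
                                   covariates={"x": int(x[i])}) for i in range(n)]
            fit = cox_fit(recs, ["x"])
            inside += abs(fit.coef[0]) < 2 * fit.se[0]
        assert inside >= 18  # ~95% coverage at beta = 0

    def test_cox_degenerate_single_subject(self):
        recs = [SurvivalRecord("P0", 5.0, 1, covariates={"x": 1.0})]
        fit = cox_fit(recs, ["x"])
        assert not fit.converged or fit.flags or np.isnan(fit.se[0]) or fit.se[0] > 10


class TestBattery:
    def test_reconstructed_pt_table_p_value(self):
        # GZMB low/high x pT 3/4 from printed validation-cohort counts
        scores = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(136)],
            "GZMB_group": ["low"] * 68 + ["high"] * 68,
        })
        clinical = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(136)],
            "pT": [3] * 52 + [4] * 16 + [3] * 62 + [4] * 6,
        })
        res = run_association_battery(scores, clinical,
                                      variable_types={"pT": "categorical"},
                                      group_columns=("GZMB_group",))
        assert len(res) == 1
        assert round(res["p_value"].iloc[0], 3) == 0.036
        assert res["n"].iloc[0] == 136

    def test_single_level_variable_skipped(self):
        scores = pd.DataFrame({"patient_id": ["a", "b", "c", "d"],
                               "CD8_group": ["low", "low", "high", "high"]})
        clinical = pd.DataFrame({"patient_id": ["a", "b", "c", "d"],
                                 "pT": [3, 3, 3, 3]})
        with pytest.warns(UserWarning):
            res = run_association_battery(
                scores, clinical, variable_types={"pT": "categorical"},
                group_columns=("CD8_group",))
        assert res.empty

    def test_scale_variables_routed(self):
        rng = np.random.default_rng(4)
        n = 60
        scores = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "CD8_group": ["low", "high"] * (n // 2)})
        clinical = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "age": rng.normal(69, 12, n),
            "tbc_percent_expanding": rng.uniform(0, 100, n)})
        res = run_association_battery(scores, clinical, group_columns=("CD8_group",))
        methods = dict(zip(res["variable"], res["method"]))
        assert methods["age"] == "t_test"
        assert methods["tbc_percent_expanding"] == "kruskal_wallis"
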