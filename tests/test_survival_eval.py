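import numpy as np
import pandas as pd
import pytest

from d3ns.data_io import ClinicalTable, ValidationError
from d3ns.survival_eval import (
    association_tests,
    cox_fit,
    km_curve,
    km_logrank,
    likelihood_ratio_test,
    stepwise_model,
)


def clinical_from(times, events, labels=None, **covariates):
    n = len(times)
    ids = [f"p{i:03d}" for i in range(n)]
    df = pd.DataFrame(
        {"os_time": times, "os_event": events, **covariates},
        index=pd.Index(ids, name="patient_id"),
    )
    table = ClinicalTable(df)
    lab = dict(zip(ids, labels)) if labels is not None else None
    return table, lab


def simulate_survival(rng, n, hazard, censor_max=30.0):
    t = rng.exponential(1.0 / hazard, n)
    c = rng.uniform(0, censor_max, n)
    return np.minimum(t, c), (t <= c).astype(int)


class TestKaplanMeier:
    def test_equals_empirical_survival_without_censoring(self):
        times = [3, 1, 4, 1, 5, 9, 2, 6]
        curve = km_curve(times, [1] * 8)
        for t, s in zip(curve.times, curve.survival):
            empirical = np.mean(np.asarray(times) > t)
            assert s == pytest.approx(empirical)

    def test_starts_below_one_and_non_increasing(self):
        rng = np.random.default_rng(0)
        t, e = simulate_survival(rng, 50, 0.1)
        curve = km_curve(t, e)
        assert curve.survival[0] <= 1.0
        assert (np.diff(curve.survival) <= 1e-12).all()

    def test_median_survival(self):
        curve = km_curve([1, 2, 3, 4], [1, 1, 1, 1])
        assert curve.median_survival() == 2


class TestLogrank:
    def test_identical_groups_null(self):
        times = [1, 2, 3, 4, 5] * 2
        events = [1, 1, 0, 1, 0] * 2
        labels = [1] * 5 + [2] * 5
        clin, lab = clinical_from(times, events, labels)
        res = km_logrank(clin, lab)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_two_group_hand_computation(self):
        # group A events at 1,2,3; group B events at 4,5,6; no censoring.
        # Hand table: O_A=3, E_A = 3/6 + 2/5 + 1/4 = 1.15,
        # V = 0.25 + 0.24 + 0.1875 = 0.6775 -> chi2 = 1.85^2/0.6775 = 5.0517
        clin, lab = clinical_from([1, 2, 3, 4, 5, 6], [1] * 6, [1, 1, 1, 2, 2, 2])
        res = km_logrank(clin, lab)
        assert res.statistic == pytest.approx(3.4225 / 0.6775, abs=1e-10)
        assert res.df == 1

    def test_agrees_with_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(3)
        t1, e1 = simulate_survival(rng, 40, 0.10)
        t2, e2 = simulate_survival(rng, 35, 0.04)
        clin, lab = clinical_from(
            np.concatenate([t1, t2]), np.concatenate([e1, e2]), [1] * 40 + [2] * 35
        )
        mine = km_logrank(clin, lab)
        ref = multivariate_logrank_test(
            clin.data["os_time"], [lab[p] for p in clin.patients], clin.data["os_event"]
        )
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-6)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-6)

    def test_three_group_power_on_planted_hazards(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t1, e1 = simulate_survival(rng, 250, 0.09)
            t2, e2 = simulate_survival(rng, 250, 0.03)
            clin, lab = clinical_from(
                np.concatenate([t1, t2]), np.concatenate([e1, e2]),
                [1] * 250 + [2] * 250,
            )
            if km_logrank(clin, lab).p_value < 0.001:
                hits += 1
        assert hits >= 95

    def test_invariant_to_relabeling_and_time_rescaling(self):
        rng = np.random.default_rng(7)
        t, e = simulate_survival(rng, 60, 0.08)
        labels = rng.integers(1, 3, 60)
        clin, lab = clinical_from(t, e, labels)
        base = km_logrank(clin, lab)
        swapped = {p: 3 - v for p, v in lab.items()}
        assert km_logrank(clin, swapped).statistic == pytest.approx(base.statistic)
        clin2, _ = clinical_from(t * 12.0, e, labels)
        assert km_logrank(clin2, lab).statistic == pytest.approx(base.statistic)


class TestCox:
    def test_recovers_simulated_log_hazard_ratio(self):
        rng = np.random.default_rng(0)
        n = 400
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.05 * np.exp(np.log(2.0) * x)))
        c = rng.uniform(0, 60, n)  # roughly 20% censoring
        clin, _ = clinical_from(np.minimum(t, c), (t <= c).astype(int), marker=x)
        res = cox_fit(clin, ["marker"])
        coef = res.terms.loc[0, "coef"]
        assert abs(coef - np.log(2.0)) < 0.25
        assert res.terms.loc[0, "ci_lower"] < res.terms.loc[0, "hr"] < res.terms.loc[0, "ci_upper"]

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(1)
        t, e = simulate_survival(rng, 40, 0.05)
        clin, _ = clinical_from(t, e, flat=np.ones(40))
        with pytest.raises(ValidationError, match="single level"):
            cox_fit(clin, ["flat"])

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        t, e = simulate_survival(rng, 100, 0.05)
        x = rng.normal(size=100)
        clin, _ = clinical_from(t, e, age=x)
        res1 = cox_fit(clin, ["age"], check_ph=False)
        perm = rng.permutation(100)
        clin2 = ClinicalTable(clin.data.iloc[perm].copy())
        res2 = cox_fit(clin2, ["age"], check_ph=False)
        assert res1.terms.loc[0, "coef"] == pytest.approx(res2.terms.loc[0, "coef"], abs=1e-8)

    def test_hr_is_exp_coef(self):
        rng = np.random.default_rng(3)
        t, e = simulate_survival(rng, 80, 0.05)
        clin, _ = clinical_from(t, e, z=rng.normal(size=80))
        res = cox_fit(clin, ["z"], check_ph=False)
        assert res.terms.loc[0, "hr"] == pytest.approx(np.exp(res.terms.loc[0, "coef"]))


class TestStepwise:
    def test_redundant_subtype_adds_nothing(self):
        rng = np.random.default_rng(4)
        group = rng.integers(0, 2, 200)
        t = rng.exponential(1.0 / (0.04 * np.exp(1.0 * group)))
        c = rng.uniform(0, 80, 200)
        clin, lab = clinical_from(
            np.minimum(t, c), (t <= c).astype(int), labels=group + 1, group=group
        )
        out = stepwise_model(clin, ["group"], lab)
        assert out["lrt_p"] > 0.5

    def test_subtype_as_sole_driver_detected(self):
        rng = np.random.default_rng(5)
        group = rng.integers(0, 2, 300)
        t = rng.exponential(1.0 / (0.03 * np.exp(1.2 * group)))
        c = rng.uniform(0, 100, 300)
        clin, lab = clinical_from(
            np.minimum(t, c), (t <= c).astype(int), labels=group + 1,
            noise=rng.normal(size=300),
        )
        out = stepwise_model(clin, ["noise"], lab)
        assert out["lrt_p"] < 0.01

    def test_unscreened_candidates_leave_null_baseline(self):
        rng = np.random.default_rng(6)
        t, e = simulate_survival(rng, 200, 0.05)
        clin, lab = clinical_from(
            t, e, labels=rng.integers(1, 3, 200), pure_noise=rng.normal(size=200)
        )
        # noise covariate is univariately non-significant with high probability
        out = stepwise_model(clin, ["pure_noise"], lab, screen_p=1e-6)
        assert out["selected"] == []
        assert len(out["baseline"].terms) == 0

    def test_lrt_non_negative_and_df_counted(self):
        rng = np.random.default_rng(7)
        t, e = simulate_survival(rng, 150, 0.05)
        clin, lab = clinical_from(t, e, labels=rng.integers(1, 4, 150))
        out = stepwise_model(clin, [], lab)
        assert out["lrt_statistic"] >= 0.0
        assert out["lrt_df"] == 2  # 3 subtypes -> 2 added parameters


class TestAssociations:
    def test_two_group_continuous_uses_wilcoxon(self):
        rng = np.random.default_rng(8)
        t, e = simulate_survival(rng, 60, 0.05)
        clin, lab = clinical_from(t, e, labels=rng.integers(1, 3, 60),
                                  age=rng.normal(60, 8, 60))
        (res,) = association_tests(clin, lab, ["age"])
        assert res.test == "Wilcoxon"

    def test_three_group_continuous_uses_kruskal(self):
        rng = np.random.default_rng(9)
        t, e = simulate_survival(rng, 90, 0.05)
        clin, lab = clinical_from(t, e, labels=rng.integers(1, 4, 90),
                                  age=rng.normal(60, 8, 90))
        (res,) = association_tests(clin, lab, ["age"])
        assert res.test == "Kruskal-Wallis"

    def test_perfectly_separated_2x2_is_fisher_significant(self):
        t = list(range(1, 21))
        e = [1] * 20
        labels = [1] * 10 + [2] * 10
        sex = ["F"] * 10 + ["M"] * 10
        clin, lab = clinical_from(t, e, labels, sex=sex)
        (res,) = association_tests(clin, lab, ["sex"])
        assert res.test == "Fisher"
        assert res.p_value < 0.001

    def test_single_valued_variable_skipped_with_note(self):
        rng = np.random.default_rng(10)
        t, e = simulate_survival(rng, 30, 0.05)
        clin, lab = clinical_from(t, e, labels=rng.integers(1, 3, 30),
                                  center=["X"] * 30)
        (res,) = association_tests(clin, lab, ["center"])
        assert res.test == "skipped"

    def test_na_excluded_listwise_with_n_reported(self):
        rng = np.random.default_rng(11)
        t, e = simulate_survival(rng, 40, 0.05)
        age = rng.normal(60, 8, 40)
        age[:5] = np.nan
        clin, lab = clinical_from(t, e, labels=rng.integers(1, 3, 40), age=age)
        (res,) = association_tests(clin, lab, ["age"])
        assert res.n == 35

    def test_null_p_values_uniform(self):
        # categorical variable independent of subtype: p ~ U(0,1)
        from scipy import stats

        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n = 1000
            t, e = simulate_survival(rng, n, 0.05)
            clin, lab = clinical_from(
                t, e, labels=rng.integers(1, 4, n),
                stage=rng.choice(["I", "II", "III", "IV"], n),
            )
            (res,) = association_tests(clin, lab, ["stage"])
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestLRT:
    def test_nested_lrt_non_negative_across_random_fits(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = 120
            t, e = simulate_survival(rng, n, 0.05)
            clin, _ = clinical_from(t, e, a=rng.normal(size=n), b=rng.normal(size=n))
            base = cox_fit(clin, ["a"], check_ph=False)
            full = cox_fit(clin, ["a", "b"], check_ph=False)
            stat, df, p = likelihood_ratio_test(base, full)
            assert stat >= 0.0 and df == 1 and 0 <= p <= 1
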