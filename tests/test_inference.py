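"""Assumption checks, repeated-measures/mixed ANOVA, Tukey HSD and the
measurement-error filter, cross-checked against pingouin/statsmodels."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

from retestkit import (
    DegenerateDataError,
    InsufficientDataError,
    detectable_differences,
    error_aware_comparison,
    greenhouse_geisser_epsilon,
    lilliefors_test,
    mauchly_test,
    mixed_design_anova,
    one_way_repeated_anova,
    studentized_range_cdf,
    tukey_hsd,
)
from retestkit.reliability import DifferenceSummary


def _long(X, groups=None):
    n, k = X.shape
    df = pd.DataFrame(X, columns=[f"c{j}" for j in range(k)])
    df["subj"] = range(n)
    long = df.melt(id_vars="subj", var_name="cond", value_name="y")
    if groups is not None:
        long["grp"] = long["subj"].map(dict(enumerate(groups)))
    return long


def _summary(d_mean, halfwidth, n=16):
    return DifferenceSummary(
        d_mean=d_mean, d_sd=1.0, se=1.0, t_quantile=2.131,
        ci_low=d_mean - halfwidth, ci_high=d_mean + halfwidth,
        abs_d_mean=abs(d_mean), confidence=0.95, n=n,
    )


class TestLilliefors:
    def test_statistic_matches_statsmodels(self, rng):
        x = rng.normal(size=60)
        stat_sm, _ = sm_lilliefors(x, dist="norm")
        assert lilliefors_test(x, mc_reps=200, seed=0).statistic == pytest.approx(stat_sm)

    def test_exponential_sample_rejected(self, rng):
        x = rng.exponential(size=1000)
        assert lilliefors_test(x, mc_reps=2000, seed=1).p_value < 0.01

    def test_normal_sample_not_rejected(self):
        x = np.random.default_rng(777).normal(size=500)
        assert lilliefors_test(x, mc_reps=2000, seed=2).p_value > 0.05

    def test_type_one_error_near_nominal(self):
        # replicate draws from the null; rejection rate at 0.05 should be ~5%
        rng = np.random.default_rng(99)
        reject = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=50)
            if lilliefors_test(x, mc_reps=500, seed=rng.integers(2**31)).p_value < 0.05:
                reject += 1
        assert 0.02 <= reject / reps <= 0.09

    def test_too_small_sample(self):
        with pytest.raises(InsufficientDataError):
            lilliefors_test(np.array([1.0, 2.0, 3.0]))

    def test_constant_vector(self):
        with pytest.raises(DegenerateDataError):
            lilliefors_test(np.full(10, 3.0))


class TestMauchly:
    def test_two_conditions_trivially_spherical(self, rng):
        res = mauchly_test(rng.normal(size=(10, 2)))
        assert (res.statistic, res.p_value) == (1.0, 1.0)

    def test_w_matches_pingouin(self, rng):
        X = rng.normal(size=(15, 4)) * np.array([1.0, 1.5, 2.0, 1.2])
        res = mauchly_test(X)
        spher = pg.sphericity(_long(X), dv="y", within="cond", subject="subj")
        assert res.statistic == pytest.approx(spher.W, abs=1e-10)
        assert res.p_value == pytest.approx(spher.pval, abs=2e-3)

    def test_heteroscedastic_conditions_rejected(self, rng):
        X = rng.normal(size=(100, 4)) * np.array([1.0, 2.0, 4.0, 8.0])
        assert mauchly_test(X).p_value < 0.01

    def test_compound_symmetry_keeps_nominal_rate(self):
        rng = np.random.default_rng(17)
        reps, reject = 300, 0
        for _ in range(reps):
            X = rng.normal(size=(40, 4)) + rng.normal(size=(40, 1))
            if mauchly_test(X).p_value < 0.05:
                reject += 1
        assert 0.02 <= reject / reps <= 0.09

    def test_singular_case_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            mauchly_test(rng.normal(size=(3, 4)))


class TestGreenhouseGeisser:
    def test_two_conditions_always_one(self, rng):
        assert greenhouse_geisser_epsilon(rng.normal(size=(6, 2))) == 1.0

    def test_compound_symmetric_construction_is_spherical(self):
        # X built so the condition covariance is exactly c·I + d·J
        rng = np.random.default_rng(3)
        n, k = 200, 4
        X = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
        S = np.cov(X, rowvar=False)
        # force exact compound symmetry by symmetrizing the sample
        off = (S.sum() - np.trace(S)) / (k * (k - 1))
        S_cs = np.full((k, k), off) + np.eye(k) * (np.trace(S) / k - off)
        L = np.linalg.cholesky(S_cs)
        Z = rng.normal(size=(n, k))
        Zc = (Z - Z.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(Z, rowvar=False))).T
        X_exact = Zc @ L.T
        assert greenhouse_geisser_epsilon(X_exact) == pytest.approx(1.0, abs=1e-9)

    def test_rank_one_covariance_hits_lower_bound(self, rng):
        base = rng.normal(size=(30, 1))
        X = base * np.array([1.0, 2.0, 3.0, 4.0]) + 5.0
        assert greenhouse_geisser_epsilon(X) == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_matches_pingouin(self, rng):
        X = rng.normal(size=(12, 5)) * np.array([1, 1, 2, 3, 1.5])
        ours = greenhouse_geisser_epsilon(X)
        theirs = pg.epsilon(pd.DataFrame(X), correction="gg")
        assert ours == pytest.approx(float(theirs), abs=1e-9)


class TestOneWayRepeatedAnova:
    def test_no_condition_effect(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = one_way_repeated_anova(X)
        assert res.f_stat == 0.0 and res.p_value == 1.0

    def test_integer_matrix_matches_bruteforce(self):
        X = np.array(
            [[3, 5, 6], [1, 4, 5], [2, 2, 4], [4, 6, 9], [0, 1, 2]], dtype=float
        )
        res = one_way_repeated_anova(X)
        n, k = X.shape
        grand = X.mean()
        ss_subj = sum(k * (X[i].mean() - grand) ** 2 for i in range(n))
        ss_cond = sum(n * (X[:, j].mean() - grand) ** 2 for j in range(k))
        ss_err = sum(
            (X[i, j] - X[i].mean() - X[:, j].mean() + grand) ** 2
            for i in range(n) for j in range(k)
        )
        f_oracle = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        assert res.f_stat == pytest.approx(f_oracle, abs=1e-10)
        assert res.ss_subjects == pytest.approx(ss_subj, abs=1e-10)
        assert res.ss_conditions == pytest.approx(ss_cond, abs=1e-10)
        assert res.ss_error == pytest.approx(ss_err, abs=1e-10)

    def test_matches_pingouin_with_gg(self, rng):
        X = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1))
        X[:, 2] *= 2.5
        res = one_way_repeated_anova(X)
        aov = pg.rm_anova(_long(X), dv="y", within="cond", subject="subj",
                          correction=True).iloc[0]
        assert res.f_stat == pytest.approx(aov["F"], abs=1e-9)
        assert res.p_uncorrected == pytest.approx(aov["p_unc"], abs=1e-9)
        assert res.epsilon_gg == pytest.approx(aov["eps"], abs=1e-9)
        if res.gg_applied:
            assert res.p_value == pytest.approx(aov["p_GG_corr"], abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(
        hnp.arrays(
            np.float64,
            st.tuples(st.integers(3, 8), st.integers(2, 5)),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
        )
    )
    def test_ss_conservation(self, X):
        X = X + np.arange(X.shape[0])[:, None] * 0.1
        try:
            res = one_way_repeated_anova(X)
        except (InsufficientDataError, DegenerateDataError):
            return
        total = float(((X - X.mean()) ** 2).sum())
        assert res.ss_subjects + res.ss_conditions + res.ss_error == pytest.approx(
            total, abs=1e-9 * max(total, 1.0)
        )

    def test_gg_correction_conservative_in_the_significance_region(self, rng):
        # shrinking both dfs raises the p-value once F is well above 1
        # (near F = 1 the correction can go either way, so the check is
        # restricted to the region where the correction matters)
        checked = 0
        for _ in range(200):
            X = rng.normal(size=(10, 4)) * np.array([1, 1, 3, 5.0])
            X += np.array([0.0, 0.5, 1.0, 1.5])
            res = one_way_repeated_anova(X)
            if res.f_stat >= 2.0 and res.gg_applied:
                assert res.p_value >= res.p_uncorrected - 1e-12
                checked += 1
        assert checked > 10

    def test_missing_data_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        X[1, 2] = np.nan
        with pytest.raises(InsufficientDataError):
            one_way_repeated_anova(X)


class TestStudentizedRange:
    def test_cdf_at_zero(self):
        assert studentized_range_cdf(0.0, 3, 10) == 0.0

    def test_monotone_in_q(self):
        qs = np.linspace(0.1, 6, 12)
        vals = [studentized_range_cdf(q, 4, 20) for q in qs]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_two_group_large_df_normal_limit(self):
        # range of two iid N(0,1) is |Z1 - Z2|: P(|Z1-Z2| <= q) = 2Φ(q/√2) − 1
        for q in (0.5, 1.5, 3.0):
            closed = 2 * stats.norm.cdf(q / np.sqrt(2)) - 1
            assert studentized_range_cdf(q, 2, 1e7) == pytest.approx(closed, abs=1e-5)

    def test_critical_value_k3_df10(self):
        # Tukey table value q_{0.05}(3, 10) ≈ 3.88
        q = stats.studentized_range.ppf(0.95, 3, 10)
        assert q == pytest.approx(3.88, abs=0.01)
        assert studentized_range_cdf(q, 3, 10) == pytest.approx(0.95, abs=1e-9)


class TestTukeyHSD:
    def test_equal_means(self):
        comps = tukey_hsd(means=[5.0, 5.0], ms_err=2.0, df_err=10, n_per_group=6)
        assert comps[0].q_stat == 0.0 and comps[0].p_adjusted == 1.0

    def test_two_groups_equal_t_test_p(self):
        # with k = 2, q = t·√2 and the studentized-range p equals the t p
        t_val, df, n = 2.4, 14.0, 8
        ms_err = 3.0
        diff = t_val * np.sqrt(2 * ms_err / n)
        comps = tukey_hsd(means=[diff, 0.0], ms_err=ms_err, df_err=df, n_per_group=n)
        # q uses SE = sqrt(ms/n); paired t for independent means uses sqrt(2ms/n)
        p_t = 2 * stats.t.sf(t_val, df)
        assert comps[0].p_adjusted == pytest.approx(p_t, abs=1e-10)

    def test_p_monotone_in_mean_difference(self):
        ps = [
            tukey_hsd(means=[d, 0.0, 0.0], ms_err=1.0, df_err=12, n_per_group=5)[0].p_adjusted
            for d in (0.2, 0.5, 1.0, 2.0)
        ]
        assert all(b <= a for a, b in zip(ps, ps[1:]))

    def test_matrix_form_uses_within_error(self, rng):
        X = rng.normal(size=(9, 3)) + np.array([0.0, 1.0, 2.0])
        comps = tukey_hsd(X, labels=["a", "b", "c"])
        assert len(comps) == 3
        assert {c.pair for c in comps} == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_single_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            tukey_hsd(means=[1.0], ms_err=1.0, df_err=5, n_per_group=4)


class TestMixedDesignAnova:
    def test_matches_pingouin(self, rng):
        X = rng.normal(size=(14, 4)) + rng.normal(size=(14, 1))
        groups = np.array(["young"] * 8 + ["elderly"] * 6)
        res = mixed_design_anova(X, groups)
        mx = pg.mixed_anova(_long(X, groups), dv="y", within="cond",
                            subject="subj", between="grp")
        by = {row["Source"]: row for _, row in mx.iterrows()}
        assert res.between.f_stat == pytest.approx(by["grp"]["F"], abs=1e-9)
        assert res.between.p_value == pytest.approx(by["grp"]["p_unc"], abs=1e-9)
        assert res.within.f_stat == pytest.approx(by["cond"]["F"], abs=1e-9)
        assert res.interaction.f_stat == pytest.approx(by["Interaction"]["F"], abs=1e-9)

    def test_duplicated_groups_have_zero_between_f(self, rng):
        half = rng.normal(size=(6, 3))
        X = np.vstack([half, half])
        groups = ["a"] * 6 + ["b"] * 6
        res = mixed_design_anova(X, groups)
        assert res.between.f_stat == pytest.approx(0.0, abs=1e-12)

    def test_large_group_shift_detected(self):
        rng = np.random.default_rng(21)
        hits = 0
        reps = 60
        for _ in range(reps):
            n1, n2 = 19, 14
            subj = rng.normal(size=(n1 + n2, 1))
            X = subj + rng.normal(size=(n1 + n2, 4))
            X[n1:] += 3.0  # 3 between-subject SDs
            res = mixed_design_anova(X, ["y"] * n1 + ["e"] * n2)
            hits += res.between.p_value < 0.05
        assert hits / reps > 0.95

    def test_small_group_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            mixed_design_anova(rng.normal(size=(5, 3)), ["a"] * 4 + ["b"])


class TestErrorAwareComparison:
    def test_equal_means_not_distinguishable(self):
        cmp = error_aware_comparison(10.0, 10.0, _summary(0.0, 2.0))
        assert not cmp.distinguishable

    def test_difference_twice_envelope(self):
        cmp = error_aware_comparison(10.0, 14.0, _summary(0.0, 2.0))
        assert cmp.distinguishable
        assert cmp.observed_diff == pytest.approx(4.0)
        assert cmp.error_interval_halfwidth == pytest.approx(2.0)

    def test_asymmetric_envelope_shifted_by_mean_difference(self):
        # d̄ = 1.5 shifts the envelope: mean_b = mean_a + 3 is inside
        # [mean_a − 0.5, mean_a + 3.5] although 3 > halfwidth 2
        summary = _summary(1.5, 2.0)
        assert not error_aware_comparison(10.0, 13.0, summary).distinguishable
        assert error_aware_comparison(10.0, 9.0, summary).distinguishable

    def test_flag_matches_envelope_definition(self, rng):
        for _ in range(50):
            d_mean, hw = rng.normal(), abs(rng.normal()) + 0.1
            a, b = rng.normal(scale=3), rng.normal(scale=3)
            cmp = error_aware_comparison(a, b, _summary(d_mean, hw))
            outside = b < a + d_mean - hw or b > a + d_mean + hw
            assert cmp.distinguishable == outside


class TestDetectableDifferences:
    @staticmethod
    def _anova(p):
        from retestkit.inference import AssumptionTestResult, RepeatedAnovaResult

        return RepeatedAnovaResult(
            f_stat=5.0, df_num=3, df_den=45, epsilon_gg=1.0,
            sphericity=AssumptionTestResult(1.0, 1.0, "mauchly", 16, 0.0),
            gg_applied=False, p_value=p, p_uncorrected=p,
            ss_conditions=1, ss_subjects=1, ss_error=1, ms_error=1.0, n=16, k=4,
        )

    def test_nonsignificant_anova_empty(self):
        assert detectable_differences(self._anova(0.2), [], {}, {}) == []

    def test_constructed_large_offset_flagged(self, rng):
        # condition "b" sits 3 envelope halfwidths above "a"
        n, k = 16, 2
        subj = rng.normal(size=(n, 1))
        X = np.hstack([subj, subj + 3.0]) + 0.1 * rng.normal(size=(n, k))
        anova = one_way_repeated_anova(X)
        posthoc = tukey_hsd(X, labels=["a", "b"])
        summaries = {lab: _summary(0.0, 1.0) for lab in ("a", "b")}
        means = {"a": float(X[:, 0].mean()), "b": float(X[:, 1].mean())}
        out = detectable_differences(anova, posthoc, means, summaries)
        assert len(out) == 1
        assert out[0].significant and out[0].distinguishable

    def test_significant_but_inside_envelope(self, rng):
        # strong significance, difference smaller than the error envelope
        n = 40
        subj = rng.normal(size=(n, 1))
        X = np.hstack([subj, subj + 0.5]) + 0.01 * rng.normal(size=(n, 2))
        anova = one_way_repeated_anova(X)
        posthoc = tukey_hsd(X, labels=["a", "b"])
        summaries = {lab: _summary(0.0, 5.0) for lab in ("a", "b")}
        means = {"a": float(X[:, 0].mean()), "b": float(X[:, 1].mean())}
        out = detectable_differences(anova, posthoc, means, summaries)
        assert out[0].significant and not out[0].distinguishable
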