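import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from headmorph.cohort_stats import (
    ancova_group,
    chi_square_independence,
    cohens_d,
    cronbach_alpha,
    mancova,
    required_sample_size,
    stepwise_regression,
    two_sample_t,
    two_sample_t_power,
)
from headmorph.errors import CollinearityError, HeadmorphError, SingularityError


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t({"HC": [1.0, 2.0, 3.0], "ASD": [1.0, 2.0, 3.0]})
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_pooled_t(self):
        # groups {0,0,1,1} vs {1,1,2,2}: pooled variance 1/3, t = 1/sqrt(1/6) = sqrt(6)
        res = two_sample_t({"a": [0, 0, 1, 1], "b": [1, 1, 2, 2]})
        assert res.statistic == pytest.approx(math.sqrt(6), rel=1e-12)
        assert res.df == (6.0,)
        assert res.p_value == pytest.approx(2 * stats.t.sf(math.sqrt(6), 6), rel=1e-12)

    def test_zero_variance_unequal_means(self):
        res = two_sample_t({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert math.isinf(res.statistic)
        assert res.p_value == 0.0

    def test_null_type_one_error(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x = rng.standard_normal(50)
            y = rng.standard_normal(50)
            if two_sample_t({"a": x, "b": y}).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065


class TestChiSquare:
    def test_identical_distributions(self):
        chi2, df, p = chi_square_independence([[10, 20], [10, 20]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_2x2(self):
        chi2, df, p = chi_square_independence([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(20 / 3, rel=1e-9)
        assert df == 1

    def test_2x4_df(self):
        chi2, df, p = chi_square_independence([[30, 20, 5, 5], [28, 22, 6, 4]])
        assert df == 3

    def test_zero_margin_dropped(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            chi2, df, p = chi_square_independence([[10, 0, 20], [20, 0, 10]])
        assert df == 1


class TestAncova:
    def _table(self, rng, n1=60, n2=60, delta=0.0, cov_effect=0.0):
        age = rng.uniform(20, 50, n1 + n2)
        y = rng.standard_normal(n1 + n2) + cov_effect * age
        y[n1:] += delta
        return pd.DataFrame(
            {"group": ["HC"] * n1 + ["ASD"] * n2, "age": age, "y": y}
        )

    def test_reduces_to_anova_with_inert_covariate(self):
        rng = np.random.default_rng(1)
        tbl = self._table(rng, delta=0.5)
        res = ancova_group(tbl, "y", covariates=[])
        t = two_sample_t(tbl["y"], tbl["group"])
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-6)
        assert res.p_value == pytest.approx(t.p_value, rel=1e-6)

    def test_statsmodels_oracle(self):
        """Group F and p must match an independent OLS ANCOVA fit."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        tbl = self._table(rng, delta=0.4, cov_effect=0.05)
        res = ancova_group(tbl, "y", covariates=["age"])
        fit = smf.ols("y ~ C(group, Treatment('HC')) + age", data=tbl).fit()
        anova = sm.stats.anova_lm(fit, typ=3)
        row = anova.loc["C(group, Treatment('HC'))"]
        assert res.statistic == pytest.approx(float(row["F"]), rel=1e-8)
        assert res.p_value == pytest.approx(float(row["PR(>F)"]), rel=1e-6)
        assert res.df == (1.0, float(fit.df_resid))

    def test_matched_outcome_gives_null_f(self):
        n = 40
        age = np.linspace(20, 50, n)
        tbl = pd.DataFrame(
            {"group": ["HC"] * (n // 2) + ["ASD"] * (n // 2), "age": np.concatenate([age[: n // 2]] * 2),
             "y": np.concatenate([np.sin(age[: n // 2])] * 2)}
        )
        res = ancova_group(tbl, "y", covariates=["age"])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_collinear_covariate_named(self):
        rng = np.random.default_rng(4)
        tbl = self._table(rng)
        tbl["age_copy"] = tbl["age"]
        with pytest.raises(CollinearityError, match="age_copy"):
            ancova_group(tbl, "y", covariates=["age", "age_copy"])

    def test_power_matches_noncentral_t_oracle(self):
        """Simulated ANCOVA rejection rate at the reference-cohort head-circumference
        effect must match noncentral-t power at the implied d (the oracle)."""
        n1, n2 = 136, 120
        m1, s1, m2, s2 = 57.4, 1.8, 58.3, 2.1
        d = cohens_d(m1, s1, n1, m2, s2, n2)
        nc = d * math.sqrt(n1 * n2 / (n1 + n2))
        tcrit = stats.t.ppf(0.975, n1 + n2 - 2)
        oracle = stats.nct.sf(tcrit, n1 + n2 - 2, nc) + stats.nct.cdf(-tcrit, n1 + n2 - 2, nc)
        rng = np.random.default_rng(7)
        reps = 2000
        hits = 0
        age = rng.uniform(20, 45, n1 + n2)
        groups = ["HC"] * n1 + ["ASD"] * n2
        for _ in range(reps):
            y = np.concatenate([rng.normal(m1, s1, n1), rng.normal(m2, s2, n2)])
            tbl = pd.DataFrame({"group": groups, "age": age, "y": y})
            if ancova_group(tbl, "y").p_value < 0.05:
                hits += 1
        mc_sd = math.sqrt(oracle * (1 - oracle) / reps)
        assert abs(hits / reps - oracle) < 4 * mc_sd + 0.01

    def test_adjusted_means_shift_with_covariate_imbalance(self):
        rng = np.random.default_rng(9)
        n = 100
        age = np.concatenate([rng.uniform(20, 30, n), rng.uniform(35, 45, n)])
        y = 0.1 * age + rng.standard_normal(2 * n) * 0.01
        tbl = pd.DataFrame({"group": ["HC"] * n + ["ASD"] * n, "age": age, "y": y})
        res = ancova_group(tbl, "y")
        raw_gap = res.group_means["ASD"] - res.group_means["HC"]
        adj_gap = res.adjusted_means["ASD"] - res.adjusted_means["HC"]
        assert abs(adj_gap) < abs(raw_gap) / 10  # age explains nearly the whole gap


class TestCohensD:
    def test_equal_means(self):
        assert cohens_d(5, 1, 10, 5, 1, 10) == 0.0

    def test_unit_effect(self):
        assert cohens_d(0, 1, 20, 1, 1, 20) == pytest.approx(1.0, rel=1e-12)

    def test_reference_cohort_value(self):
        # control 57.4 (1.8, n=136) vs clinical 58.3 (2.1, n=120)
        assert cohens_d(57.4, 1.8, 136, 58.3, 2.1, 120) == pytest.approx(0.462, abs=5e-4)

    def test_zero_pooled_sd_missing(self):
        assert math.isnan(cohens_d(1, 0, 5, 2, 0, 5))


class TestMancova:
    def _table(self, rng, n=80, p=3, delta=None):
        groups = ["HC"] * n + ["ASD"] * n
        age = rng.uniform(20, 50, 2 * n)
        Y = rng.standard_normal((2 * n, p))
        if delta is not None:
            Y[n:] += delta
        cols = {f"m{j}": Y[:, j] for j in range(p)}
        return pd.DataFrame({"group": groups, "age": age} | cols)

    def test_single_outcome_reduces_to_ancova(self):
        rng = np.random.default_rng(21)
        tbl = self._table(rng, p=1, delta=[0.3])
        multi = mancova(tbl, ["m0"])
        uni = ancova_group(tbl, "m0")
        assert multi.statistic == pytest.approx(uni.statistic, rel=1e-6)
        assert multi.p_value == pytest.approx(uni.p_value, rel=1e-6)

    def test_statsmodels_oracle(self):
        """Wilks' lambda and its F must match statsmodels MANOVA."""
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(22)
        tbl = self._table(rng, p=4, delta=[0.2, 0.0, -0.3, 0.1])
        res = mancova(tbl, ["m0", "m1", "m2", "m3"])
        fit = MANOVA.from_formula("m0 + m1 + m2 + m3 ~ group + age", data=tbl)
        sm_tbl = fit.mv_test().results["group"]["stat"]
        assert res.wilks_lambda == pytest.approx(float(sm_tbl.loc["Wilks' lambda", "Value"]), rel=1e-8)
        assert res.statistic == pytest.approx(float(sm_tbl.loc["Wilks' lambda", "F Value"]), rel=1e-6)
        assert res.pillai == pytest.approx(float(sm_tbl.loc["Pillai's trace", "Value"]), rel=1e-8)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(23)
        n, p = 100, 6
        groups = ["HC"] * n + ["ASD"] * n
        age = rng.uniform(20, 50, 2 * n)
        hits = 0
        reps = 1000
        for _ in range(reps):
            Y = rng.standard_normal((2 * n, p))
            tbl = pd.DataFrame({"group": groups, "age": age} | {f"m{j}": Y[:, j] for j in range(p)})
            if mancova(tbl, [f"m{j}" for j in range(p)]).p_value < 0.05:
                hits += 1
        assert 0.035 <= hits / reps <= 0.065

    def test_duplicated_outcome_singular(self):
        rng = np.random.default_rng(24)
        tbl = self._table(rng, p=2)
        tbl["m_dup"] = tbl["m0"]
        with pytest.raises(SingularityError):
            mancova(tbl, ["m0", "m1", "m_dup"])

    def test_df_bookkeeping(self):
        rng = np.random.default_rng(25)
        n_hc, n_asd, p = 136, 120, 6
        groups = ["HC"] * n_hc + ["ASD"] * n_asd
        age = rng.uniform(20, 50, n_hc + n_asd)
        Y = rng.standard_normal((n_hc + n_asd, p))
        tbl = pd.DataFrame({"group": groups, "age": age} | {f"m{j}": Y[:, j] for j in range(p)})
        res = mancova(tbl, [f"m{j}" for j in range(p)])
        assert res.df == (6.0, 248.0)


class TestStepwise:
    def test_exact_copy_predictor(self):
        rng = np.random.default_rng(31)
        n = 100
        x = rng.standard_normal(n)
        tbl = pd.DataFrame({"y": x, "a": x, "b": rng.standard_normal(n)})
        res = stepwise_regression(tbl, "y", ["a", "b"])
        assert res.terms == ["a"]
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_false_entry_rate_near_p_enter(self):
        rng = np.random.default_rng(32)
        reps, n, k = 500, 200, 5
        entries = 0
        for _ in range(reps):
            data = {"y": rng.standard_normal(n)}
            data |= {f"x{j}": rng.standard_normal(n) for j in range(k)}
            res = stepwise_regression(pd.DataFrame(data), "y", [f"x{j}" for j in range(k)])
            entries += len(res.terms)
        per_candidate = entries / (reps * k)
        # forward selection of the minimum of k p-values inflates per-candidate
        # entry slightly above alpha; the rate must sit near p_enter
        assert 0.02 <= per_candidate <= 0.09

    def test_entry_order_follows_marginal_r2(self):
        rng = np.random.default_rng(33)
        n = 400
        # orthonormal predictors with exactly controlled marginal R^2
        M = rng.standard_normal((n, 4))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        x1, x2, x3, e = Q.T
        y = math.sqrt(0.40) * x1 + math.sqrt(0.05) * x2 + math.sqrt(0.01) * x3 + math.sqrt(0.54) * e
        tbl = pd.DataFrame({"y": y, "x1": x1, "x2": x2, "x3": x3})
        res = stepwise_regression(tbl, "y", ["x3", "x1", "x2"])
        assert res.terms[:2] == ["x1", "x2"]
        r2 = dict(res.entered)
        assert r2["x1"] == pytest.approx(0.40, abs=0.02)
        assert r2["x2"] == pytest.approx(0.45, abs=0.02)

    def test_cumulative_r2_nondecreasing(self):
        rng = np.random.default_rng(34)
        n = 300
        X = rng.standard_normal((n, 4))
        y = X @ [0.8, 0.4, 0.2, 0.0] + rng.standard_normal(n)
        tbl = pd.DataFrame({"y": y} | {f"x{j}": X[:, j] for j in range(4)})
        res = stepwise_regression(tbl, "y", [f"x{j}" for j in range(4)])
        r2s = [r2 for _, r2 in res.entered]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))
        assert res.terms == sorted(set(res.terms), key=res.terms.index)  # unique

    def test_no_candidate_passes(self):
        tbl = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0], "x": [1.0, 1.0, 1.0, 1.0]})
        res = stepwise_regression(tbl, "y", ["x"])
        assert res.terms == []
        assert res.r_squared == 0.0


class TestPowerAnalysis:
    def test_reference_sample_size(self):
        assert required_sample_size(0.4, 0.05, 0.80) == 100

    def test_large_effect(self):
        assert required_sample_size(0.8, 0.05, 0.80) == 26

    def test_monotonicity_in_power(self):
        assert required_sample_size(0.5, 0.05, 0.90) > required_sample_size(0.5, 0.05, 0.80)

    @pytest.mark.parametrize("d,power", [(0.3, 0.8), (0.4, 0.8), (0.6, 0.9)])
    def test_inverse_consistency(self, d, power):
        n = required_sample_size(d, 0.05, power)
        assert two_sample_t_power(d, n) >= power
        assert two_sample_t_power(d, n - 1) < power

    def test_invalid_domain(self):
        with pytest.raises(HeadmorphError):
            required_sample_size(-0.5)


class TestCronbachAlpha:
    def test_identical_columns(self):
        x = np.arange(10.0)
        assert cronbach_alpha(np.column_stack([x, x])) == pytest.approx(1.0, rel=1e-12)

    def test_closed_form_two_columns(self):
        # exact sample correlation 0.5 between equal-variance columns -> alpha = 2/3
        rng = np.random.default_rng(41)
        n = 200
        M = rng.standard_normal((n, 3))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        u, v = Q[:, 0], Q[:, 1]
        c1 = u
        c2 = 0.5 * u + math.sqrt(0.75) * v
        assert cronbach_alpha(np.column_stack([c1, c2])) == pytest.approx(2 / 3, rel=1e-9)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((1000, 5))
        assert abs(cronbach_alpha(X)) < 0.1

    def test_zero_total_variance(self):
        assert math.isnan(cronbach_alpha(np.array([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0]])))
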