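import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dkipipe.group_stats import (ancova, bh_fdr, mahalanobis_filter,
                                 partial_correlation, stepwise_regression,
                                 zscore_qc)


def bh_oracle(p, q):
    """Independent step-up enumeration: walk k from m down to 1 and stop at
    the first sorted p(k) <= (k/m) q."""
    order = sorted(p)
    m = len(p)
    for k in range(m, 0, -1):
        if order[k - 1] <= k / m * q:
            return order[k - 1]
    return None


class TestZscoreQC:
    def test_constant_vector_no_outliers(self):
        with pytest.warns(UserWarning):
            kept, out, _ = zscore_qc(np.full(6, 2.0))
        assert len(out) == 0 and len(kept) == 6

    def test_single_extreme_value_flagged(self):
        vals = np.array([1, 1, 1, 1, 1, 6], dtype=float)
        kept, out, _ = zscore_qc(vals)
        # hand computation: mean 1.833, SD 2.041 -> Z(6) ~ 2.04 > 2
        assert list(out) == [5]
        assert 5 not in kept

    def test_normal_sample_outlier_fraction(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal(1000)
        _, out, _ = zscore_qc(vals)
        expected = 2 * stats.norm.sf(2.0)  # ~4.6%
        assert abs(len(out) / 1000 - expected) < 0.02

    def test_qq_points_sorted_and_paired(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal(50)
        _, _, qq = zscore_qc(vals)
        assert qq.shape == (50, 2)
        assert np.all(np.diff(qq[:, 0]) > 0)
        assert np.array_equal(qq[:, 1], np.sort(vals))


def make_ancova_table(rng, n_per=25, effects=(0.0, 0.5, 1.0), beta_age=0.02):
    rows = []
    for g, eff in zip(("SIVD", "AD", "NC"), effects):
        age = rng.normal(72, 8, n_per)
        edu = rng.normal(9, 3, n_per)
        y = eff + beta_age * age + 0.05 * edu + rng.normal(0, 0.3, n_per)
        rows.append(pd.DataFrame({"group": g, "age": age, "education": edu,
                                  "y": y}))
    return pd.concat(rows, ignore_index=True)


class TestAncova:
    def test_constant_outcome_zero_effect(self, rng):
        t = make_ancova_table(rng)
        t["y"] = 1.0
        res = ancova(t, "y", ["age"])
        assert res.partial_eta_sq == 0.0

    def test_two_groups_f_equals_t_squared(self, rng):
        """With two groups and no covariates, the group F equals the squared
        pooled-variance two-sample t, computed here by the textbook formula."""
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.8, 1, 25)
        t = pd.DataFrame({"group": ["A"] * 20 + ["B"] * 25,
                          "y": np.concatenate([a, b])})
        res = ancova(t, "y", [])
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) \
            / (len(a) + len(b) - 2)
        t_stat = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert res.F == pytest.approx(t_stat ** 2, rel=1e-10)

    def test_no_covariates_equals_one_way_anova(self, rng):
        t = make_ancova_table(rng, beta_age=0.0)
        res = ancova(t, "y", [])
        groups = [t.loc[t["group"] == g, "y"] for g in ("SIVD", "AD", "NC")]
        F, p = stats.f_oneway(*groups)
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-8)

    def test_adjusted_means_match_normal_equations(self, rng):
        """Pairwise adjusted mean differences agree with an independent
        normal-equations solve of the dummy-coded linear model to 1e-10."""
        t = make_ancova_table(rng)
        res = ancova(t, "y", ["age", "education"])
        # independent OLS: y ~ 1 + I(AD) + I(NC) + age + education
        d_ad = (t["group"] == "AD").astype(float)
        d_nc = (t["group"] == "NC").astype(float)
        X = np.column_stack([np.ones(len(t)), d_ad, d_nc, t["age"],
                             t["education"]])
        beta = np.linalg.solve(X.T @ X, X.T @ t["y"].to_numpy())
        expect = {("AD", "NC"): beta[1] - beta[2],
                  ("AD", "SIVD"): beta[1],
                  ("NC", "SIVD"): beta[2]}
        for _, row in res.pairwise.iterrows():
            key = (row["group_a"], row["group_b"])
            assert row["diff"] == pytest.approx(expect[key], abs=1e-10)
            assert row["ci_low"] <= row["diff"] <= row["ci_high"]

    def test_bonferroni_p_capped_at_one(self, rng):
        t = make_ancova_table(rng, effects=(0.0, 0.0, 0.0))
        res = ancova(t, "y", ["age"])
        assert (res.pairwise["p_adj"] <= 1.0).all()

    def test_effect_size_in_unit_interval(self, rng):
        t = make_ancova_table(rng)
        res = ancova(t, "y", ["age", "education"])
        assert 0.0 <= res.partial_eta_sq <= 1.0
        assert res.p < 0.05  # built-in group effect is large


class TestBhFdr:
    def test_all_pass_step_up(self):
        res = bh_fdr(np.array([0.01, 0.02, 0.04, 0.05]), q=0.05)
        assert res.critical_value == pytest.approx(0.05)
        assert res.significant.all()

    def test_none_pass(self):
        res = bh_fdr(np.array([0.04, 0.2, 0.5]), q=0.05)
        assert not res.any_significant
        assert res.critical_value == 0.0
        assert not res.significant.any()

    def test_uniform_small_p_all_pass(self):
        res = bh_fdr(np.full(13, 0.001), q=0.05)
        assert res.significant.all()

    @given(m=st.integers(1, 8), seed=st.integers(0, 500))
    @settings(max_examples=120, deadline=None)
    def test_matches_step_up_enumeration(self, m, seed):
        """Decision agrees with an independent step-up enumeration for
        p-vectors on a 0.01 grid."""
        rng = np.random.default_rng(seed)
        p = rng.integers(0, 101, size=m) / 100.0
        res = bh_fdr(p, q=0.05)
        crit = bh_oracle(p, 0.05)
        if crit is None:
            assert not res.any_significant
        else:
            assert res.critical_value == pytest.approx(crit)
            assert np.array_equal(res.significant, p <= crit)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([]))


class TestPartialCorrelation:
    def test_identity_r_one(self, rng):
        x = rng.standard_normal(50)
        cov = rng.standard_normal(50)
        r, _ = partial_correlation(x, x.copy(), cov)
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_outcome_equal_to_covariate_gives_zero(self, rng):
        cov = rng.standard_normal(200)
        x = rng.standard_normal(200)
        r, p = partial_correlation(x, cov.copy(), cov)
        assert abs(r) < 1e-10 or p > 0.9

    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal((2, 80))
        r, p = partial_correlation(x, y)
        rr, pp = stats.pearsonr(x, y)
        assert r == pytest.approx(rr, abs=1e-12)
        assert p == pytest.approx(pp, rel=1e-6)

    def test_recovers_generated_negative_correlation(self):
        """Data generated with r = -0.36 between a kurtosis metric and the
        dementia-severity score is recovered within 0.03 at n = 5,000."""
        rng = np.random.default_rng(12)
        n = 5000
        target = -0.36
        z1 = rng.standard_normal(n)
        z2 = target * z1 + np.sqrt(1 - target ** 2) * rng.standard_normal(n)
        covs = rng.standard_normal((n, 2))  # independent age/education
        x = 0.88 + 0.08 * z1
        y = 4.5 + 2.6 * z2
        r, p = partial_correlation(x, y, covs)
        assert r == pytest.approx(target, abs=0.03)
        assert p < 1e-6

    def test_matches_pingouin(self, rng):
        """Dual route: agrees with pingouin's partial correlation."""
        pingouin = pytest.importorskip("pingouin")
        n = 120
        df = pd.DataFrame({"x": rng.standard_normal(n),
                           "y": rng.standard_normal(n),
                           "c1": rng.standard_normal(n),
                           "c2": rng.standard_normal(n)})
        df["y"] += 0.5 * df["x"] + 0.3 * df["c1"]
        r, p = partial_correlation(df["x"], df["y"], df[["c1", "c2"]].to_numpy())
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)


class TestMahalanobisFilter:
    def test_distant_row_removed(self, rng):
        X = rng.normal(0, 1, (30, 3))
        X[7] = 40.0
        kept, removed = mahalanobis_filter(X)
        assert 7 in removed

    def test_one_dimensional_reduction_to_z_rule(self, rng):
        """With one predictor, distance/1 is the squared Z-score, so the
        threshold is |Z| > sqrt(2)."""
        x = rng.standard_normal(200)
        kept, removed = mahalanobis_filter(x[:, None])
        mu, sd = x.mean(), x.std(ddof=1)
        z = (x - mu) / sd
        assert set(removed) == set(np.flatnonzero(z ** 2 > 2))

    def test_rows_on_centroid_kept(self, rng):
        X = rng.normal(0, 1, (20, 2))
        X[5] = X.mean(axis=0)
        kept, removed = mahalanobis_filter(X)
        assert 5 in kept


class TestStepwise:
    def test_dominant_predictor_selected_alone(self, rng):
        n = 200
        x1, x2 = rng.standard_normal((2, n))
        t = pd.DataFrame({"x1": x1, "x2": x2,
                          "y": 2 * x1 + rng.normal(0, 1e-4, n)})
        res = stepwise_regression(t, "y", ["x1", "x2"])
        assert list(res["predictor"]) == ["x1"]
        assert res["p"].iloc[0] < 1e-10

    def test_orthogonal_candidates_empty_selection(self, rng):
        n = 100
        t = pd.DataFrame({"x1": rng.standard_normal(n),
                          "x2": rng.standard_normal(n),
                          "y": rng.standard_normal(n)})
        # regenerate until chance correlation is tiny, then no entry at 0.05
        res = stepwise_regression(t, "y", ["x1", "x2"], p_enter=1e-6)
        assert res.empty

    def test_two_true_predictors_recovered(self, rng):
        """Selection-recovery simulation: two active predictors among eight
        candidates are both found in at least 95% of replicates."""
        hits = 0
        reps = 60
        for k in range(reps):
            r = np.random.default_rng(k)
            n = 500
            X = r.standard_normal((n, 8))
            y = 0.6 * X[:, 1] - 0.5 * X[:, 4] + r.standard_normal(n)
            t = pd.DataFrame(X, columns=[f"x{i}" for i in range(8)])
            t["y"] = y
            res = stepwise_regression(t, "y", [f"x{i}" for i in range(8)])
            if {"x1", "x4"} <= set(res["predictor"]):
                hits += 1
        assert hits / reps >= 0.95

    def test_standardized_beta_sign_and_scale(self, rng):
        n = 300
        x = rng.standard_normal(n)
        t = pd.DataFrame({"x": x, "y": -0.5 * x + rng.normal(0, 0.5, n)})
        res = stepwise_regression(t, "y", ["x"])
        beta = res["beta"].iloc[0]
        assert -1.0 < beta < 0.0
        # standardized beta of a single predictor equals the Pearson r
        assert beta == pytest.approx(stats.pearsonr(t["x"], t["y"])[0],
                                     abs=1e-10)
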