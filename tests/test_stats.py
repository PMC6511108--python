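"""Group assignment, Holm correction, mediation, ANCOVA, post hocs, contingency."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from svdconn import (
    ancova_type2,
    assign_group,
    group_contingency,
    holm_adjust,
    log_transform,
    mediation_path,
    multiple_regression_standardized,
    posthoc_tukey,
)


class TestAssignGroup:
    @pytest.mark.parametrize(
        "aes, cesd, expected",
        [
            (40, 10, "apathy"),
            (34, 16, "comorbid"),
            (33, 15, "control"),
            (20, 30, "depression"),
            (34, 15, "apathy"),
            (33, 16, "depression"),
        ],
    )
    def test_cut_scores(self, aes, cesd, expected):
        assert assign_group(aes, cesd) == expected

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(18, 72), st.integers(0, 60))
    def test_partitions_the_score_plane(self, aes, cesd):
        assert assign_group(aes, cesd) in ("apathy", "depression", "comorbid",
                                           "control")


class TestHolm:
    def test_step_down_hand_example(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2])[0] == pytest.approx(0.2)

    def test_capped_at_one(self):
        assert np.allclose(holm_adjust([0.5, 0.5]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_adjusted_at_least_raw(self, pvals):
        adj = holm_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)


def test_correlate_matches_pearson_and_holm_dominates_raw():
    from svdconn import correlate

    rng = np.random.default_rng(20)
    table = pd.DataFrame({"AES": rng.normal(size=100)})
    for k in range(3):
        table[f"v{k}"] = 0.3 * table["AES"] + rng.normal(size=100)
    out = correlate(table, "AES", ["v0", "v1", "v2"])
    for _, row in out.iterrows():
        r_ref, p_ref = sps.pearsonr(table["AES"], table[row["variable"]])
        assert row["r"] == pytest.approx(r_ref)
        assert row["p"] == pytest.approx(p_ref)
        assert row["p_holm"] >= row["p"] - 1e-12


class TestMediation:
    def test_full_mediation_by_construction(self):
        rng = np.random.default_rng(0)
        n = 2000
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = m.copy()
        res = mediation_path(x, m, y)
        assert abs(res.beta_direct) < 0.05
        assert res.beta_total > 0.3

    def test_irrelevant_mediator_leaves_beta_unchanged(self):
        n = 64
        x = np.linspace(-1, 1, n)
        y = 2.0 * x
        m = np.tile([1.0, -1.0], n // 2)  # exactly orthogonal to x and y
        res = mediation_path(x, m, y)
        assert res.beta_direct == pytest.approx(res.beta_total, abs=1e-12)

    def test_path_algebra_identity(self):
        """beta_total = beta_direct + a*b exactly for standardized OLS with a
        single mediator and no covariates."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = 50
            x = rng.normal(size=n)
            m = 0.6 * x + rng.normal(size=n)
            y = 0.2 * x + 0.5 * m + rng.normal(size=n)
            res = mediation_path(x, m, y)
            assert res.beta_total == pytest.approx(
                res.beta_direct + res.indirect, abs=1e-10)

    def test_parameter_recovery(self):
        """Generating paths (a, b, direct) = (0.6, 0.5, 0.2) are recovered."""
        rng = np.random.default_rng(2)
        a_g, b_g, c_g = 0.6, 0.5, 0.2
        est = []
        for _ in range(50):
            n = 1000
            x = rng.normal(size=n)
            m = a_g * x + np.sqrt(1 - a_g**2) * rng.normal(size=n)
            sd_y = np.sqrt(max(0.0, 1 - (c_g**2 + b_g**2 + 2 * a_g * b_g * c_g)))
            y = c_g * x + b_g * m + sd_y * rng.normal(size=n)
            r = mediation_path(x, m, y)
            est.append([r.a, r.b, r.beta_direct])
        mean = np.mean(est, axis=0)
        assert np.allclose(mean, [a_g, b_g, c_g], atol=0.05)

    def test_two_mediators_supported(self):
        rng = np.random.default_rng(3)
        n = 500
        x = rng.normal(size=n)
        m1 = 0.5 * x + rng.normal(size=n)
        m2 = -0.4 * x + rng.normal(size=n)
        y = 0.3 * m1 + 0.3 * m2 + rng.normal(size=n)
        res = mediation_path(x, [m1, m2], y)
        assert len(np.atleast_1d(res.a)) == 2
        assert abs(res.beta_direct) < abs(res.beta_total) + 0.2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            mediation_path(np.ones(50), np.arange(50.0), np.arange(50.0))


class TestMultipleRegression:
    def test_single_predictor_beta_equals_pearson_r(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        out = multiple_regression_standardized(y, {"x": x})
        r, _ = sps.pearsonr(x, y)
        assert out["beta"].iloc[0] == pytest.approx(r, abs=1e-10)

    def test_orthogonal_predictors_equal_marginal_betas(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = 0.7 * x1 - 0.2 * x2
        joint = multiple_regression_standardized(y, {"x1": x1, "x2": x2})
        for name, x in [("x1", x1), ("x2", x2)]:
            marg = multiple_regression_standardized(y, {name: x})
            joint_beta = joint.loc[joint.predictor == name, "beta"].iloc[0]
            assert joint_beta == pytest.approx(marg["beta"].iloc[0], abs=1e-10)

    def test_collinear_predictors_rejected(self):
        x = np.arange(30.0)
        with pytest.raises(ValueError):
            multiple_regression_standardized(x, {"a": x, "b": 2 * x})


def _type2_oracle(outcome, group, covariates):
    """Full-vs-reduced residual-SS model comparison, fitted from scratch."""
    y = np.asarray(outcome, dtype=float)
    levels = sorted(set(group))
    G = np.column_stack([(np.asarray(group) == lev).astype(float)
                         for lev in levels[1:]])
    C = np.column_stack([np.asarray(v, dtype=float)
                         for v in covariates.values()]) if covariates else \
        np.empty((len(y), 0))
    ones = np.ones((len(y), 1))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), X.shape[1]

    rss_full, p_full = rss(np.hstack([ones, G, C]))
    df_resid = len(y) - p_full
    ms_resid = rss_full / df_resid
    out = {}
    rss_nog, _ = rss(np.hstack([ones, C]))
    out["group"] = ((rss_nog - rss_full) / G.shape[1]) / ms_resid
    for k, v in covariates.items():
        others = np.column_stack([np.asarray(w, dtype=float)
                                  for kk, w in covariates.items() if kk != k]) \
            if len(covariates) > 1 else np.empty((len(y), 0))
        rss_red, _ = rss(np.hstack([ones, G, others]))
        out[k] = (rss_red - rss_full) / ms_resid
    return out


class TestAncova:
    def make_data(self, seed=0, n_per=20, shift=0.0):
        rng = np.random.default_rng(seed)
        group = np.repeat(["a", "b", "c", "d"], n_per)
        cov = rng.normal(size=len(group))
        y = 0.5 * cov + rng.normal(size=len(group))
        y[group == "a"] += shift
        return y, group, {"cov": cov}

    def test_balanced_no_covariates_equals_oneway_f(self):
        y, group, _ = self.make_data(shift=1.0)
        tab = ancova_type2(y, group, {})
        f_ref, p_ref = sps.f_oneway(*[y[group == g] for g in "abcd"])
        row = tab[tab.term == "group"].iloc[0]
        assert row["F"] == pytest.approx(f_ref, rel=1e-10)
        assert row["p"] == pytest.approx(p_ref, rel=1e-10)

    def test_matches_model_comparison_oracle(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            n = int(rng.integers(40, 80))
            group = rng.choice(list("abcd"), size=n)
            covs = {"c1": rng.normal(size=n), "c2": rng.normal(size=n)}
            y = rng.normal(size=n) + 0.4 * covs["c1"]
            tab = ancova_type2(y, group, covs)
            oracle = _type2_oracle(y, group, covs)
            for term, f_ref in oracle.items():
                f_got = tab[tab.term == term]["F"].iloc[0]
                assert f_got == pytest.approx(f_ref, abs=1e-8)

    def test_single_group_level_rejected(self):
        with pytest.raises(ValueError):
            ancova_type2(np.arange(10.0), ["a"] * 10, {})


class TestPosthoc:
    def test_two_groups_tukey_equals_t_test(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=40)
        group = np.repeat(["a", "b"], 20)
        y[group == "b"] += 0.8
        tk = posthoc_tukey(y, group)
        _, p_ref = sps.ttest_ind(y[group == "a"], y[group == "b"], equal_var=True)
        assert tk["p"].iloc[0] == pytest.approx(p_ref, rel=1e-6)

    def test_equal_means_near_one(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=400)
        group = np.repeat(["a", "b"], 200)
        assert posthoc_tukey(y, group)["p"].iloc[0] > 0.3

    def test_one_shifted_group_detected(self):
        rng = np.random.default_rng(8)
        group = np.repeat(["a", "b", "c", "d"], 50)
        y = rng.normal(size=200)
        y[group == "a"] += 3.0
        tk = posthoc_tukey(y, group)
        involves_a = tk[(tk.group1 == "a") | (tk.group2 == "a")]
        others = tk[(tk.group1 != "a") & (tk.group2 != "a")]
        assert (involves_a["p"] < 0.001).all()
        assert (others["p"] > 0.05).all()

    def test_fisher_unadjusted_leq_tukey(self):
        rng = np.random.default_rng(9)
        group = np.repeat(["a", "b", "c"], 30)
        y = rng.normal(size=90)
        tk = posthoc_tukey(y, group, method="tukey")
        fi = posthoc_tukey(y, group, method="fisher")
        assert np.all(fi["p"].to_numpy() <= tk["p"].to_numpy() + 1e-12)


class TestContingency:
    def test_uniform_table_null(self):
        tab = pd.DataFrame([[10, 10], [10, 10]], index=["g1", "g2"])
        res = group_contingency(tab, pairs=[("g1", "g2")])
        assert res.chi2 == pytest.approx(0.0)
        assert res.odds_ratios["odds_ratio"].iloc[0] == pytest.approx(1.0)

    def test_known_odds_ratio(self):
        tab = pd.DataFrame([[20, 10], [10, 20]], index=["g1", "g2"])
        res = group_contingency(tab, pairs=[("g1", "g2")])
        assert res.odds_ratios["odds_ratio"].iloc[0] == pytest.approx(4.0)

    def test_chi2_matches_formula_oracle(self):
        rng = np.random.default_rng(10)
        counts = rng.integers(5, 60, size=(4, 2)).astype(float)
        tab = pd.DataFrame(counts, index=list("abcd"))
        res = group_contingency(tab)
        expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
        chi2_ref = float(((counts - expected) ** 2 / expected).sum())
        assert res.chi2 == pytest.approx(chi2_ref, rel=1e-12)

    def test_zero_margin_rejected(self):
        tab = pd.DataFrame([[0, 0], [10, 20]], index=["g1", "g2"])
        with pytest.raises(ValueError):
            group_contingency(tab)


class TestLogTransform:
    @pytest.mark.parametrize("x, expected", [(0.0, 0.0), (np.e - 1, 1.0)])
    def test_log1p_values(self, x, expected):
        assert log_transform([x])[0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform([-1.0])

    def test_reduces_skew_of_lognormal_sample(self):
        rng = np.random.default_rng(11)
        x = rng.lognormal(1.0, 1.0, size=2000)
        assert abs(sps.skew(np.log1p(x))) < abs(sps.skew(x))
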