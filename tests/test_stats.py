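"""Category statistics: transforms, G-tests, GLM/LM with type-3 tests,
Dunnett contrasts, Kruskal-Wallis/Dunn, partial Spearman."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from immusel import stats as st


# -------------------------------------------------------------- transforms
class TestTransforms:
    def _table(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "category": rng.choice(["control", "cytokines"], n),
            "dnds": rng.uniform(0, 1, n),
            "pnps": rng.uniform(0, 1, n),
            "mean_expression": rng.lognormal(2, 1, n),
            "tau": rng.uniform(0, 1, n),
            "ppi_count": rng.poisson(20, n),
            "seq_length": rng.integers(300, 3000, n),
        })

    def test_tau_endpoints(self):
        df = self._table()
        df.loc[0, "tau"] = 0.0
        df.loc[1, "tau"] = 1.0
        out = st.transform_covariates(df)
        assert out.loc[0, "asin_sqrt_tau"] == pytest.approx(0.0)
        assert out.loc[1, "asin_sqrt_tau"] == pytest.approx(np.pi / 2)

    def test_log10_length(self):
        df = self._table()
        df.loc[0, "seq_length"] = 1000
        out = st.transform_covariates(df)
        assert out.loc[0, "log10_length"] == pytest.approx(3.0)

    def test_z_columns_standardized(self):
        out = st.transform_covariates(self._table())
        for col in ("z_mean_expression", "z_tau", "z_ppi", "z_length", "z_pnps"):
            assert out[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert out[col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_negative_dnds_rejected(self):
        df = self._table()
        df.loc[0, "dnds"] = -0.1
        with pytest.raises(ValueError):
            st.transform_covariates(df)


# ------------------------------------------------------------------ G-test
def direct_two_binomial_g(k1, n1, k2, n2):
    """Independent computation: maximize each binomial log-likelihood on a
    fine grid plus the closed-form MLE, then compare with the pooled fit."""
    def ll(k, n, p):
        p = min(max(p, 1e-12), 1 - 1e-12)
        return k * np.log(p) + (n - k) * np.log(1 - p)

    def max_ll(k, n):
        grid = np.concatenate([np.linspace(1e-6, 1 - 1e-6, 4001), [k / n]])
        return max(ll(k, n, p) for p in grid)

    pooled_p = (k1 + k2) / (n1 + n2)
    return 2 * (
        max_ll(k1, n1) + max_ll(k2, n2)
        - ll(k1, n1, pooled_p) - ll(k2, n2, pooled_p)
    )


class TestTwoByTwoLrt:
    def test_published_contingency_values(self):
        # six model rows over 1,005 control and 977 immune genes
        expected = {
            (142, 307): 86.0, (138, 305): 88.9, (201, 356): 66.9,
            (218, 363): 57.6, (89, 127): 8.79, (20, 37): 5.80,
        }
        for (kc, ki), g_ref in expected.items():
            g, df, p = st.two_by_two_lrt(kc, 1005, ki, 977)
            assert g == pytest.approx(g_ref, abs=0.15)
            assert df == 1

    def test_known_p_value(self):
        g, _, p = st.two_by_two_lrt(20, 1005, 37, 977)
        assert p == pytest.approx(0.016, abs=0.001)

    def test_equal_proportions_zero(self):
        g, _, p = st.two_by_two_lrt(10, 100, 20, 200)
        assert g == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_oracle_equivalence_small_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n1, n2 = rng.integers(2, 31, size=2)
            k1 = rng.integers(0, n1 + 1)
            k2 = rng.integers(0, n2 + 1)
            g, _, _ = st.two_by_two_lrt(k1, n1, k2, n2)
            assert g == pytest.approx(
                direct_two_binomial_g(k1, n1, k2, n2), abs=1e-5
            )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            st.two_by_two_lrt(1, 0, 1, 10)
        with pytest.raises(ValueError):
            st.two_by_two_lrt(11, 10, 1, 10)


class TestProportionRatioRange:
    def test_published_range(self):
        rows = [
            (142, 1005, 307, 977), (138, 1005, 305, 977),
            (201, 1005, 356, 977), (218, 1005, 363, 977),
            (89, 1005, 127, 977), (20, 1005, 37, 977),
        ]
        assert st.proportion_ratio_range(rows) == (1.5, 2.3)

    def test_identical_proportions(self):
        rows = [(10, 100, 20, 200)] * 3
        assert st.proportion_ratio_range(rows) == (1.0, 1.0)

    def test_single_row(self):
        lo, hi = st.proportion_ratio_range([(10, 100, 30, 100)])
        assert lo == hi == 3.0

    def test_zero_control_errors(self):
        with pytest.raises(ValueError):
            st.proportion_ratio_range([(0, 100, 5, 100)])


# ------------------------------------------------------------------ models
def _glm_world(n_per_group=500, beta=1.0, seed=0):
    rng = np.random.default_rng(seed)
    base = -1.5
    rows = []
    for cat, shift in (("control", 0.0), ("cytokines", beta)):
        p = 1 / (1 + np.exp(-(base + shift)))
        y = rng.random(n_per_group) < p
        rows.append(pd.DataFrame({"category": cat, "positive": y}))
    return pd.concat(rows, ignore_index=True)


class TestBinomialGlm:
    def test_effect_recovery(self):
        hits = 0
        for rep in range(10):
            df = _glm_world(beta=1.0, seed=rep)
            cr = st.fit_binomial_glm(df, "positive ~ category")
            beta_hat = [
                v for k, v in cr.fitted.params.items() if "cytokines" in k
            ][0]
            hits += abs(beta_hat - 1.0) <= 0.35
        assert hits >= 9

    def test_null_covariate_type_one_error(self):
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 120
        for rep in range(n_rep):
            df = _glm_world(beta=0.8, seed=1000 + rep)
            df["noise"] = rng.normal(size=len(df))
            cr = st.fit_binomial_glm(df, "positive ~ category + noise")
            p = cr.terms.loc[cr.terms["term"] == "noise", "p"].iloc[0]
            rejections += p < 0.05
        assert 0.01 <= rejections / n_rep <= 0.10

    def test_single_category_errors(self):
        df = _glm_world().query("category == 'control'")
        with pytest.raises(ValueError):
            st.fit_binomial_glm(df, "positive ~ category")


class TestLinearModel:
    def test_identical_groups_f_near_zero(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=100)
        df = pd.DataFrame({
            "sqrt_dnds": np.concatenate([y, y]),
            "category": ["control"] * 100 + ["cytokines"] * 100,
        })
        cr = st.fit_linear_model(df, "sqrt_dnds ~ category")
        assert cr.terms["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_shift_detected_with_power(self):
        detected = 0
        for rep in range(10):
            rng = np.random.default_rng(50 + rep)
            df = pd.DataFrame({
                "sqrt_dnds": np.concatenate([
                    rng.normal(0.5, 0.3, 200), rng.normal(0.6, 0.3, 200)
                ]),
                "category": ["control"] * 200 + ["cytokines"] * 200,
            })
            cr = st.fit_linear_model(df, "sqrt_dnds ~ category")
            detected += cr.terms["p"].iloc[0] < 0.05
        assert detected >= 9

    def test_residual_df(self):
        df = _glm_world(n_per_group=50, seed=6)
        df["sqrt_dnds"] = np.random.default_rng(6).normal(size=len(df))
        cr = st.fit_linear_model(df, "sqrt_dnds ~ category")
        assert cr.fitted.df_resid == len(df) - 2


class TestDunnett:
    def test_single_comparison_matches_unadjusted(self):
        df = _glm_world(seed=7)
        cr = st.fit_binomial_glm(df, "positive ~ category")
        dun = st.dunnett_vs_control(cr.fitted, seed=1)
        assert len(dun) == 1
        assert dun["p_adjusted"].iloc[0] == pytest.approx(
            dun["p_unadjusted"].iloc[0], abs=0.01
        )

    def test_ordering_between_unadjusted_and_bonferroni(self):
        rng = np.random.default_rng(8)
        rows = []
        for cat, shift in (("control", 0.0), ("a", 0.4), ("b", 0.2), ("c", 0.0)):
            y = rng.normal(shift, 1.0, 150)
            rows.append(pd.DataFrame({"category": cat, "sqrt_dnds": y}))
        df = pd.concat(rows, ignore_index=True)
        cr = st.fit_linear_model(df, "sqrt_dnds ~ category")
        dun = st.dunnett_vs_control(cr.fitted, seed=2)
        k = len(dun)
        for _, row in dun.iterrows():
            assert row["p_unadjusted"] <= row["p_adjusted"] + 0.005
            assert row["p_adjusted"] <= min(1.0, k * row["p_unadjusted"]) + 0.01

    def test_independent_contrasts_closed_form(self):
        # three orthogonal contrasts: adjusted p = 1 - (1 - p_single)^3
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        n = 4000

        class Fake:
            params = pd.Series(
                {"C(category)[T.a]": 0.1, "C(category)[T.b]": 0.05,
                 "C(category)[T.c]": 0.02},
            )
            use_t = False
            df_resid = np.inf

            def cov_params(self):
                return pd.DataFrame(
                    np.eye(3) * 0.0025,
                    index=self.params.index, columns=self.params.index,
                )

        dun = st.dunnett_vs_control(Fake(), seed=3, n_draws=400_000)
        for _, row in dun.iterrows():
            p1 = row["p_unadjusted"]
            assert row["p_adjusted"] == pytest.approx(
                1 - (1 - p1) ** 3, abs=0.004
            )


class TestKruskalDunn:
    def test_two_group_identity_with_ranksum(self):
        rng = np.random.default_rng(10)
        vals = np.concatenate([
            rng.normal(0, 1, 40), rng.normal(0.5, 1, 35)
        ])
        cats = ["control"] * 40 + ["x"] * 35
        cr = st.kruskal_dunn(vals, cats)
        kw = cr.terms["statistic"].iloc[0]
        z = cr.contrasts["z"].iloc[0]
        assert kw == pytest.approx(z**2, rel=1e-6)

    def test_constant_data_statistic_zero(self):
        cr = st.kruskal_dunn([1.0] * 20, ["control"] * 10 + ["x"] * 10)
        assert cr.terms["statistic"].iloc[0] == 0.0

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            vals = rng.normal(size=60)
            cats = ["control"] * 20 + ["a"] * 20 + ["b"] * 20
            ps.append(st.kruskal_dunn(vals, cats).terms["p"].iloc[0])
        ps = np.array(ps)
        # uniform-ish: KS test should not reject wildly
        assert sps.kstest(ps, "uniform").pvalue > 0.01
        assert 0.01 <= (ps < 0.05).mean() <= 0.12

    def test_bh_applied_to_contrasts(self):
        rng = np.random.default_rng(12)
        vals = np.concatenate([rng.normal(0, 1, 30)] * 4)
        cats = (["control"] * 30 + ["a"] * 30 + ["b"] * 30 + ["c"] * 30)
        cr = st.kruskal_dunn(vals, cats)
        assert "p_adjusted" in cr.contrasts
        assert (cr.contrasts["p_adjusted"] >= cr.contrasts["p"] - 1e-12).all()


class TestPartialSpearman:
    def test_perfect_monotone(self):
        x = np.arange(50.0)
        r, p = st.partial_spearman(x, x**3)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_conditional_independence_mean_zero(self):
        rng = np.random.default_rng(13)
        rs = []
        for _ in range(200):
            z = rng.normal(size=60)
            x = z + rng.normal(size=60)
            y = z + rng.normal(size=60)
            r, _ = st.partial_spearman(x, y, controls=[z])
            rs.append(r)
        assert abs(np.mean(rs)) < 0.04

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=80)
        y = x + rng.normal(size=80)
        z = rng.normal(size=80)
        r1, _ = st.partial_spearman(x, y, controls=[z])
        r2, _ = st.partial_spearman(np.exp(x), y, controls=[z])
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(15)
        z = rng.normal(size=100)
        x = 0.5 * z + rng.normal(size=100)
        y = -0.3 * z + 0.4 * x + rng.normal(size=100)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z",
                                    method="spearman")
        r, _ = st.partial_spearman(x, y, controls=[z])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)

    def test_constant_variable_missing(self):
        r, p = st.partial_spearman(np.ones(30), np.arange(30.0))
        assert np.isnan(r)
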