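"""OLS engine, design matrices, stratified fits and model variants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from weightgx import association as assoc
from weightgx import genetics as gx


def _normal_equations_oracle(y, X):
    """Brute-force reference fit: solve XᵀXβ = Xᵀy directly."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    p = 2 * stats.t.sf(np.abs(beta / se), df)
    return beta, se, p


class TestFitOLS:
    def test_exact_linear_data(self):
        x = np.arange(10, dtype=float)
        X = np.column_stack([np.ones(10), x])
        y = 2 * x + 1
        fit = assoc.fit_ols(y, X, ["b0", "b1"])
        np.testing.assert_allclose(fit.beta, [1.0, 2.0], atol=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.df_resid == 8

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 3))])
        y = rng.normal(size=40)
        fit1 = assoc.fit_ols(y, X)
        perm = rng.permutation(40)
        fit2 = assoc.fit_ols(y[perm], X[perm])
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-10)
        np.testing.assert_allclose(fit1.se, fit2.se, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 4))])
        y = rng.normal(size=50)
        fit = assoc.fit_ols(y, X)
        beta, se, p = _normal_equations_oracle(y, X)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-8)
        np.testing.assert_allclose(fit.se, se, atol=1e-8)
        np.testing.assert_allclose(fit.p, p, atol=1e-8)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(60), rng.normal(size=(60, 3))])
        y = rng.normal(size=60)
        fit = assoc.fit_ols(y, X)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-10)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-10)
        np.testing.assert_allclose(fit.p, ref.pvalues, atol=1e-10)

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(80), rng.normal(size=(80, 5))])
        y = rng.normal(size=80)
        fit = assoc.fit_ols(y, X)
        resid = y - X @ fit.beta
        assert np.max(np.abs(X.T @ resid)) < 1e-8

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), 2 * np.arange(20.0)])
        with pytest.raises(ValueError, match="collinear"):
            assoc.fit_ols(np.zeros(20), X, ["intercept", "a", "a_copy"])

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            assoc.fit_ols(np.zeros(3), np.ones((3, 3)))

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        y = rng.normal(size=50)
        fit1 = assoc.fit_ols(y, X, ["b0", "x"])
        X2 = X.copy()
        X2[:, 1] *= c
        fit2 = assoc.fit_ols(y, X2, ["b0", "x"])
        assert fit2.term("x")[0] == pytest.approx(fit1.term("x")[0] / c, rel=1e-8)
        assert fit2.term("x")[1] == pytest.approx(fit1.term("x")[1] / c, rel=1e-8)
        assert fit2.term("x")[2] == pytest.approx(fit1.term("x")[2], rel=1e-8, abs=1e-12)


def _toy_cohort(n=50, seed=0, arm="glp1"):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "person_id": [f"p{i}" for i in range(n)],
            "arm": arm,
            "study_id": "S",
            "ancestry": "EUR",
            "stratum": "S:EUR",
            "sex": rng.choice(["F", "M"], n),
            "age": rng.uniform(30, 70, n),
            "t2d": rng.integers(0, 2, n),
            "w0_kg": rng.normal(100, 15, n),
            "mw1_kg": rng.normal(95, 15, n),
            "n_followup": 2,
            "pct_change": rng.normal(-4, 6, n),
            "medication_type": rng.choice(["semaglutide", "liraglutide", "dulaglutide"], n),
            "procedure_type": None,
        }
    )


class TestDesignMatrix:
    def test_minimal_design(self):
        cohort = _toy_cohort(10)
        spec = assoc.ModelSpec(exposure_id="x", adjust_baseline=False, include_medication_type=False)
        expo = pd.Series(np.arange(10.0), index=cohort.index)
        y, X, names, dropped = assoc.build_design_matrix(cohort, spec, "bs", exposure=expo)
        assert names[:2] == ["intercept", "x"]
        assert "w0_kg" not in names
        assert dropped == 0

    def test_medication_reference_coding(self):
        cohort = _toy_cohort(60)
        spec = assoc.ModelSpec(exposure_id="x")
        expo = pd.Series(np.random.default_rng(1).normal(size=60), index=cohort.index)
        _, _, names, _ = assoc.build_design_matrix(cohort, spec, "glp1", exposure=expo)
        med_cols = [n for n in names if n.startswith("med_")]
        assert len(med_cols) == 2  # 3 levels -> 2 indicators
        assert "med_dulaglutide" not in med_cols  # first level is the reference

    def test_interaction_column_is_product(self):
        cohort = _toy_cohort(30)
        spec = assoc.ModelSpec(
            exposure_id="x", outcome="post_weight", interaction_baseline_x_exposure=True,
            include_medication_type=False,
        )
        expo = pd.Series(np.random.default_rng(2).normal(size=30), index=cohort.index)
        _, X, names, _ = assoc.build_design_matrix(cohort, spec, "bs", exposure=expo)
        prod = X[:, names.index("w0_kg")] * X[:, names.index("x")]
        np.testing.assert_allclose(X[:, names.index("w0_x_exposure")], prod)

    def test_interaction_requires_post_weight_outcome(self):
        with pytest.raises(ValueError, match="interaction"):
            assoc.ModelSpec(outcome="pct_change", interaction_baseline_x_exposure=True)


class TestRunStratified:
    def test_single_stratum_equals_direct_fit(self, tables, glp1_cohort):
        cohort, _ = glp1_cohort
        stratum = cohort["stratum"].value_counts().idxmax()
        sub = cohort[cohort["stratum"] == stratum]
        fits, _ = assoc.run_stratified(
            sub, tables["persons"], tables["genetics"], "glp1", exposures=["PGS_BMI"]
        )
        assert len(fits) == 1
        pcs = tables["persons"].set_index("person_id")[[f"pc{i}" for i in range(1, 21)]]
        merged = sub.merge(pcs, left_on="person_id", right_index=True)
        expo = gx.standardize_pgs(
            merged["person_id"].map(tables["genetics"].set_index("person_id")["PGS_BMI"])
        )
        spec = assoc.ModelSpec(exposure_id="PGS_BMI")
        y, X, names, _ = assoc.build_design_matrix(merged, spec, "glp1", exposure=expo)
        direct = assoc.fit_ols(y, X, names)
        assert fits.iloc[0]["beta"] == pytest.approx(direct.term("PGS_BMI")[0])
        assert fits.iloc[0]["se"] == pytest.approx(direct.term("PGS_BMI")[1])

    def test_small_stratum_skipped_with_log(self, tables, glp1_cohort):
        cohort, _ = glp1_cohort
        small = cohort.head(10)
        fits, skips = assoc.run_stratified(
            small, tables["persons"], tables["genetics"], "glp1", exposures=["PGS_BMI"]
        )
        assert fits.empty
        assert any("stratum n=" in s["reason"] for s in skips)

    def test_rare_snp_skipped_by_mac(self, tables, glp1_cohort):
        cohort, _ = glp1_cohort
        fits, skips = assoc.run_stratified(
            cohort, tables["persons"], tables["genetics"], "glp1",
            exposures=["rs2295006"],  # sub-percent MAF in the generator
        )
        reasons = [s["reason"] for s in skips if s["exposure_id"] == "rs2295006"]
        assert len(fits) + len(reasons) > 0
        assert all("MAC=" in r for r in reasons)

    def test_null_exposure_pvalues_uniform(self, tables, glp1_cohort):
        """Redrawn genotypes with zero effect give Uniform(0,1) p-values."""
        cohort, _ = glp1_cohort
        stratum = cohort["stratum"].value_counts().idxmax()
        sub = cohort[cohort["stratum"] == stratum]
        pcs = tables["persons"].set_index("person_id")[[f"pc{i}" for i in range(1, 21)]]
        merged = sub.merge(pcs, left_on="person_id", right_index=True)
        spec = assoc.ModelSpec(exposure_id="g")
        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(500):
            g = pd.Series(rng.binomial(2, 0.3, len(merged)).astype(float), index=merged.index)
            y, X, names, _ = assoc.build_design_matrix(merged, spec, "glp1", exposure=g)
            pvals.append(assoc.fit_ols(y, X, names).term("g")[2])
        stat = stats.kstest(pvals, "uniform")
        assert stat.pvalue > 0.01


class TestAncestryContrast:
    def _multi_cohort(self, effect_amr=0.0, n=4000, seed=10):
        rng = np.random.default_rng(seed)
        anc = rng.choice(["EUR", "AFR", "AMR"], n, p=[0.5, 0.3, 0.2])
        w0 = rng.normal(100, 15, n)
        sex = rng.choice(["F", "M"], n)
        pct = rng.normal(-4, 6, n) - 0.05 * (w0 - 100) + effect_amr * (anc == "AMR")
        return pd.DataFrame(
            {
                "person_id": [f"p{i}" for i in range(n)],
                "arm": "bs",
                "study_id": rng.choice(["S1", "S2"], n),
                "ancestry": anc,
                "stratum": "x",
                "sex": sex,
                "age": rng.uniform(30, 70, n),
                "t2d": 0,
                "w0_kg": w0,
                "mw1_kg": 0.0,
                "n_followup": 1,
                "pct_change": pct,
                "medication_type": None,
                "procedure_type": "RYGB",
            }
        )

    def test_injected_ancestry_effect_recovered(self):
        cohort = self._multi_cohort(effect_amr=0.9)
        fits, _ = assoc.run_ancestry_contrast(cohort, "bs")
        amr = fits[fits["ancestry"] == "AMR"]
        assert len(amr) == 2  # both studies
        for _, r in amr.iterrows():
            assert abs(r["beta"] - 0.9) < 3 * r["se"]

    def test_single_ancestry_study_skipped(self):
        cohort = self._multi_cohort()
        cohort["ancestry"] = "EUR"
        fits, skips = assoc.run_ancestry_contrast(cohort, "bs")
        assert fits.empty
        assert all("single-ancestry" in s["reason"] for s in skips)

    def test_missing_eur_reference_skipped(self):
        cohort = self._multi_cohort()
        cohort = cohort[cohort["ancestry"] != "EUR"]
        fits, skips = assoc.run_ancestry_contrast(cohort, "bs")
        assert fits.empty
        assert all("EUR" in s["reason"] for s in skips)


class TestSensitivitySuite:
    def test_variant_flags(self, tables):
        out = assoc.run_sensitivity_suite(
            tables, "glp1", variants=["no_baseline", "min_weight_outcome", "sema_lira_only"],
            exposures=["PGS_BMI"],
        )
        assert set(out) == {"no_baseline", "min_weight_outcome", "sema_lira_only"}
        for fits in out.values():
            assert not fits.empty

    def test_unknown_variant_rejected(self, tables):
        with pytest.raises(ValueError, match="unknown sensitivity variant"):
            assoc.run_sensitivity_suite(tables, "glp1", variants=["bogus"])

    def test_min_outcome_never_above_median_outcome(self, tables):
        from weightgx import phenotyping

        med, _ = phenotyping.build_cohort(tables, "glp1")
        low, _ = phenotyping.build_cohort(
            tables, "glp1", phenotyping.CohortOptions(aggregate="min")
        )
        joined = med.set_index("person_id")[["pct_change"]].join(
            low.set_index("person_id")[["pct_change"]], rsuffix="_min", how="inner"
        )
        assert (joined["pct_change_min"] <= joined["pct_change"] + 1e-12).all()
        assert joined["pct_change_min"].mean() <= joined["pct_change"].mean()

    def test_no_baseline_design_lacks_w0(self):
        cohort = _toy_cohort(40)
        spec = assoc.ModelSpec(exposure_id="x", adjust_baseline=False)
        expo = pd.Series(np.random.default_rng(0).normal(size=40), index=cohort.index)
        _, _, names, _ = assoc.build_design_matrix(cohort, spec, "glp1", exposure=expo)
        assert "w0_kg" not in names
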