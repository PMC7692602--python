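"""GLM/GEE fits, quintile and trend models, pooling round trips."""

import numpy as np
import pandas as pd
import pytest

from gxecohort.genetics import assign_quintiles, standardize
from gxecohort.models import (
    FitResult,
    ModelSpec,
    fit_gee,
    fit_glm,
    interaction_plot_grid,
    quintile_model,
    run_analysis,
    trend_test,
)


def make_cohort(n=400, beta_int=-0.5, noise=1.0, seed=0, n_fsa=15):
    rng = np.random.default_rng(seed)
    prs_z = rng.standard_normal(n)
    hei_z = rng.standard_normal(n)
    sex = rng.choice(["male", "female"], size=n)
    age = rng.normal(55, 8, size=n)
    y = (90 + 1.3 * prs_z - 1.6 * hei_z + beta_int * prs_z * hei_z
         - 8 * (sex == "female") + 0.1 * (age - 55)
         + noise * rng.standard_normal(n))
    return pd.DataFrame({
        "waist": y, "prs_z": prs_z, "hei_z": hei_z, "sex": sex, "age": age,
        "fsa": rng.choice([f"F{i}" for i in range(n_fsa)], size=n),
    })


SPEC = ModelSpec(outcome="waist", covariates=("sex", "age"),
                 categorical=("sex",))


class TestGLM:
    def test_noise_free_data_recovers_generating_coefficients(self):
        df = make_cohort(noise=0.0)
        fit = fit_glm(SPEC, df)
        assert fit.params["prs_z"] == pytest.approx(1.3, abs=1e-8)
        assert fit.params["hei_z"] == pytest.approx(-1.6, abs=1e-8)
        assert fit.params["prs_z:hei_z"] == pytest.approx(-0.5, abs=1e-8)

    def test_toy_fit_matches_normal_equations(self):
        df = pd.DataFrame({
            "waist": [1.0, 2.0, 1.5, 3.0, 2.5, 4.0],
            "prs_z": [-1, 0, 1, -1, 0, 1.0],
            "hei_z": [1, 1, 1, -1, -1, -1.0],
        })
        spec = ModelSpec(outcome="waist", covariates=())
        fit = fit_glm(spec, df)
        X = np.column_stack([np.ones(6), df["prs_z"], df["hei_z"],
                             df["prs_z"] * df["hei_z"]])
        beta = np.linalg.solve(X.T @ X, X.T @ df["waist"])
        got = fit.params[["Intercept", "prs_z", "hei_z", "prs_z:hei_z"]]
        np.testing.assert_allclose(got, beta, atol=1e-8)

    def test_rank_deficiency_names_aliased_term(self):
        df = make_cohort(n=50)
        df["dup"] = df["prs_z"]
        spec = ModelSpec(outcome="waist", exposures=("prs_z", "hei_z"),
                         covariates=("dup",), categorical=())
        with pytest.raises(ValueError, match="aliased"):
            fit_glm(spec, df)

    def test_scale_invariance_through_standardization(self):
        df = make_cohort(seed=5)
        raw = df["prs_z"] * 3.7 + 12  # pretend this is the raw score
        df1 = df.assign(prs_z=standardize(raw))
        df2 = df.assign(prs_z=standardize(raw * 41.0))
        f1, f2 = fit_glm(SPEC, df1), fit_glm(SPEC, df2)
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-10)

    def test_sensitivity_flag_drops_energy_column(self):
        df = make_cohort()
        df["energy"] = np.random.default_rng(77).normal(1700, 300, len(df))
        spec = ModelSpec(outcome="waist", covariates=("sex", "age", "energy"),
                         categorical=("sex",))
        full = fit_glm(spec, df)
        from dataclasses import replace
        sens = fit_glm(replace(spec, drop_energy=True), df)
        assert len(full.params) - len(sens.params) == 1
        assert "energy" not in sens.params.index


class TestGEE:
    def test_singleton_clusters_match_glm_coefficients(self):
        df = make_cohort(n=120)
        df["fsa"] = [f"u{i}" for i in range(len(df))]  # one subject per cluster
        from dataclasses import replace
        glm = fit_glm(SPEC, df)
        gee = fit_gee(replace(SPEC, estimator="gee"), df)
        common = [t for t in glm.params.index if t in gee.params.index]
        np.testing.assert_allclose(gee.params[common], glm.params[common],
                                   rtol=1e-6, atol=1e-6)

    def test_zero_icc_generator_gives_near_zero_working_correlation(self):
        df = make_cohort(n=1500, seed=8, n_fsa=30)  # no cluster effect generated
        from dataclasses import replace
        fit = fit_gee(replace(SPEC, estimator="gee"), df)
        assert abs(fit.extra["working_corr"]) < 0.05

    def test_cluster_permutation_of_rows_leaves_estimates_unchanged(self):
        df = make_cohort(n=300, seed=2)
        from dataclasses import replace
        spec = replace(SPEC, estimator="gee")
        a = fit_gee(spec, df)
        b = fit_gee(spec, df.sample(frac=1, random_state=4))
        np.testing.assert_allclose(a.params, b.params, atol=1e-8)

    def test_single_cluster_rejected(self):
        df = make_cohort(n=60)
        df["fsa"] = "only"
        from dataclasses import replace
        with pytest.raises(ValueError):
            fit_gee(replace(SPEC, estimator="gee"), df)


class TestQuintileAndTrend:
    def test_design_has_four_quintile_columns_with_q1_reference(self):
        df = make_cohort(n=250)
        df["prs_quintile"] = assign_quintiles(df["prs_z"]).astype(int)
        fit = quintile_model(SPEC, df)
        qcols = [t for t in fit.params.index
                 if t.startswith("C(prs_quintile") and ":" not in t]
        assert len(qcols) == 4
        assert not any("[T.1]" in t for t in qcols)
        # interaction terms retained alongside main effects
        assert sum(":" in t for t in fit.params.index) == 4

    def test_equal_quintile_means_give_near_zero_contrasts(self):
        rng = np.random.default_rng(0)
        df = make_cohort(n=4000, beta_int=0.0, seed=1)
        df["waist"] = 90 + 0.5 * rng.standard_normal(len(df))  # no PRS effect
        df["prs_quintile"] = assign_quintiles(df["prs_z"]).astype(int)
        fit = quintile_model(ModelSpec(outcome="waist", covariates=()), df)
        qmains = [t for t in fit.params.index
                  if t.startswith("C(prs_quintile") and ":" not in t]
        for t in qmains:
            assert abs(fit.params[t]) < 4 * np.sqrt(fit.variances[t])

    def test_monotone_generator_orders_quintile_contrasts(self):
        df = make_cohort(n=5000, noise=0.5, seed=3)
        df["prs_quintile"] = assign_quintiles(df["prs_z"]).astype(int)
        fit = quintile_model(SPEC, df)
        q2 = fit.params["C(prs_quintile, Treatment(reference=1))[T.2]"]
        q5 = fit.params["C(prs_quintile, Treatment(reference=1))[T.5]"]
        assert q5 > q2

    def test_empty_quintile_rejected(self):
        df = make_cohort(n=50)
        df["prs_quintile"] = 1 + (np.arange(len(df)) % 4)  # only 4 groups
        with pytest.raises(ValueError, match="quintile 5"):
            quintile_model(SPEC, df)

    def test_strong_trend_detected(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "grp": np.repeat([1, 2, 3, 4], 100),
            "y": np.repeat([0.0, 1, 2, 3], 100) + rng.standard_normal(400),
        })
        out = trend_test(df, "y", "grp", adjustment=())
        assert out["p"] < 1e-3 and out["estimate"] > 0

    def test_trend_invariant_to_shifting_group_labels(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"grp": np.repeat([1, 2, 3, 4], 50),
                           "y": rng.standard_normal(200)})
        p1 = trend_test(df, "y", "grp", adjustment=())["p"]
        df["grp"] = df["grp"] + 10
        p2 = trend_test(df, "y", "grp", adjustment=())["p"]
        assert p1 == pytest.approx(p2)

    def test_too_few_groups_rejected(self):
        df = pd.DataFrame({"grp": [1] * 10, "y": np.arange(10.0)})
        with pytest.raises(ValueError):
            trend_test(df, "y", "grp", adjustment=())


class TestPoolingRoundTrip:
    def test_no_missingness_path_equals_direct_single_fit(self):
        df = make_cohort(n=300, seed=9)
        pooled = run_analysis(SPEC, [df])
        direct = fit_glm(SPEC, df)
        np.testing.assert_allclose(pooled.table["estimate"], direct.params,
                                   atol=1e-10)
        np.testing.assert_allclose(pooled.table["total_var"], direct.variances,
                                   atol=1e-10)

    def test_stratified_fits_recoverable_from_full_interaction_model(self):
        df = make_cohort(n=2000, seed=12, noise=0.8)
        male = df[df["sex"] == "male"]
        spec_m = ModelSpec(outcome="waist", covariates=("age",), categorical=())
        fit_male = fit_glm(spec_m, male)
        # full model with sex interacted with everything
        import statsmodels.formula.api as smf
        full = smf.ols("waist ~ (prs_z * hei_z + age) * C(sex)", data=df).fit()
        # male is the second level -> male coefficients = base + [T.male] terms
        assert full.params["prs_z"] + full.params["prs_z:C(sex)[T.male]"] == \
            pytest.approx(fit_male.params["prs_z"], abs=1e-8)


class TestInteractionPlot:
    def prepare(self):
        df = make_cohort(n=1200, seed=21, noise=0.5)
        df["prs_quintile"] = assign_quintiles(df["prs_z"]).astype(int)
        fit = quintile_model(SPEC, df)
        pooled = run_analysis(
            ModelSpec(outcome="waist", covariates=("sex", "age"),
                      categorical=("sex",), quintile_col="prs_quintile"), [df])
        return df, fit, pooled

    def test_predictions_match_design_matrix_oracle(self):
        df, fit, pooled = self.prepare()
        spec = ModelSpec(outcome="waist", covariates=("sex", "age"),
                         categorical=("sex",), quintile_col="prs_quintile")
        grid = interaction_plot_grid(pooled, fit, df, spec,
                                     hei_grid=np.array([-1.0, 0.0, 1.0]))
        import patsy
        base = {c: (df[c].mean() if df[c].dtype.kind in "if" and df[c].nunique() > 2
                    else df[c].mode().iloc[0]) for c in df.columns}
        row = dict(base)
        row["prs_quintile"], row["hei_z"] = 5, 1.0
        (X,) = patsy.build_design_matrices([fit.design_info],
                                           pd.DataFrame([row]),
                                           return_type="dataframe")
        want = float(
            (X.to_numpy() @ pooled.table["estimate"].reindex(X.columns).to_numpy())[0]
        )
        got = grid[(grid["quintile"] == 5) & (grid["exposure_z"] == 1.0)]
        assert got["predicted"].iloc[0] == pytest.approx(want)

    def test_negative_q5_interaction_flattens_q5_slope(self):
        df, fit, pooled = self.prepare()
        spec = ModelSpec(outcome="waist", covariates=("sex", "age"),
                         categorical=("sex",), quintile_col="prs_quintile")
        grid = interaction_plot_grid(pooled, fit, df, spec,
                                     hei_grid=np.array([-1.0, 1.0]))
        slope = {}
        for q in (1, 5):
            g = grid[grid["quintile"] == q].sort_values("exposure_z")
            slope[q] = (g["predicted"].iloc[-1] - g["predicted"].iloc[0]) / 2
        # generating interaction is negative: Q5 slope below Q1 slope
        assert slope[5] < slope[1]
        assert (grid["reference_cutoff"] == 102.0).all()

    def test_quintile_outside_range_rejected(self):
        df, fit, pooled = self.prepare()
        spec = ModelSpec(outcome="waist", covariates=("sex", "age"),
                         categorical=("sex",), quintile_col="prs_quintile")
        with pytest.raises(ValueError):
            interaction_plot_grid(pooled, fit, df, spec, quintiles=(0, 5))
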