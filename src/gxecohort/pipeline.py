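"""End-to-end orchestration: simulate -> score -> link -> impute -> analyze.

A single configuration mapping drives the whole run.  The pipeline
generates (or loads) the cohort, constructs the PRS and ancestry PCs,
scores the HEI-C, classifies energy misreporting, builds smoothed retail
exposures, links geography and census covariates, imposes the configured
missingness, imputes m times, fits the diet-sample (GLM, PRS x HEI-C) and
retail-sample (FSA-clustered GEE, PRS x each of the four marketing ratios)
interaction models, pools with Rubin's rules, and writes tidy report CSVs
plus a JSON run manifest.  Identical config + seed reproduces identical
outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import energy, genetics, linkage, retail as retail_mod
from .diet import classify_adiposity_table, score_hei_table
from .impute import ImputationSpec, mice_impute, pool_estimates
from .models import (
    CENSUS_COVARIATES,
    DEFAULT_COVARIATES,
    ModelSpec,
    quintile_model,
    run_analysis,
    tidy,
    trend_test,
)
from .simulate import SimulationConfig, apply_missingness, simulate_study

DEFAULT_CONFIG = {
    "n_subjects": 2000,
    "n_fsa": 40,
    "seed": 0,
    "m_diet": 20,
    "m_retail": 50,
    "mice_iterations": 10,
    "smoothing_decay": 0.3,
    "retail_fsa_coverage": 0.8,   # share of FSAs represented in the panel
    "missing_rates": {"hei_total": 0.06, "waist": 0.03, "bodyfat": 0.05},
    "outcomes": ["waist", "bmi", "bodyfat"],
    "retail_ratios": ["variety_ratio", "price_ratio",
                      "discount_ratio", "display_ratio"],
    "run_retail": True,
    "run_stratified": True,
    "run_quintile": True,
    "run_sensitivity": True,
}

#: covariates available in the synthetic cohort (a subset of the full
#: questionnaire adjustment set; absent columns are dropped at fit time)
def _present_covariates(table, covariates=DEFAULT_COVARIATES, extra=()):
    return tuple(c for c in tuple(covariates) + tuple(extra) if c in table.columns)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _prepare_analysis_tables(completed: list) -> list:
    """Within-dataset transforms after imputation: standardize exposures,
    rebuild the interaction inputs, assign PRS quintiles."""
    out = []
    for t in completed:
        t = t.copy()
        t["hei_z"] = genetics.standardize(t["hei_total"])
        t["prs_z"] = genetics.standardize(t["prs"])
        t["prs_quintile"] = genetics.assign_quintiles(t["prs"]).astype(int)
        out.append(t)
    return out


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None,
                 seed: int | None = None) -> dict:
    """Execute the full synthetic-study analysis; return the run manifest.

    ``config`` overrides :data:`DEFAULT_CONFIG` key-by-key; ``seed``
    overrides ``config['seed']``.  When ``out_dir`` is given every report
    table is written there as CSV along with ``manifest.json``.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    manifest = {"config_hash": _config_hash(cfg), "seed": cfg["seed"],
                "stages": {}, "warnings": [], "outputs": []}
    t_start = time.time()
    reports: dict[str, pd.DataFrame] = {}

    # --- stage: simulate -------------------------------------------------
    t0 = time.time()
    sim_cfg = SimulationConfig(
        n_subjects=cfg["n_subjects"], n_fsa=cfg["n_fsa"], seed=cfg["seed"],
        smoothing_decay=cfg["smoothing_decay"],
        missing_rates=cfg["missing_rates"],
    )
    study = simulate_study(sim_cfg)
    subjects = study.subjects
    manifest["stages"]["simulate"] = round(time.time() - t0, 3)

    # --- stage: score ----------------------------------------------------
    t0 = time.time()
    pcs, _ = genetics.principal_components(study.genotypes, k=3)
    subjects = subjects.join(pcs)
    bmr = pd.Series(
        [energy.predict_bmr(r["sex"], r["age"], r["weight"], r["height"])
         for _, r in subjects.iterrows()], index=subjects.index)
    subjects["bmr"] = bmr
    subjects["reporter"] = [
        energy.classify_reporter(e, b)
        for e, b in zip(subjects["energy"], subjects["bmr"])
    ]
    adip = classify_adiposity_table(
        subjects.rename(columns={"bodyfat": "bodyfat_pct"})
        [["bmi", "waist", "bodyfat_pct", "sex"]])
    subjects = subjects.join(adip)
    manifest["stages"]["score"] = round(time.time() - t0, 3)

    # --- stage: retail exposures + linkage -------------------------------
    t0 = time.time()
    exposures = None
    if cfg["run_retail"] and study.retail is not None and len(study.retail):
        rng = np.random.default_rng(np.random.SeedSequence([cfg["seed"], 811]))
        fsas = sorted(study.retail["fsa"].unique())
        n_keep = max(2, int(round(cfg["retail_fsa_coverage"] * len(fsas))))
        keep = set(rng.choice(fsas, size=n_keep, replace=False))
        panel_obs = study.retail[study.retail["fsa"].isin(keep)]
        exposures = retail_mod.build_exposures(
            panel_obs, decay=cfg["smoothing_decay"], include_components=True)
    else:
        manifest["warnings"].append(
            "retail panel unavailable; retail analysis skipped")
    if exposures is not None:
        linked, link_report = linkage.link_retail(subjects, exposures)
        linked = linkage.link_census(linked, study.census)
        manifest["stages"]["linkage_coverage"] = round(link_report["coverage"], 4)
        subjects = linked
    else:
        subjects["season"] = subjects["quarter"].map(linkage.season_from_quarter)
    manifest["stages"]["retail_link"] = round(time.time() - t0, 3)

    # --- stage: missingness ----------------------------------------------
    t0 = time.time()
    masked, mask_log = apply_missingness(
        subjects, cfg["missing_rates"], mechanism="MAR",
        seed=int(np.random.SeedSequence([cfg["seed"], 99]).generate_state(1)[0] % 2**31))
    manifest["stages"]["missingness_cells"] = int(len(mask_log))
    manifest["stages"]["mask"] = round(time.time() - t0, 3)

    # --- stage: descriptives ---------------------------------------------
    t0 = time.time()
    desc = descriptive_report(masked)
    reports.update(desc)
    manifest["stages"]["descriptives"] = round(time.time() - t0, 3)

    # --- stage: impute + diet analysis -----------------------------------
    t0 = time.time()
    masked["sex_female"] = (masked["sex"] == "female").astype(float)
    impute_vars = {v: "linear" for v in cfg["missing_rates"]
                   if v in masked.columns}
    aux = [c for c in ("prs", "age", "sex_female", "energy", "bmi",
                       "physical_activity") if c in masked.columns]
    spec_mi = ImputationSpec(
        m=cfg["m_diet"], variables=impute_vars, auxiliary=aux,
        n_iter=cfg["mice_iterations"],
        seed=int(np.random.SeedSequence([cfg["seed"], 7]).generate_state(1)[0] % 2**31))
    completed = mice_impute(masked, spec_mi)
    tables = _prepare_analysis_tables(completed)
    manifest["stages"]["impute_diet"] = round(time.time() - t0, 3)

    t0 = time.time()
    covs = _present_covariates(tables[0])
    diet_rows = []
    for outcome in cfg["outcomes"]:
        spec = ModelSpec(outcome=outcome, covariates=covs)
        diet_rows.append(tidy(run_analysis(spec, tables), f"{outcome}~prs_z*hei_z"))
        if cfg["run_stratified"]:
            covs_nosex = tuple(c for c in covs if c != "sex")
            for sx in ("male", "female"):
                sub = [t[t["sex"] == sx] for t in tables]
                sspec = ModelSpec(outcome=outcome, covariates=covs_nosex)
                diet_rows.append(
                    tidy(run_analysis(sspec, sub), f"{outcome}~prs_z*hei_z|{sx}"))
        if cfg["run_quintile"]:
            fits = [quintile_model(
                ModelSpec(outcome=outcome, covariates=covs), t) for t in tables]
            est = pd.DataFrame([f.params for f in fits]).reset_index(drop=True)
            var = pd.DataFrame([f.variances for f in fits]).reset_index(drop=True)
            pooled = pool_estimates(est, var, df_com=fits[0].df_resid)
            diet_rows.append(tidy(pooled, f"{outcome}~quintiles*hei_z"))
        if cfg["run_sensitivity"]:
            sens = ModelSpec(outcome=outcome, covariates=covs, drop_energy=True)
            diet_rows.append(
                tidy(run_analysis(sens, tables), f"{outcome}~prs_z*hei_z|no_energy"))
    reports["diet_analysis"] = pd.concat(diet_rows, ignore_index=True)
    manifest["stages"]["diet_models"] = round(time.time() - t0, 3)

    # --- stage: retail analysis (GEE, clustered by FSA) -------------------
    if exposures is not None:
        t0 = time.time()
        retail_sample = masked[masked["fsa"].notna()].copy()
        retail_sample["sex_female"] = (retail_sample["sex"] == "female").astype(float)
        ratio_vars = {r: "linear" for r in cfg["retail_ratios"]
                      if retail_sample[r].isna().any()}
        ratio_vars.update({v: "linear" for v in cfg["missing_rates"]
                           if v in retail_sample.columns})
        aux_retail = aux + [c for c in retail_sample.columns
                            if c.startswith(("veg_", "soda_"))]
        aux_retail = [a for a in aux_retail
                      if not retail_sample[a].isna().all()]
        spec_ri = ImputationSpec(
            m=cfg["m_retail"], variables=ratio_vars, auxiliary=aux_retail,
            n_iter=cfg["mice_iterations"],
            seed=int(np.random.SeedSequence([cfg["seed"], 13]).generate_state(1)[0] % 2**31))
        completed_r = mice_impute(retail_sample, spec_ri)
        rtables = []
        for t in _prepare_analysis_tables(completed_r):
            for r in cfg["retail_ratios"]:
                t[f"{r}_z"] = genetics.standardize(t[r])
            rtables.append(t)
        covs_r = _present_covariates(rtables[0], extra=CENSUS_COVARIATES)
        retail_rows = []
        retail_outcomes = list(cfg["outcomes"]) + ["hei_total"]
        for outcome in retail_outcomes:
            for r in cfg["retail_ratios"]:
                use_covs = covs_r
                if outcome == "hei_total":
                    use_covs = tuple(c for c in covs_r if c != "reporter")
                rspec = ModelSpec(outcome=outcome,
                                  exposures=("prs_z", f"{r}_z"),
                                  covariates=use_covs, estimator="gee")
                retail_rows.append(
                    tidy(run_analysis(rspec, rtables), f"{outcome}~prs_z*{r}"))
        reports["retail_analysis"] = pd.concat(retail_rows, ignore_index=True)
        manifest["stages"]["retail_models"] = round(time.time() - t0, 3)

    manifest["elapsed"] = round(time.time() - t_start, 3)
    manifest["truth"] = {k: dict(v) if hasattr(v, "items") else v
                         for k, v in study.truth["effect_sizes"].items()}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in reports.items():
            path = out / f"{name}.csv"
            df.to_csv(path, index=False, float_format="%.10g")
            manifest["outputs"].append(str(path))
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str))
    manifest["reports"] = reports
    return manifest


def descriptive_report(cohort: pd.DataFrame) -> dict:
    """Cohort characteristic summaries and HEI-quartile component profiles.

    Returns report tables: ``characteristics`` (means/SDs and counts),
    ``hei_by_quartile`` (least-squares means of each HEI-C component per
    total-score quartile, adjusted for sex, age, total energy and reporter
    status, with a trend p-value).
    """
    num_cols = [c for c in ("age", "waist", "bmi", "bodyfat", "prs",
                            "hei_total", "energy", "alcohol",
                            "physical_activity") if c in cohort.columns]
    char_rows = [{"characteristic": c,
                  "mean": float(cohort[c].mean()),
                  "sd": float(cohort[c].std(ddof=1)),
                  "n": int(cohort[c].notna().sum())} for c in num_cols]
    for c in ("sex", "reporter", "income", "education"):
        if c in cohort.columns:
            for level, cnt in cohort[c].value_counts().items():
                char_rows.append({"characteristic": f"{c}={level}",
                                  "mean": float(cnt / len(cohort)),
                                  "sd": float("nan"), "n": int(cnt)})
    characteristics = pd.DataFrame(char_rows)

    out = {"characteristics": characteristics}
    if "hei_total" in cohort.columns:
        ok = cohort[cohort["hei_total"].notna()].copy()
        qs = ok["hei_total"].rank(method="first") / len(ok)
        ok["hei_quartile"] = np.minimum((qs * 4).apply(np.ceil).astype(int), 4)
        comp_cols = [c for c in (
            "fruit_and_vegetables", "whole_fruit", "greens_and_beans",
            "whole_grains", "dairy", "total_protein", "seafood_plant_protein",
            "fatty_acid_ratio", "refined_grains", "sodium",
            "empty_calorie_pct") if c in ok.columns]
        rows = []
        for comp in comp_cols:
            ls = ls_means(ok, comp, "hei_quartile",
                          adjustment=("sex", "age", "energy", "reporter"))
            tt = trend_test(ok, comp, "hei_quartile")
            row = {"component": comp, "p_trend": tt["p"]}
            row.update({f"q{g}": v for g, v in ls.items()})
            rows.append(row)
        out["hei_by_quartile"] = pd.DataFrame(rows)
    return out


def ls_means(table: pd.DataFrame, outcome: str, group_col: str,
             adjustment: tuple = ("sex", "age", "energy", "reporter"),
             categorical: tuple = ("sex", "reporter")) -> dict:
    """Least-squares (adjusted) means of ``outcome`` per group.

    Fits OLS of the outcome on the group factor plus the adjustment set and
    predicts each group at the covariate means (numeric) / observed mix
    (categorical, via averaging predictions over the sample).
    """
    import statsmodels.formula.api as smf

    adj = [c for c in adjustment if c in table.columns]
    terms = [f"C({group_col})"] + [f"C({c})" if c in categorical else c
                                   for c in adj]
    work = table.dropna(subset=[outcome, group_col] + adj)
    res = smf.ols(f"{outcome} ~ {' + '.join(terms)}", data=work).fit()
    means = {}
    for g in sorted(work[group_col].unique()):
        counterfactual = work.copy()
        counterfactual[group_col] = g
        means[g] = float(res.predict(counterfactual).mean())
    return means
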