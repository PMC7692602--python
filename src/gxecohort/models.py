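"""Regression layer: GLM and FSA-clustered GEE fits with interaction terms.

Main and interaction associations are estimated with Gaussian identity-link
models: ordinary GLM for the diet analysis, and generalized estimating
equations (GEE) with an exchangeable working correlation and robust
sandwich variances for the retail analysis, where subjects cluster within
forward sortation areas.  Exposures enter standardized; the gene x
environment interaction is the product of the two standardized exposures
(or indicator x exposure products in quintile mode, quintile 1 reference).
Per-imputation fits are pooled with Rubin's rules (see
:mod:`gxecohort.impute`).  Wald tests are two-sided at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import linalg, stats

from .impute import PooledModelResult, pool_estimates

#: full individual-level adjustment set of the primary models
DEFAULT_COVARIATES = (
    "age", "sex", "PC1", "PC2", "PC3", "marital", "income", "education",
    "smoking", "energy", "alcohol", "physical_activity", "reporter",
    "language", "season", "genotyping_source",
)
DEFAULT_CATEGORICAL = (
    "sex", "marital", "income", "education", "smoking", "reporter",
    "language", "season", "genotyping_source",
)
#: neighbourhood covariates added for the retail (GEE) models
CENSUS_COVARIATES = (
    "population_density", "low_income_prevalence", "median_income",
    "pct_immigrant", "employment_rate", "pct_highschool",
)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression fit.

    ``exposures`` are already-standardized columns; with ``interaction``
    their product term is included alongside the main effects.  Setting
    ``quintile_col`` replaces the first exposure with indicator coding of
    that column (reference level 1).  ``drop_energy`` is the sensitivity
    variant that removes total energy intake from the adjustment set.
    """

    outcome: str
    exposures: tuple = ("prs_z", "hei_z")
    interaction: bool = True
    covariates: tuple = ()
    categorical: tuple = DEFAULT_CATEGORICAL
    estimator: str = "glm"           # "glm" | "gee"
    cluster: str = "fsa"
    quintile_col: str | None = None
    drop_energy: bool = False

    def formula(self) -> str:
        if self.quintile_col:
            first = f"C({self.quintile_col}, Treatment(reference=1))"
            rest = list(self.exposures[1:])
        else:
            first = self.exposures[0]
            rest = list(self.exposures[1:])
        joiner = " * " if (self.interaction and rest) else " + "
        exposure_part = joiner.join([first] + rest) if rest else first
        covs = [c for c in self.covariates if not (self.drop_energy and c == "energy")]
        terms = [f"C({c})" if c in self.categorical else c for c in covs]
        rhs = " + ".join([exposure_part] + terms) if terms else exposure_part
        return f"{self.outcome} ~ {rhs}"


@dataclass
class FitResult:
    """Per-term estimates and variances from one completed-data fit."""

    params: pd.Series
    variances: pd.Series
    df_resid: float
    design_info: object = None
    extra: dict = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "variance": self.variances})


def _check_rank(formula: str, table: pd.DataFrame):
    y, X = patsy.dmatrices(formula, table, return_type="dataframe")
    arr = X.to_numpy()
    if arr.shape[0] <= arr.shape[1]:
        raise ValueError("more model terms than observations")
    _, r, piv = linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < arr.shape[1]:
        aliased = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    return y, X


def fit_glm(spec: ModelSpec, table: pd.DataFrame) -> FitResult:
    """Gaussian identity-link fit (ordinary least squares) for one table."""
    formula = spec.formula()
    y, X = _check_rank(formula, table)
    model = sm.GLM(y, X, family=sm.families.Gaussian())
    res = model.fit()
    params = pd.Series(np.asarray(res.params).ravel(), index=X.columns)
    variances = pd.Series(np.diag(res.cov_params()), index=X.columns)
    return FitResult(params, variances, df_resid=float(res.df_resid),
                     design_info=X.design_info)


def fit_gee(spec: ModelSpec, table: pd.DataFrame,
            cluster_ids: pd.Series | None = None) -> FitResult:
    """GEE fit with exchangeable working correlation and robust variances."""
    if cluster_ids is None:
        if spec.cluster not in table.columns:
            raise KeyError(f"cluster column {spec.cluster!r} not in table")
        cluster_ids = table[spec.cluster]
    if cluster_ids.isna().any():
        raise ValueError("cluster ids contain missing values")
    if cluster_ids.nunique() < 2:
        raise ValueError("GEE needs at least 2 clusters")
    formula = spec.formula()
    _check_rank(formula, table)
    cov_struct = sm.cov_struct.Exchangeable()
    model = smf.gee(formula, groups=cluster_ids, data=table,
                    family=sm.families.Gaussian(), cov_struct=cov_struct)
    res = model.fit()
    params = pd.Series(np.asarray(res.params), index=res.params.index)
    variances = pd.Series(np.diag(res.cov_params()), index=res.params.index)
    n = len(table)
    return FitResult(
        params, variances,
        df_resid=float(n - len(params)),
        design_info=getattr(res.model.data, "design_info", None),
        extra={"working_corr": float(cov_struct.dep_params)},
    )


def fit_model(spec: ModelSpec, table: pd.DataFrame) -> FitResult:
    if spec.estimator == "gee":
        return fit_gee(spec, table)
    if spec.estimator == "glm":
        return fit_glm(spec, table)
    raise ValueError(f"unknown estimator {spec.estimator!r}")


def quintile_model(spec: ModelSpec, table: pd.DataFrame,
                   quintile_col: str = "prs_quintile") -> FitResult:
    """Indicator-coded quintile fit with Q1 reference and Qk x exposure terms."""
    qspec = replace(spec, quintile_col=quintile_col)
    counts = table[quintile_col].value_counts()
    for q in range(1, 6):
        if counts.get(q, 0) == 0:
            raise ValueError(f"quintile {q} is empty")
    return fit_model(qspec, table)


def trend_test(table: pd.DataFrame, outcome: str, group_col: str,
               adjustment: tuple = ("sex", "age", "energy", "reporter"),
               categorical: tuple = ("sex", "reporter")) -> dict:
    """Two-sided p for a linear trend of ``outcome`` across ordered groups.

    Groups are integer-coded in their sorted order (so shifting all labels
    by a constant changes nothing); the trend coefficient is tested by a
    Wald t-test in an OLS fit with the configured adjustment covariates.
    """
    groups = sorted(pd.Series(table[group_col]).dropna().unique())
    if len(groups) < 2:
        raise ValueError("trend test needs at least 2 ordered groups")
    work = table.copy()
    work["_trend"] = work[group_col].map({g: i for i, g in enumerate(groups)})
    terms = ["_trend"] + [f"C({c})" if c in categorical else c
                          for c in adjustment if c in work.columns]
    res = smf.ols(f"{outcome} ~ {' + '.join(terms)}", data=work).fit()
    return {"estimate": float(res.params["_trend"]),
            "p": float(res.pvalues["_trend"]),
            "n": int(res.nobs)}


def run_analysis(spec: ModelSpec, imputed_tables: list) -> PooledModelResult:
    """Fit ``spec`` in every completed dataset and pool with Rubin's rules."""
    if len(imputed_tables) < 1:
        raise ValueError("need at least one completed table")
    fits = [fit_model(spec, t) for t in imputed_tables]
    est = pd.DataFrame([f.params for f in fits]).reset_index(drop=True)
    var = pd.DataFrame([f.variances for f in fits]).reset_index(drop=True)
    pooled = pool_estimates(est, var, df_com=fits[0].df_resid)
    pooled.table.attrs["formula"] = spec.formula()
    return pooled


def tidy(pooled: PooledModelResult, model_label: str = "") -> pd.DataFrame:
    """Report-shaped frame: term, beta, 95% CI, p."""
    t = pooled.table
    out = pd.DataFrame({
        "model": model_label, "term": t.index,
        "beta": t["estimate"].to_numpy(),
        "ci_low": t["ci_low"].to_numpy(), "ci_high": t["ci_high"].to_numpy(),
        "p": t["p"].to_numpy(),
    })
    return out.reset_index(drop=True)


#: reference cutoffs drawn on interaction plots, per outcome and sex
PLOT_CUTOFFS = {
    "waist": {"male": 102.0, "female": 88.0},
    "bmi": {"male": 30.0, "female": 30.0},
    "bodyfat": {"male": 25.0, "female": 35.0},
}


def interaction_plot_grid(
    pooled: PooledModelResult,
    fit: FitResult,
    data: pd.DataFrame,
    spec: ModelSpec,
    hei_grid=np.linspace(-2, 2, 9),
    quintiles=(1, 5),
    sex: str = "male",
) -> pd.DataFrame:
    """Predicted outcome over a standardized-HEI grid for extreme quintiles.

    Predictions are evaluated at covariate means (numeric) / modal levels
    (categorical) using the stored design information, multiplied by the
    pooled coefficient vector.  The output includes the obesity reference
    cutoff for the outcome so plots can draw the threshold line.
    """
    if spec.quintile_col is None:
        raise ValueError("spec must be a quintile model (quintile_col set)")
    for q in quintiles:
        if q not in range(1, 6):
            raise ValueError(f"quintile {q} outside 1..5")
    if fit.design_info is None:
        raise ValueError("fit carries no design information")

    grid_exposure = spec.exposures[1]
    base = {}
    for col in data.columns:
        s = data[col]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
            base[col] = float(s.mean())
        else:
            base[col] = s.mode(dropna=True).iloc[0]
    rows = []
    for q in quintiles:
        for x in hei_grid:
            row = dict(base)
            row[spec.quintile_col] = q
            row[grid_exposure] = float(x)
            rows.append(row)
    grid = pd.DataFrame(rows)
    (X,) = patsy.build_design_matrices([fit.design_info], grid, return_type="dataframe")
    coef = pooled.table["estimate"].reindex(X.columns)
    if coef.isna().any():
        raise ValueError("pooled terms do not match the design matrix")
    grid_out = grid[[spec.quintile_col, grid_exposure]].copy()
    grid_out.columns = ["quintile", "exposure_z"]
    grid_out["predicted"] = X.to_numpy() @ coef.to_numpy()
    cutoff = PLOT_CUTOFFS.get(spec.outcome, {}).get(sex, np.nan)
    grid_out["reference_cutoff"] = cutoff
    return grid_out


def wald_interaction_p(fit: FitResult, term_substring: str = ":") -> float:
    """Two-sided Wald p-value of the (first) interaction term in a fit."""
    terms = [t for t in fit.params.index if term_substring in t]
    if not terms:
        raise KeyError("no interaction term in fit")
    t0 = terms[0]
    z = fit.params[t0] / np.sqrt(fit.variances[t0])
    return float(2 * stats.norm.sf(abs(z)))
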