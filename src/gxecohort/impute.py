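"""Multiple imputation by chained equations (MICE) and Rubin's-rules pooling.

Missing analysis variables are filled m times by cycling per-variable
conditional regressions: a Bayesian posterior-draw linear model for
continuous variables and a logistic model (coefficient draw + Bernoulli
draw) for binaries, each regressing the variable on every other spec
variable plus the configured auxiliaries.  Imputations use independent
seeded sub-streams, so a run is reproducible bit-for-bit.

Estimates fitted within each completed dataset are combined with Rubin's
rules: pooled estimate Q-bar, within-imputation variance W-bar, between
variance B, total variance T = W-bar + (1 + 1/m) B, with Barnard-Rubin
small-sample degrees of freedom for the t-based intervals and p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ImputationSpec:
    """Configuration for one chained-equations run.

    ``variables`` maps each variable that may contain missing values to its
    conditional model type (``linear`` or ``logistic``); ``auxiliary`` lists
    extra fully-usable predictor columns (e.g. the four category-specific
    retail measures) that inform imputation without being imputed
    themselves unless they too appear in ``variables``.
    """

    m: int = 20
    variables: dict = field(default_factory=dict)
    auxiliary: list = field(default_factory=list)
    n_iter: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        for v, kind in self.variables.items():
            if kind not in ("linear", "logistic"):
                raise ValueError(f"unknown conditional model {kind!r} for {v!r}")


def _posterior_draw_linear(X, y, Xmis, rng):
    """Impute via a Bayesian linear regression posterior draw.

    sigma^2 drawn from its scaled inverse-chi-square posterior, beta from
    N(beta_hat, sigma^2 (X'X)^-1), then missing values from the predictive
    normal.  Ridge jitter guards rank-deficient corner cases.
    """
    n, p = X.shape
    XtX = X.T @ X + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    df = max(n - p, 1)
    sigma2 = (resid @ resid) / stats.chi2.rvs(df, random_state=rng)
    cov = sigma2 * np.linalg.inv(XtX)
    # svd-based draw tolerates the near-singular covariances that
    # collinear auxiliary predictors produce
    beta = rng.multivariate_normal(beta_hat, cov, method="svd")
    return Xmis @ beta + np.sqrt(sigma2) * rng.standard_normal(Xmis.shape[0])


def _posterior_draw_logistic(X, y, Xmis, rng):
    import statsmodels.api as sm

    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=50)
        beta = rng.multivariate_normal(
            np.asarray(fit.params), np.asarray(fit.cov_params()), method="svd"
        )
    except Exception:
        # separation or non-convergence: fall back to the marginal rate
        p = np.full(Xmis.shape[0], max(min(y.mean(), 1 - 1e-6), 1e-6))
        return (rng.random(Xmis.shape[0]) < p).astype(float)
    p = 1.0 / (1.0 + np.exp(-(Xmis @ beta)))
    return (rng.random(Xmis.shape[0]) < p).astype(float)


def mice_impute(table: pd.DataFrame, spec: ImputationSpec) -> list:
    """Return ``spec.m`` completed copies of ``table``.

    Only the columns named in ``spec.variables`` are imputed; predictors are
    all other spec variables plus ``spec.auxiliary`` columns (their own
    missing cells are mean-filled for prediction only).  A table with no
    missing cells among the modeled variables returns m identical copies.
    """
    for v in list(spec.variables) + list(spec.auxiliary):
        if v not in table.columns:
            raise KeyError(f"spec variable {v!r} not in table")
    modeled = [v for v in spec.variables if table[v].isna().any()]
    for v in modeled:
        if table[v].isna().all():
            raise ValueError(f"variable {v!r} is 100% missing; nothing to condition on")
    if not modeled:
        return [table.copy() for _ in range(spec.m)]

    predictors = sorted(set(spec.variables) | set(spec.auxiliary))
    base = table[predictors].astype(float)
    mask = base.isna()

    completed = []
    ss = np.random.SeedSequence(spec.seed)
    for child in ss.spawn(spec.m):
        rng = np.random.default_rng(child)
        work = base.copy()
        # initialize each missing cell with a bootstrap draw from observed values
        for v in predictors:
            miss = mask[v]
            if miss.any():
                obs = work.loc[~miss, v].to_numpy()
                if obs.size == 0:
                    work.loc[miss, v] = 0.0
                else:
                    work.loc[miss, v] = rng.choice(obs, size=int(miss.sum()))
        for _ in range(spec.n_iter):
            for v in modeled:
                miss = mask[v].to_numpy()
                others = [c for c in predictors if c != v]
                X = np.column_stack([np.ones(len(work)), work[others].to_numpy()])
                y = work[v].to_numpy()
                if spec.variables[v] == "linear":
                    drawn = _posterior_draw_linear(X[~miss], y[~miss], X[miss], rng)
                else:
                    drawn = _posterior_draw_logistic(X[~miss], y[~miss], X[miss], rng)
                work.iloc[miss, work.columns.get_loc(v)] = drawn
        out = table.copy()
        for v in modeled:
            out[v] = out[v].astype(float)
            out.loc[mask[v], v] = work.loc[mask[v], v]
        completed.append(out)
    return completed


@dataclass
class PooledModelResult:
    """Tidy per-term pooled estimates.

    ``table`` columns: estimate (Q-bar), within (W-bar), between (B),
    total_var (T), se, df, ci_low, ci_high, p; indexed by term name.
    """

    table: pd.DataFrame
    m: int

    def __getitem__(self, term):
        return self.table.loc[term]


def pool_estimates(
    estimates: pd.DataFrame,
    variances: pd.DataFrame,
    df_com: float | None = None,
    alpha: float = 0.05,
) -> PooledModelResult:
    """Rubin's-rules pooling of m per-imputation fits.

    ``estimates`` and ``variances`` are m x terms frames (rows =
    imputations) with identical columns.  ``df_com`` is the complete-data
    residual degrees of freedom used for the Barnard-Rubin adjustment; when
    omitted, the large-sample formula applies.
    """
    estimates = pd.DataFrame(estimates)
    variances = pd.DataFrame(variances)
    if list(estimates.columns) != list(variances.columns):
        raise ValueError("estimate and variance term sets differ")
    if estimates.shape != variances.shape:
        raise ValueError("estimate and variance shapes differ")
    m = len(estimates)

    qbar = estimates.mean(axis=0)
    wbar = variances.mean(axis=0)
    b = estimates.var(axis=0, ddof=1) if m > 1 else pd.Series(0.0, index=qbar.index)
    t = wbar + (1 + 1 / m) * b

    rows = {}
    for term in qbar.index:
        T = t[term]
        se = np.sqrt(T)
        if m > 1 and b[term] > 0:
            lam = (1 + 1 / m) * b[term] / T
            nu_old = (m - 1) / lam**2
            if df_com is not None and np.isfinite(df_com):
                nu_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
                nu = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
            else:
                nu = nu_old
        else:
            nu = df_com if df_com is not None else np.inf
        dist = stats.t(nu) if np.isfinite(nu) else stats.norm()
        crit = dist.ppf(1 - alpha / 2)
        z = qbar[term] / se if se > 0 else np.inf * np.sign(qbar[term])
        p = 2 * dist.sf(abs(z)) if se > 0 else 0.0
        rows[term] = {
            "estimate": qbar[term], "within": wbar[term], "between": b[term],
            "total_var": T, "se": se, "df": nu,
            "ci_low": qbar[term] - crit * se, "ci_high": qbar[term] + crit * se,
            "p": p,
        }
    return PooledModelResult(pd.DataFrame(rows).T, m=m)
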