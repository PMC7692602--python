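"""Geo-temporal linkage of subjects to retail exposures and census covariates.

Subjects are joined to smoothed retail exposures by forward sortation area
(FSA, the first three characters of a Canadian postal code) and to census
covariates by census tract.  Both joins are left joins: subjects that
cannot be linked are retained with missing exposure/covariate values and a
logged reason, so the downstream multiple-imputation stage sees them.
Season is derived from the calendar quarter of the assessment as a proxy:
Q4 and Q1 fall in October-March, Q2 and Q3 in April-September.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

CENSUS_COVARIATES = [
    "population_density", "low_income_prevalence", "median_income",
    "pct_immigrant", "employment_rate", "pct_highschool",
]

_FSA_RE = re.compile(r"^[A-Za-z][0-9][A-Za-z]$")


def season_from_quarter(quarter) -> str | float:
    """Map a year-quarter label like ``2011Q3`` to its season half."""
    if pd.isna(quarter):
        return np.nan
    q = int(str(quarter).strip()[-1])
    return "Oct-Mar" if q in (4, 1) else "Apr-Sep"


def link_retail(subjects: pd.DataFrame, exposures: pd.DataFrame):
    """Attach retail exposures to subjects by FSA.

    Returns ``(linked, report)`` where ``report`` carries the coverage
    fraction (linked among subjects with a valid FSA) and per-subject link
    status.  Malformed or absent FSAs leave the exposures missing; the
    subject row is never dropped.
    """
    out = subjects.copy()
    fsa = out.get("fsa")
    if fsa is None:
        raise KeyError("subjects table has no 'fsa' column")

    valid = fsa.notna() & fsa.astype(str).str.match(_FSA_RE.pattern, na=False)
    status = pd.Series("linked", index=out.index, dtype=object)
    status[~valid & fsa.notna()] = "malformed FSA"
    status[fsa.isna()] = "no postal code"

    exp = exposures.reset_index() if exposures.index.name == "fsa" else exposures.copy()
    merged = out.merge(exp, on="fsa", how="left", suffixes=("", "_exposure"))
    merged.index = out.index
    ratio_cols = [c for c in exp.columns if c.endswith("_ratio")]
    unlinked = valid & merged[ratio_cols].isna().all(axis=1)
    status[unlinked] = "FSA not in retail panel"
    # clear anything that leaked onto malformed keys (exact join should not match)
    merged.loc[~valid, ratio_cols] = np.nan

    if "quarter" in merged.columns and "season" not in merged.columns:
        merged["season"] = merged["quarter"].map(season_from_quarter)

    coverage = float((status[valid] == "linked").mean()) if valid.any() else 0.0
    report = {"coverage": coverage, "status": status,
              "n_no_postal": int((status == "no postal code").sum())}
    return merged, report


def link_census(cohort: pd.DataFrame, census: pd.DataFrame) -> pd.DataFrame:
    """Left-join census covariates by tract; duplicate tract keys are an error."""
    cen = census.reset_index() if census.index.name == "tract" else census.copy()
    if "tract" not in cen.columns:
        raise KeyError("census table has no 'tract' column")
    if cen["tract"].duplicated().any():
        dupes = cen.loc[cen["tract"].duplicated(), "tract"].unique().tolist()
        raise ValueError(f"duplicate census tract keys: {dupes}")
    if "tract" not in cohort.columns:
        raise KeyError("cohort has no 'tract' column")
    add = [c for c in cen.columns if c != "tract" and c not in cohort.columns]
    merged = cohort.merge(cen[["tract"] + add], on="tract", how="left")
    merged.index = cohort.index
    return merged
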