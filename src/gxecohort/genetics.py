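"""Polygenic risk score construction and ancestry adjustment.

The obesity polygenic risk score (PRS) is an additive count of risk alleles
across 97 BMI-associated loci: each subject's score is the weighted sum of
their risk-allele dosages (0-2 per locus), so with unit weights the score
spans 0-194.  Ancestry structure is summarised by principal components of
the centred dosage matrix; the first few components enter downstream models
as covariates.  Quintile assignment and z-standardization of the score are
also provided here because they are genetics-facing transforms of the same
quantity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_DEFAULT_LOCI = 97


def default_score_definition(n_loci: int = N_DEFAULT_LOCI) -> pd.DataFrame:
    """Return a synthetic stand-in score definition with unit weights.

    The identity and weights of the real BMI loci live in the source GWAS;
    this packaged definition is a synthetic placeholder with the correct
    cardinality (97 loci) and the default unweighted (weight = 1) counting
    scheme.  Columns: ``locus``, ``effect_allele``, ``weight``.
    """
    return pd.DataFrame(
        {
            "locus": [f"snp_{i:03d}" for i in range(1, n_loci + 1)],
            "effect_allele": ["A"] * n_loci,
            "weight": np.ones(n_loci),
        }
    )


def validate_score_definition(score_def: pd.DataFrame) -> None:
    if score_def["locus"].duplicated().any():
        dupes = score_def.loc[score_def["locus"].duplicated(), "locus"].tolist()
        raise ValueError(f"duplicate locus ids in score definition: {dupes}")
    if not np.isfinite(score_def["weight"].to_numpy(dtype=float)).all():
        raise ValueError("score definition contains non-finite weights")


def compute_prs(
    genotypes: pd.DataFrame,
    score_def: pd.DataFrame | None = None,
    return_flags: bool = False,
):
    """Additive risk-allele score per subject.

    Parameters
    ----------
    genotypes
        Subjects x loci dosage matrix, values in [0, 2]; NaN marks a missing
        dosage call.
    score_def
        Table with columns ``locus`` and ``weight``.  Defaults to the
        packaged unit-weight 97-locus definition restricted to the matrix's
        columns only if the matrix carries exactly those loci.
    return_flags
        If True, also return a boolean Series flagging subjects whose score
        used any frequency-imputed dosage.

    Missing dosages are substituted with twice the locus risk-allele
    frequency estimated from non-missing subjects (the expected dosage under
    Hardy-Weinberg), and affected subjects are flagged.
    """
    if score_def is None:
        score_def = default_score_definition(genotypes.shape[1])
        score_def["locus"] = list(genotypes.columns)
    validate_score_definition(score_def)

    missing_loci = [l for l in score_def["locus"] if l not in genotypes.columns]
    if missing_loci:
        raise KeyError(f"loci absent from genotype matrix: {missing_loci}")

    X = genotypes[score_def["locus"]].to_numpy(dtype=float)
    finite = np.isfinite(X)
    if not finite.all(axis=0).all():
        n_obs = finite.sum(axis=0)
        if (n_obs == 0).any():
            bad = np.asarray(score_def["locus"])[n_obs == 0].tolist()
            raise ValueError(f"all dosages missing at loci: {bad}")
        # expected dosage 2*p from non-missing subjects
        col_mean = np.nansum(np.where(finite, X, 0.0), axis=0) / n_obs
        X = np.where(finite, X, col_mean[None, :])

    out_of_range = finite & ((genotypes[score_def["locus"]].to_numpy(dtype=float) < 0)
                             | (genotypes[score_def["locus"]].to_numpy(dtype=float) > 2))
    if out_of_range.any():
        j = np.where(out_of_range.any(axis=0))[0][0]
        raise ValueError(
            f"dosage outside [0, 2] at locus {score_def['locus'].iloc[j]!r}"
        )

    w = score_def["weight"].to_numpy(dtype=float)
    score = pd.Series(X @ w, index=genotypes.index, name="prs")
    if return_flags:
        flags = pd.Series(~finite.all(axis=1), index=genotypes.index, name="prs_imputed")
        return score, flags
    return score


def principal_components(genotypes: pd.DataFrame, k: int = 3):
    """First ``k`` principal components of the column-centred dosage matrix.

    Returns ``(scores, explained)`` where ``scores`` is an n x k DataFrame
    (columns PC1..PCk) and ``explained`` the fraction of total variance each
    component captures.  Sign convention: within each component the loading
    of largest magnitude is made positive, so results are reproducible
    across LAPACK builds.
    """
    n, p = genotypes.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(n_subjects-1, n_loci)={min(n - 1, p)}")
    X = genotypes.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    if np.allclose(X, 0):
        raise ValueError("constant genotype matrix has no principal components")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U[:, :k] * s[:k]
    explained = (s**2 / (s**2).sum())[:k]
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=genotypes.index, columns=cols), explained


def assign_quintiles(values) -> pd.Series:
    """Quintile labels 1..5 with boundaries at the 20/40/60/80 percentiles.

    Ties are placed in the lower quintile (a value exactly at a boundary
    stays below it), so equal values always share a quintile and the
    assignment is monotone in the input.
    """
    v = pd.Series(values).astype(float)
    if np.unique(v.dropna()).size < 5:
        raise ValueError("need at least 5 distinct finite values for quintiles")
    bounds = np.percentile(v.dropna(), [20, 40, 60, 80])
    q = 1 + (v.to_numpy()[:, None] > bounds[None, :]).sum(axis=1)
    out = pd.Series(q, index=v.index, name="quintile", dtype="Int64")
    out[v.isna()] = pd.NA
    return out


def standardize(values) -> pd.Series:
    """Z-score: subtract the mean, divide by the sample SD (ddof=1)."""
    v = pd.Series(values).astype(float)
    sd = v.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardize a constant (or empty) vector")
    return (v - v.mean()) / sd
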