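"""Synthetic study generator with a known structural truth.

Every downstream stage of the pipeline — PRS construction, HEI-C scoring,
retail exposure building, linkage, imputation and the interaction models —
is exercised against data from this module, whose generating parameters are
recorded in an immutable truth ledger so that estimates can be compared
with the values that produced the data.

The generator emulates the study's inputs: biallelic risk-allele dosages at
97 loci in Hardy-Weinberg proportions (no linkage disequilibrium — the
score is additive, so LD is irrelevant to the downstream math), daily
food-group intake summaries and questionnaire covariates, a weekly
store-level marketing panel for vegetables and soft drinks keyed by FSA and
year-quarter, census-tract covariates, and adiposity outcomes drawn from a
linear structural model with configurable main effects and a PRS x
environment interaction, plus missing-at-random masking.

All randomness flows through one seed: stage sub-streams are spawned from
``numpy.random.SeedSequence(seed)`` in a documented fixed order
(genotypes, diet, assignment, retail, census, outcomes, missingness).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from string import ascii_uppercase
from types import MappingProxyType

import numpy as np
import pandas as pd

from . import genetics, retail as retail_mod
from .diet import score_hei_table

DEFAULT_QUARTERS = [f"{y}Q{q}" for y in (2011, 2012) for q in (1, 2, 3, 4)]

#: generating coefficients; magnitudes echo the reported per-SD effects
DEFAULT_EFFECT_SIZES = {
    "waist": {
        "intercept": 99.0, "sex_female": -11.0, "age_c": 0.15,
        "prs_z": 1.3, "hei_z": -1.6, "prs_z:hei_z": -0.5,
        "retail_z": 0.1, "prs_z:retail_z": 0.7,
    },
    "bmi": {
        "intercept": 27.5, "sex_female": -0.7, "age_c": 0.03,
        "prs_z": 0.6, "hei_z": -0.5, "prs_z:hei_z": -0.1,
        "retail_z": 0.1, "prs_z:retail_z": 0.1,
    },
    "bodyfat": {
        "intercept": 25.0, "sex_female": 10.0, "age_c": 0.10,
        "prs_z": 0.6, "hei_z": -0.7, "prs_z:hei_z": -0.2,
        "retail_z": 0.1, "prs_z:retail_z": 0.2,
    },
}
DEFAULT_NOISE_SD = {"waist": 11.0, "bmi": 4.8, "bodyfat": 6.5}

#: lognormal intake profile: component -> (median, quality loading, log-SD)
DEFAULT_DIET_PROFILE = {
    "fruit_and_vegetables": (6.8, 0.25, 0.35),
    "whole_fruit": (2.0, 0.30, 0.50),
    "greens_and_beans": (0.9, 0.35, 0.60),
    "whole_grains": (0.55, 0.30, 0.60),
    "dairy": (1.7, 0.05, 0.40),
    "total_protein": (1.7, 0.15, 0.35),
    "seafood_plant_protein": (0.4, 0.35, 0.70),
    "refined_grains": (2.5, -0.05, 0.40),
    "fatty_acid_ratio": (1.85, 0.20, 0.30),
    "sodium": (2400.0, -0.05, 0.30),
}


@dataclass
class SimulationConfig:
    """Generating conditions of a synthetic study run.

    ``effect_sizes`` maps outcome -> term -> coefficient of the structural
    model; recognised terms are ``intercept``, the standardized exposures
    ``prs_z`` / ``hei_z`` / ``retail_z``, the products ``prs_z:hei_z`` and
    ``prs_z:retail_z``, ``sex_female``, ``age_c`` (age centred at 55), or
    any numeric subject column.  ``missing_rates`` maps a variable to its
    target missingness rate in [0, 1).
    """

    n_subjects: int = 2000
    n_loci: int = 97
    allele_freqs: np.ndarray | None = None
    n_fsa: int = 40
    quarters: list = field(default_factory=lambda: list(DEFAULT_QUARTERS))
    effect_sizes: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_EFFECT_SIZES))
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    missing_rates: dict = field(default_factory=lambda: {
        "hei_z": 0.05, "energy": 0.04, "waist": 0.03, "bodyfat": 0.05,
    })
    seed: int = 0
    # diet / covariate generation
    mean_energy: float = 1716.0
    sd_energy: float = 961.0
    diet_profile: dict = field(default_factory=lambda: dict(DEFAULT_DIET_PROFILE))
    covariate_noise_scale: float = 1.0
    # geography / retail
    postal_missing_rate: float = 0.23
    tracts_per_fsa: int = 2
    weeks_per_quarter: int = 4
    stores_per_fsa: int = 2
    skus: dict = field(default_factory=lambda: {"vegetables": 6, "soft_drinks": 5})
    smoothing_decay: float = 0.3
    retail_exposure_indicator: str = "price_ratio"

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_loci < 1 or self.n_fsa < 1:
            raise ValueError("n_subjects, n_loci and n_fsa must be positive")
        if self.allele_freqs is None:
            rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 97]))
            self.allele_freqs = rng.uniform(0.05, 0.95, size=self.n_loci)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        if len(self.allele_freqs) != self.n_loci:
            raise ValueError("allele_freqs length must equal n_loci")
        bad = np.where(~np.isfinite(self.allele_freqs)
                       | (self.allele_freqs <= 0) | (self.allele_freqs >= 1))[0]
        if bad.size:
            raise ValueError(f"allele frequency outside (0,1) at locus index {bad[0]}")
        if not self.quarters:
            raise ValueError("quarters must be nonempty")
        if list(self.quarters) != sorted(self.quarters):
            raise ValueError("quarters must be sorted")
        for v, r in self.missing_rates.items():
            if not 0 <= r < 1:
                raise ValueError(f"missing rate for {v!r} must lie in [0, 1)")


@dataclass
class SyntheticStudy:
    """Bundle of all generated tables plus the immutable truth ledger."""

    genotypes: pd.DataFrame
    diet: pd.DataFrame
    retail: pd.DataFrame
    census: pd.DataFrame
    subjects: pd.DataFrame
    truth: MappingProxyType
    exposures: pd.DataFrame | None = None


def _freeze(d: dict) -> MappingProxyType:
    return MappingProxyType({
        k: _freeze(v) if isinstance(v, dict) else v for k, v in d.items()
    })


def _streams(seed: int, n: int = 8):
    return [np.random.default_rng(c)
            for c in np.random.SeedSequence(int(seed)).spawn(n)]


def simulate_genotypes(n_subjects: int, allele_freqs, seed: int) -> pd.DataFrame:
    """Binomial(2, freq) dosages per locus under Hardy-Weinberg, no LD."""
    freqs = np.asarray(allele_freqs, dtype=float)
    bad = np.where(~np.isfinite(freqs) | (freqs <= 0) | (freqs >= 1))[0]
    if bad.size:
        raise ValueError(
            f"allele frequency outside (0,1) at locus index {bad[0]} "
            f"(value {freqs[bad[0]]!r})"
        )
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, freqs[None, :], size=(n_subjects, len(freqs)))
    cols = [f"snp_{i:03d}" for i in range(1, len(freqs) + 1)]
    idx = [f"S{i:05d}" for i in range(1, n_subjects + 1)]
    return pd.DataFrame(dosages.astype(float), index=idx, columns=cols)


def _categorical(rng, levels, probs, n, scale):
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    if scale == 0:
        return np.repeat(levels[int(np.argmax(probs))], n)
    return rng.choice(levels, size=n, p=probs)


def simulate_diet_and_covariates(subject_ids, config: SimulationConfig,
                                 seed: int) -> pd.DataFrame:
    """Questionnaire covariates and daily food-group intakes per subject.

    A latent diet-quality factor q ~ N(0,1) loads (lognormally) on every
    intake, giving correlated components with positive support; empty-
    calorie energy share is logistic-normal so it stays in (0, 100).
    Energy is gamma-distributed with the configured mean and SD (positive
    support, exact configured moments).  With ``covariate_noise_scale = 0``
    every subject is identical (all noise suppressed, modal categories).
    """
    ids = pd.Index(subject_ids)
    if ids.duplicated().any():
        raise ValueError("subject ids must be unique")
    n = len(ids)
    rng = np.random.default_rng(seed)
    s = float(config.covariate_noise_scale)

    sex = _categorical(rng, np.array(["female", "male"]), [0.543, 0.457], n, s)
    female = (sex == "female").astype(float)
    age = 55.0 + 8.0 * s * rng.standard_normal(n)
    age = np.clip(age, 40.0, 70.0)
    height = np.where(female == 1, 162.0, 175.0) + 7.0 * s * rng.standard_normal(n)

    income = _categorical(rng, np.arange(1, 6), [0.08, 0.22, 0.23, 0.35, 0.12], n, s)
    education = _categorical(rng, np.array(["highschool", "college", "university"]),
                             [0.22, 0.32, 0.46], n, s)
    smoking = _categorical(rng, np.array(["never", "daily", "occasional", "past"]),
                           [0.42, 0.11, 0.04, 0.43], n, s)
    marital = _categorical(rng, np.array(["married", "divorced", "single"]),
                           [0.67, 0.19, 0.14], n, s)
    language = _categorical(rng, np.array(["french", "english"]), [0.95, 0.05], n, s)
    geno_source = _categorical(rng, np.array(["omni", "axiom", "gsa"]),
                               [0.4, 0.3, 0.3], n, s)
    pal = np.clip(1.48 + 0.36 * s * rng.standard_normal(n), 1.0, 2.5)

    if s == 0:
        energy = np.full(n, config.mean_energy)
        alcohol = np.full(n, 82.0)
        q = np.zeros(n)
    else:
        shape = (config.mean_energy / (config.sd_energy * s)) ** 2
        scale_g = (config.sd_energy * s) ** 2 / config.mean_energy
        energy = rng.gamma(shape, scale_g, size=n)
        alcohol = rng.exponential(82.0 * s, size=n)
        q = rng.standard_normal(n)

    df = pd.DataFrame({
        "sex": sex, "age": age, "height": height, "income": income,
        "education": education, "smoking": smoking, "marital": marital,
        "language": language, "genotyping_source": geno_source,
        "physical_activity": pal, "energy": energy, "alcohol": alcohol,
        "diet_quality_latent": q,
    }, index=ids)

    for comp, (median, loading, log_sd) in config.diet_profile.items():
        eps = rng.standard_normal(n) if s > 0 else np.zeros(n)
        df[comp] = median * np.exp(loading * q + log_sd * s * eps)

    # empty-calorie share, logistic-normal around ~17%, lower for high quality
    eps = rng.standard_normal(n) if s > 0 else np.zeros(n)
    logit = np.log(0.17 / 0.83) - 0.5 * q + 0.45 * s * eps
    df["empty_calorie_pct"] = 100.0 / (1.0 + np.exp(-logit))
    return df


def _fsa_codes(n_fsa: int) -> list:
    codes = []
    for i in range(n_fsa):
        codes.append(f"{ascii_uppercase[i % 26]}{(i // 26) % 10}"
                     f"{ascii_uppercase[(i * 7) % 26]}")
    if len(set(codes)) != n_fsa:
        raise ValueError("n_fsa too large for the code generator")
    return codes


def simulate_retail_panel(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Weekly store x SKU marketing panel for the two food categories.

    Each FSA has a latent healthfulness factor that shifts vegetable
    marketing up and soft-drink marketing down (promotion and display
    probabilities, and relative prices), so the smoothed exposure ratios
    vary across FSAs the way an interaction analysis needs.
    """
    rng = np.random.default_rng(seed)
    fsas = _fsa_codes(config.n_fsa)
    h = rng.normal(0.0, 0.4, size=config.n_fsa)  # FSA healthfulness factor

    base = {
        "vegetables": {"promo": 0.15, "display": 0.25, "price": 3.0, "servings": 4},
        "soft_drinks": {"promo": 0.30, "display": 0.35, "price": 2.5, "servings": 6},
    }
    sgn = {"vegetables": 1.0, "soft_drinks": -1.0}

    rows = []
    for f_idx, fsa in enumerate(fsas):
        hf = h[f_idx]
        for quarter in config.quarters:
            for week in range(1, config.weeks_per_quarter + 1):
                for store in range(1, config.stores_per_fsa + 1):
                    for cat, n_sku in config.skus.items():
                        b = base[cat]
                        p_promo = _sigmoid(_logit(b["promo"]) + sgn[cat] * hf)
                        p_disp = _sigmoid(_logit(b["display"]) + sgn[cat] * hf)
                        price_mult = np.exp(-sgn[cat] * 0.25 * hf)
                        for sku in range(1, n_sku + 1):
                            price = b["price"] * price_mult * np.exp(
                                0.15 * rng.standard_normal())
                            rows.append((
                                fsa, quarter, week, f"{fsa}-st{store}", cat,
                                f"{cat[:3]}_{sku:02d}", round(price, 2),
                                b["servings"],
                                bool(rng.random() < p_promo),
                                bool(rng.random() < p_disp),
                                bool(rng.random() < 0.92),
                            ))
    return pd.DataFrame(rows, columns=retail_mod.PANEL_COLUMNS)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1 - p))


def simulate_census(fsas, tracts_per_fsa: int, seed: int) -> pd.DataFrame:
    """Census-tract covariate table; tracts nest within FSAs."""
    rng = np.random.default_rng(seed)
    rows = []
    for fsa in fsas:
        for t in range(1, tracts_per_fsa + 1):
            rows.append({
                "tract": f"{fsa}-t{t}",
                "fsa": fsa,
                "population_density": float(np.exp(rng.normal(7.0, 0.8))),
                "low_income_prevalence": float(rng.beta(3, 17)),
                "median_income": float(rng.normal(65000, 12000)),
                "pct_immigrant": float(100 * rng.beta(2, 12)),
                "employment_rate": float(100 * rng.beta(18, 6)),
                "pct_highschool": float(100 * rng.beta(16, 4)),
            })
    return pd.DataFrame(rows)


_SPECIAL_TERMS = ("intercept", "prs_z", "hei_z", "retail_z",
                  "prs_z:hei_z", "prs_z:retail_z", "sex_female", "age_c")


def simulate_outcomes(subjects: pd.DataFrame, prs_z, hei_z, retail_z,
                      effect_sizes: dict, noise_sd: dict, seed: int) -> pd.DataFrame:
    """Adiposity outcomes from the linear, additive structural model.

    outcome = intercept + sum(beta_i * term_i) + beta_int * prs_z*hei_z
    (+ the retail analogue) + Gaussian noise.  Unknown term names are
    rejected so silent typos cannot change the generating model.
    """
    rng = np.random.default_rng(seed)
    n = len(subjects)
    prs_z = np.asarray(prs_z, dtype=float)
    hei_z = np.asarray(hei_z, dtype=float)
    retail_z = np.asarray(retail_z, dtype=float)
    for arr, name in ((prs_z, "prs_z"), (hei_z, "hei_z"), (retail_z, "retail_z")):
        if not np.isfinite(arr).all():
            raise ValueError(f"{name} must be finite (standardize/complete first)")

    terms = {
        "intercept": np.ones(n),
        "prs_z": prs_z, "hei_z": hei_z, "retail_z": retail_z,
        "prs_z:hei_z": prs_z * hei_z, "prs_z:retail_z": prs_z * retail_z,
        "sex_female": (subjects["sex"].to_numpy() == "female").astype(float)
        if "sex" in subjects else np.zeros(n),
        "age_c": subjects["age"].to_numpy(dtype=float) - 55.0
        if "age" in subjects else np.zeros(n),
    }
    out = {}
    for outcome, betas in effect_sizes.items():
        y = np.zeros(n)
        for term, beta in betas.items():
            if term in terms:
                x = terms[term]
            elif term in subjects.columns and pd.api.types.is_numeric_dtype(subjects[term]):
                x = subjects[term].to_numpy(dtype=float)
            else:
                raise KeyError(
                    f"unknown term {term!r} in effect_sizes[{outcome!r}]; "
                    f"recognised: {_SPECIAL_TERMS} or numeric subject columns"
                )
            y = y + beta * x
        sd = float(noise_sd.get(outcome, 0.0))
        if sd > 0:
            y = y + sd * rng.standard_normal(n)
        out[outcome] = y
    return pd.DataFrame(out, index=subjects.index)


def _calibrate_intercept(lin: np.ndarray, rate: float) -> float:
    """Find alpha so that mean(sigmoid(alpha + lin)) == rate (bisection)."""
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _sigmoid(mid + lin).mean() < rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def apply_missingness(table: pd.DataFrame, missing_rates: dict,
                      mechanism: str = "MAR", seed: int = 0):
    """Mask cells missing-at-random (or completely at random).

    MCAR masks each cell independently with its variable's rate.  MAR masks
    with a logistic probability depending only on the fully observed
    variables sex, age and income (calibrated so the mean probability hits
    the requested rate), so missingness never depends on the masked values
    themselves.  Returns ``(masked_table, mask_log)``; the log records each
    masked cell with its variable and mechanism.
    """
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError("mechanism must be 'MCAR' or 'MAR'")
    for v, r in missing_rates.items():
        if not 0 <= r < 1:
            raise ValueError(f"missing rate for {v!r} must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = table.copy()
    log_rows = []
    n = len(table)
    if mechanism == "MAR":
        female = ((table["sex"] == "female").astype(float).to_numpy()
                  if "sex" in table else np.zeros(n))
        age = (table["age"].to_numpy(dtype=float) if "age" in table
               else np.full(n, 55.0))
        income = (pd.to_numeric(table["income"], errors="coerce")
                  .fillna(3).to_numpy(dtype=float) if "income" in table
                  else np.full(n, 3.0))
        lin = 0.4 * female + 0.04 * (age - 55.0) + 0.25 * (income - 3.0)
    for var, rate in missing_rates.items():
        if rate == 0 or var not in out.columns:
            continue
        if mechanism == "MCAR":
            mask = rng.random(n) < rate
        else:
            alpha = _calibrate_intercept(lin, rate)
            mask = rng.random(n) < _sigmoid(alpha + lin)
        out[var] = out[var].astype(float) if pd.api.types.is_numeric_dtype(out[var]) else out[var]
        out.loc[mask, var] = np.nan
        for idx in out.index[mask]:
            log_rows.append({"variable": var, "subject": idx, "mechanism": mechanism})
    log = pd.DataFrame(log_rows, columns=["variable", "subject", "mechanism"])
    return out, log


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete synthetic study (no missingness applied yet).

    The subjects table is the analysis spine: ids, geography, assessment
    quarter, covariates, true standardized exposures (``prs_z``, ``hei_z``,
    ``retail_z``) and the three adiposity outcomes, plus weight back-derived
    from generated BMI and height so BMR prediction has anthropometry.
    Call :func:`apply_missingness` afterwards to impose the observational
    missingness pattern.
    """
    (rng_geno, rng_diet, rng_assign, rng_retail,
     rng_census, rng_out, rng_miss, _spare) = _streams(config.seed)

    genotypes = simulate_genotypes(
        config.n_subjects, config.allele_freqs, rng_geno.integers(2**31))
    ids = genotypes.index
    diet = simulate_diet_and_covariates(ids, config, rng_diet.integers(2**31))

    fsas = _fsa_codes(config.n_fsa)
    weights = rng_assign.dirichlet(np.full(config.n_fsa, 5.0))
    fsa_assign = rng_assign.choice(fsas, size=config.n_subjects, p=weights)
    tract_assign = np.array([
        f"{f}-t{rng_assign.integers(1, config.tracts_per_fsa + 1)}"
        for f in fsa_assign
    ])
    quarter_assign = rng_assign.choice(np.asarray(config.quarters),
                                       size=config.n_subjects)

    panel = simulate_retail_panel(config, rng_retail.integers(2**31))
    census = simulate_census(fsas, config.tracts_per_fsa,
                             rng_census.integers(2**31))
    exposures = retail_mod.build_exposures(panel, decay=config.smoothing_decay)

    prs = genetics.compute_prs(genotypes)
    prs_z = genetics.standardize(prs)
    hei = score_hei_table(diet, diet["age"], diet["sex"])
    hei_z = genetics.standardize(hei["hei_total"])
    raw_retail = pd.Series(
        exposures.loc[fsa_assign, config.retail_exposure_indicator].to_numpy(),
        index=ids,
    )
    raw_retail = raw_retail.fillna(raw_retail.mean())  # degenerate price cells
    retail_z = genetics.standardize(raw_retail)

    subjects = diet.copy()
    subjects["fsa"] = fsa_assign
    subjects["tract"] = tract_assign
    subjects["quarter"] = quarter_assign
    subjects["prs"] = prs
    subjects["prs_z"] = prs_z
    subjects["hei_total"] = hei["hei_total"]
    subjects["hei_z"] = hei_z
    subjects["retail_z"] = retail_z.to_numpy()

    outcomes = simulate_outcomes(
        subjects, prs_z, hei_z, subjects["retail_z"],
        config.effect_sizes, config.noise_sd, rng_out.integers(2**31))
    for c in outcomes.columns:
        subjects[c] = outcomes[c]
    if "bmi" in subjects:
        subjects["weight"] = subjects["bmi"] * (subjects["height"] / 100.0) ** 2

    # postal-code nonresponse: geography withheld, subject retained
    n_missing_postal = int(round(config.postal_missing_rate * config.n_subjects))
    if n_missing_postal:
        drop = rng_miss.choice(config.n_subjects, size=n_missing_postal,
                               replace=False)
        subjects.iloc[drop, subjects.columns.get_loc("fsa")] = np.nan
        subjects.iloc[drop, subjects.columns.get_loc("tract")] = np.nan

    truth = _freeze({
        "effect_sizes": copy.deepcopy(config.effect_sizes),
        "noise_sd": dict(config.noise_sd),
        "missing_rates": dict(config.missing_rates),
        "seed": config.seed,
    })
    return SyntheticStudy(genotypes=genotypes, diet=diet, retail=panel,
                          census=census, subjects=subjects, truth=truth,
                          exposures=exposures)
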