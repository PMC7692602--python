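# Methods

This note documents the models, defaults and design choices behind
`gxecohort`, the assumptions they rest on, and what the synthetic tests do
and do not demonstrate about real cohort data.

## Polygenic risk score

The PRS is an additive allele count: `PRS_i = Σ_l w_l · d_il` over 97
biallelic loci with dosages `d ∈ [0, 2]`.  The default weights are all 1,
so the theoretical range is 0–194 — the score counts risk alleles.
GWAS-beta weighting is supported through the score-definition table but is
off by default.  The packaged 97-locus definition is a synthetic stand-in
with the correct cardinality; real analyses supply their own locus list as
CSV (`locus,effect_allele,weight`).

Missing dosages are replaced with `2p̂_l`, the expected dosage under
Hardy–Weinberg using the allele frequency estimated from non-missing
subjects, and affected subjects are flagged.  This keeps the score defined
for everyone at the cost of slightly shrinking those subjects toward the
mean; a locus that is missing in all subjects is an error.

Ancestry principal components come from the SVD of the column-centred
dosage matrix, ordered by explained variance, with the sign convention
that each component's largest-magnitude loading is positive (so results do
not depend on the LAPACK build).  Quintiles are cut at the empirical
20/40/60/80 percentiles; a value exactly at a boundary stays in the lower
quintile, which guarantees tied values share a quintile and the assignment
is monotone.  Standardization is `(x − x̄)/s` with the sample SD (ddof 1).
When analyses run on multiply-imputed data, standardization is recomputed
**within each completed dataset** — each fit is internally consistent; the
alternative (standardize once on the incomplete data) is a one-line change.

## HEI-C 2010 scoring

Eleven components: eight adequacy (score `max · min(1, intake/standard)`,
linear and saturating) and three moderation (full points at or below a
best threshold, zero at or above a worst threshold, linear between).
Component maxima (adequacy 60 / moderation 40):
fruit & vegetables 10, whole fruit 5, greens & beans 5, whole grains 10,
dairy 10, total protein 5, seafood & plant protein 5, fatty acids 10;
refined grains 10, sodium 10, empty calories 20.

Default standards sit at the midpoints of the recommended adult serving
ranges (fruit & vegetables 7.5/day, whole fruit 1.575, greens & beans
0.7875, whole grains 3.5, dairy 2.5, total protein 2.5, seafood & plant
protein 0.8); the fatty-acids standard is a (PUFA+MUFA)/SFA ratio of 2.5;
empty calories earn full points at ≤19% of energy.  Three decisions were
genuinely open and are encoded as configurable defaults:

- **Refined grains** are scored on the refined *share* of total grain
  servings: full points below a 50% share, zero at a 100% share, and full
  points when no grains are eaten at all (zero share).  Scoring the share
  rather than absolute servings keeps the component meaningful across
  energy intakes.
- **Sodium** uses the age-specific adequate intake (AI: 1500 mg/day for
  19–50, 1300 for 51–70, 1200 for 71+) as the best threshold and 2×AI as
  the worst; the doubling is a convention, not a guideline value.
- **Empty calories** hit zero at 50% of energy, the allocation used by the
  US HEI-2010.

Age bands are half-open (`[19,51)`, `[51,71)`, `[71,∞)`); both sexes share
the default standards but the table is keyed by (age group, sex) so
sex-specific recommendations drop in without code changes.

Adiposity categories use the conventional clinical boundaries: BMI
<18.5 / 18.5–24.9 / 25.0–29.9 / ≥30.0; waist risk strictly above
102 cm (males) / 88 cm (females); body-fat obesity strictly above
25% / 35%.

## Energy misreporting

Basal metabolic rate is predicted with the Mifflin–St Jeor equation
(kcal/day = 10·kg + 6.25·cm − 5·age + 5 for males, −161 for females); the
coefficients are a config entry, not hard-coded science.  The EI:BMR ratio
is classified with Goldberg-type limits `PAL · exp(±z·S/100)`,
`S = sqrt(CV_EI²/d + CV_BMR² + CV_PAL²)`, defaults PAL 1.55, CV_EI 23%,
CV_BMR 8.5%, CV_PAL 15%, d = 1 reporting day, z = 1.96, giving the
familiar adult band ≈ 0.88–2.72.  Boundary values are plausible;
non-positive intake is "under" by convention and logged.  Misreporter
status is an adjustment covariate, never an exclusion criterion.

## Retail exposures

For each (FSA, quarter, category) cell of the weekly panel:
variety = mean over store-weeks of distinct available SKUs; regular price
per serving = mean of price/servings over **non-promoted** observations
(a cell whose every observation is promoted has no regular price — it is
left missing for imputation rather than contaminated with sale prices);
discount frequency = promoted share of observations; display share =
on-display share of available SKUs averaged over store-weeks.

The vegetable:soft-drink ratio of each indicator is taken **per quarter**,
then the quarterly series is collapsed with exponential smoothing: quarter
`q` (position in the sorted label list) gets weight ∝ `(1−λ)^(latest−q)`
over non-missing quarters, normalized to sum 1.  Default decay λ = 0.3 per
quarter — a one-year half-life-ish memory; there is no canonical value, so
it is a config entry and recorded in provenance.  Ratio-then-smooth (not
smooth-then-ratio) keeps each quarter's healthfulness interpretable before
time averaging; the two orders genuinely differ and a regression test
pins the implemented one.  Interpretation: ratio > 1 is healthful for
variety/discount/display and unhealthful for price (dearer vegetables
relative to soft drinks).

## Linkage

Retail exposures join subjects by exact FSA key; census covariates
(population density, low-income prevalence, median income, % immigrant,
employment rate, % high-school completion) join by tract.  Both are left
joins: subjects without a postal code, with a malformed FSA, or in an FSA
the panel does not cover are retained with missing exposures and a logged
reason — they stay in the diet analysis and enter the retail analysis only
through imputation or exclusion, mirroring the diet-sample / retail-sample
split.  Season is proxied from the assessment quarter: Q4 and Q1 →
October–March, Q2 and Q3 → April–September.

## Imputation and pooling

Chained equations with `m` completed datasets (defaults: 20 for the diet
analysis, 50 for the retail analysis, reflecting their different
missingness burdens).  Each variable with missing values gets a
conditional model on all other spec variables plus auxiliaries: continuous
variables use a Bayesian linear regression posterior draw (σ² from its
scaled inverse-χ² posterior, β from N(β̂, σ²(XᵀX)⁻¹), then the predictive
normal); binaries use a logistic fit with an asymptotic-normal coefficient
draw and a Bernoulli draw.  Missing cells are initialized by bootstrap
draws from the observed margin; 10 chained iterations by default.  The
per-category retail measures (smoothed vegetable and soft-drink indicator
values) are included as auxiliary predictors in the retail imputation.
All randomness flows through seeded sub-streams, so runs are bit-for-bit
reproducible.

Interaction terms are computed **after** imputation within each completed
dataset (impute-then-transform).  A known consequence: main-effects-only
conditionals attenuate interaction estimates, noticeably so at small n.
The acceptance experiments therefore add the exposure-relevant product
(PRS × outcome, plus PRS²) as auxiliary predictors — the standard
interaction-aware imputation remedy — after which the residual
finite-sample attenuation at n ≈ 6000 is ~0.02 on a coefficient of 0.5,
well inside Monte-Carlo error.  Real analyses with interaction targets
should do the same.

Pooling follows Rubin's rules: `Q̄ = mean(Q_j)`, `W̄ = mean(U_j)`,
`B = var(Q_j)`, `T = W̄ + (1 + 1/m)B`, with Barnard–Rubin small-sample
degrees of freedom `ν = (1/ν_old + 1/ν_obs)⁻¹`,
`ν_old = (m−1)/λ²`, `ν_obs = (ν_com+1)/(ν_com+3)·ν_com·(1−λ)`,
`λ = (1+1/m)B/T`.  With `B = 0` (or m = 1) the complete-data degrees of
freedom apply.  Intervals and p-values are t-based, two-sided, α = 0.05,
with no multiple-testing correction (none is part of the analysis design).

## Regression models

All continuous outcomes use a Gaussian identity link, so estimates are in
outcome units (cm, kg/m², percentage points).  Diet-sample models are
ordinary GLMs; retail-sample models are GEE with an **exchangeable**
working correlation, clustered by FSA, with robust sandwich variances —
areal clustering has no natural ordering, so exchangeable is the
defensible default, and the sandwich variance protects against its
misspecification.  With singleton clusters GEE reproduces the GLM
coefficients, a property the tests pin.

Designs are built from patsy formulas.  Exposures enter standardized; the
interaction is their product.  Quintile mode replaces the continuous PRS
with indicator coding, quintile 1 reference, keeping Qk × exposure
products alongside the main effects.  Categorical covariates enter as
indicator sets with the first observed level as reference (this affects
intercepts only).  Rank deficiency is detected by pivoted QR before
fitting and reported with the aliased column names.  The sensitivity
variant drops total energy from the adjustment set, addressing the concern
that energy lies on the causal path from PRS to adiposity.  Trend tests
regress the outcome on the integer-coded group index with a small
adjustment set (sex, age, energy, reporter status); least-squares means
are model predictions averaged over the observed covariate mix.

Interaction plot grids evaluate pooled quintile models at covariate means
over a standardized-HEI grid for quintiles 1 and 5, and carry the clinical
reference cutoff for the outcome (BMI 30; waist 102/88; body fat 25/35) so
plots can draw the threshold line.

## Synthetic data generator

The generator defines the study conditions and exists as first-class,
tested code.  Genotypes are binomial(2, p) per locus in Hardy–Weinberg
proportions with no LD — the score is additive, so LD structure would not
change any downstream mathematics.  Allele frequencies default to
Uniform(0.05, 0.95) draws fixed by the seed.

Covariates and intakes: sex (54.3% female), age N(55, 8) clipped to 40–70,
height by sex, five income levels, three education levels, four smoking
levels, three marital levels, language (95% French), physical activity
N(1.48, 0.36).  Energy intake is gamma with mean 1716 and SD 961 kcal/day
(positive support, exact configured moments).  A latent diet-quality
factor q ~ N(0,1) loads log-normally on every food-group intake (positive
support, correlated components; medians near 0.4–6.8 servings/day by
component); the empty-calorie share is logistic-normal around ~17% so it
stays inside (0, 100).  Setting `covariate_noise_scale = 0` collapses the
cohort to identical subjects, which several tests exploit.

The retail panel gives each FSA a latent healthfulness factor that shifts
vegetable marketing up and soft-drink marketing down (promotion and
display probabilities on the logit scale, prices log-scale), creating the
between-FSA exposure variance an interaction analysis needs.  Default
panel geometry: 8 quarters × 4 weeks × 2 stores × (6 vegetable + 5
soft-drink SKUs) per FSA.

Outcomes follow the linear structural model
`Y = β₀ + β_G·PRS_z + β_E·HEI_z + β_GE·PRS_z·HEI_z + β_R·retail_z +
β_GR·PRS_z·retail_z + γ_sex·female + γ_age·(age−55) + ε`,
with default coefficients echoing the magnitudes a study of this kind
reports (waist: 1.3 / −1.6 / −0.5; BMI: 0.6 / −0.5 / −0.1; body fat:
0.6 / −0.7 / −0.2; noise SDs 11 / 4.8 / 6.5) and intercepts at typical
adult anthropometry.  The PRS_z and HEI_z entering the generator are the
**actual scored values** from the simulated genotypes and diet, so the
whole scoring chain sits inside the generative loop.  Weight is
back-derived from generated BMI and height so BMR prediction has
anthropometry.  The generating coefficients are frozen into an immutable
truth ledger.

Missingness is MCAR or MAR; MAR masks with a logistic probability in sex,
age and income only (fully observed variables), with the intercept
calibrated by bisection so the realized mean probability matches the
requested rate.  Mask positions are logged.  About 23% of subjects
withhold their postal code (losing geography), and the pipeline's observed
panel covers ~80% of FSAs, reproducing the diet-sample / retail-sample
size split and the high exposure missingness of the motivating design.

**What the generator does not emulate:** linkage disequilibrium and
ancestry structure (the PCs of simulated genotypes carry no signal),
FFQ item-level measurement error, store-type heterogeneity, spatially
correlated residuals beyond the FSA factor, and MNAR missingness.
Passing tests therefore demonstrate the *mathematics* of the chain —
scoring rules, linkage contracts, imputation validity under MAR, estimator
calibration — not robustness to those real-data complications.

## Numerical choices and degenerate inputs

- Quintile ties go to the lower group; constant vectors cannot be
  standardized or quintiled (errors, not NaNs).
- PCA on a constant matrix, GEE with one cluster, empty quintiles,
  inverted moderation thresholds, missing anthropometry at BMR time, and
  100%-missing imputation targets are all rejected with named errors.
- The chained-equations linear solver adds a 1e−8 ridge to XᵀX and draws
  coefficients via SVD, so near-collinear auxiliary sets degrade
  gracefully instead of failing; a separated logistic conditional falls
  back to the marginal rate.
- Exponential smoothing skips missing quarters and renormalizes; an
  all-missing series yields a missing exposure, never zero.
- Report CSVs are written with `%.10g` so determinism checks compare
  bytes.

## Problem sizes in the test suite

Unit tests run at n of tens to a few thousand.  The acceptance experiments
use: interaction recovery at n = 6087 subjects per replicate, 100
replicates, m = 5 imputations (reduced from 20 — m trades pooling
precision, not bias); type-I error at n = 2000 with 1000 replicates;
pipeline determinism at n = 250 with m = 2.  The full suite completes in
roughly two minutes on one CPU.

## Known limitations

- The GEE degrees of freedom used for pooling are the large-sample
  `n − p`; with few clusters, robust-variance small-sample corrections
  (e.g. bias-reduced linearization) would be preferable and are not
  implemented.
- The misreporter category is classified on observed energy only; if
  energy itself is imputed, classification should be repeated per
  completed dataset (the pipeline's default config keeps energy complete).
- Passive/“just-another-variable” imputation of interaction terms is not
  implemented; interaction-aware auxiliaries are the supported route.
- The HEI-C standards table ships research-grade defaults, not an official
  guideline extract; real analyses should load their own table.
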