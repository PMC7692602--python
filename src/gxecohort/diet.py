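"""Canadian Healthy Eating Index 2010 (HEI-C) scoring and adiposity categories.

The HEI-C summarises diet quality against 2007 Canada's Food Guide
recommendations with 11 components: eight *adequacy* components (more is
better, score rises linearly from 0 at zero intake to the component maximum
at the age/sex standard and saturates there) and three *moderation*
components (less is better, full points at or below a best-score threshold,
zero at or above a worst threshold, linear in between).  Adequacy maxima
sum to 60, moderation maxima to 40, so the total spans 0-100.

Component allocation (adequacy 60 / moderation 40):

====================  ====  ==========================================
component             max   standard for full points (default adults)
====================  ====  ==========================================
fruit_and_vegetables   10   7.5 servings/day
whole_fruit             5   1.575 servings/day
greens_and_beans        5   0.7875 servings/day
whole_grains           10   3.5 servings/day
dairy                  10   2.5 servings/day
total_protein           5   2.5 servings/day
seafood_plant_protein   5   0.8 servings/day
fatty_acids            10   (PUFA+MUFA)/SFA ratio >= 2.5
refined_grains         10   < 50% of total grain servings refined
sodium                 10   <= age/sex adequate intake (AI), zero at 2x AI
empty_calories         20   <= 19% of energy, zero at 50% of energy
====================  ====  ==========================================

Standards are shipped as an editable table keyed by (age group, sex) so the
defaults above can be replaced with cohort-specific recommendations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ADEQUACY_COMPONENTS = (
    "fruit_and_vegetables",
    "whole_fruit",
    "greens_and_beans",
    "whole_grains",
    "dairy",
    "total_protein",
    "seafood_plant_protein",
    "fatty_acids",
)
MODERATION_COMPONENTS = ("refined_grains", "sodium", "empty_calories")

MAX_POINTS = {
    "fruit_and_vegetables": 10.0,
    "whole_fruit": 5.0,
    "greens_and_beans": 5.0,
    "whole_grains": 10.0,
    "dairy": 10.0,
    "total_protein": 5.0,
    "seafood_plant_protein": 5.0,
    "fatty_acids": 10.0,
    "refined_grains": 10.0,
    "sodium": 10.0,
    "empty_calories": 20.0,
}

# adequate intake for sodium, mg/day, by adult age band (sexes share the AI)
SODIUM_AI = {"19-50": 1500.0, "51-70": 1300.0, "71+": 1200.0}


@dataclass(frozen=True)
class DietRecord:
    """One subject's daily intake summary feeding the HEI-C scorer.

    Serving counts are Canada's Food Guide 2007 servings per day;
    ``fatty_acid_ratio`` is the unitless (PUFA+MUFA)/SFA ratio; ``sodium``
    is mg/day; ``empty_calorie_pct`` the percent of total energy from empty
    calories; energies are kcal/day.
    """

    fruit_and_vegetables: float
    whole_fruit: float
    greens_and_beans: float
    whole_grains: float
    dairy: float
    total_protein: float
    seafood_plant_protein: float
    refined_grains: float
    fatty_acid_ratio: float
    sodium: float
    empty_calorie_pct: float
    total_energy: float
    alcohol_energy: float = 0.0

    def __post_init__(self):
        for name in (
            "fruit_and_vegetables", "whole_fruit", "greens_and_beans",
            "whole_grains", "dairy", "total_protein", "seafood_plant_protein",
            "refined_grains", "fatty_acid_ratio", "sodium", "alcohol_energy",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.empty_calorie_pct <= 100:
            raise ValueError("empty_calorie_pct must lie in [0, 100]")
        if self.total_energy <= 0:
            raise ValueError("total_energy must be positive")


@dataclass
class ComponentStandard:
    """Scoring parameters for one component within one age/sex group."""

    standard: float          # intake earning full points (adequacy) / best threshold (moderation)
    max_points: float
    worst: float | None = None   # moderation only: intake earning zero points


@dataclass
class ScoringStandards:
    """Full standards table: (age_group, sex) -> component -> parameters."""

    table: dict = field(default_factory=dict)
    # half-open [lo, hi) age bands, contiguous over the adult range
    age_breaks: tuple = ((19, 51, "19-50"), (51, 71, "51-70"), (71, 200, "71+"))

    def resolve(self, age: float, sex: str) -> dict:
        sex = _norm_sex(sex)
        group = None
        for lo, hi, label in self.age_breaks:
            if lo <= age < hi:
                group = label
                break
        if group is None or (group, sex) not in self.table:
            raise KeyError(f"no scoring standards for age={age}, sex={sex!r}")
        return self.table[(group, sex)]


def default_standards() -> ScoringStandards:
    """Default adult standards at the midpoints of the recommended ranges."""
    base = {
        "fruit_and_vegetables": ComponentStandard(7.5, 10.0),
        "whole_fruit": ComponentStandard(1.575, 5.0),
        "greens_and_beans": ComponentStandard(0.7875, 5.0),
        "whole_grains": ComponentStandard(3.5, 10.0),
        "dairy": ComponentStandard(2.5, 10.0),
        "total_protein": ComponentStandard(2.5, 5.0),
        "seafood_plant_protein": ComponentStandard(0.8, 5.0),
        "fatty_acids": ComponentStandard(2.5, 10.0),
        # refined grains scored on the refined share of total grains
        "refined_grains": ComponentStandard(0.5, 10.0, worst=1.0),
        "empty_calories": ComponentStandard(19.0, 20.0, worst=50.0),
    }
    table = {}
    for group, ai in SODIUM_AI.items():
        for sex in ("male", "female"):
            comps = dict(base)
            comps["sodium"] = ComponentStandard(ai, 10.0, worst=2 * ai)
            table[(group, sex)] = comps
    return ScoringStandards(table=table)


def score_adequacy_component(intake: float, standard: float, max_points: float) -> float:
    """Linear, saturating: ``max_points * min(1, intake / standard)``."""
    if intake < 0:
        raise ValueError("adequacy intake must be nonnegative")
    if standard <= 0:
        raise ValueError("adequacy standard must be positive")
    return max_points * min(1.0, intake / standard)


def score_moderation_component(
    intake: float, best_threshold: float, worst_threshold: float, max_points: float
) -> float:
    """Full points at or below best, zero at or above worst, linear between."""
    if best_threshold >= worst_threshold:
        raise ValueError("best_threshold must be below worst_threshold")
    if intake <= best_threshold:
        return max_points
    if intake >= worst_threshold:
        return 0.0
    frac = (worst_threshold - intake) / (worst_threshold - best_threshold)
    return max_points * frac


@dataclass(frozen=True)
class HEIResult:
    components: dict
    adequacy: float
    moderation: float
    total: float


def score_hei(
    record: DietRecord,
    age: float,
    sex: str,
    standards: ScoringStandards | None = None,
) -> HEIResult:
    """Score all 11 HEI-C components for one subject.

    Refined grains are scored on the refined *share* of total grain servings
    (full points below a 50% share, zero at 100%); a subject eating no
    grains at all has a zero refined share and earns full points.
    """
    if standards is None:
        standards = default_standards()
    std = standards.resolve(age, sex)

    components: dict[str, float] = {}
    for name in ADEQUACY_COMPONENTS:
        cs = std[name]
        intake = record.fatty_acid_ratio if name == "fatty_acids" else getattr(record, name)
        components[name] = score_adequacy_component(intake, cs.standard, cs.max_points)

    total_grains = record.whole_grains + record.refined_grains
    refined_share = 0.0 if total_grains == 0 else record.refined_grains / total_grains
    cs = std["refined_grains"]
    components["refined_grains"] = score_moderation_component(
        refined_share, cs.standard, cs.worst, cs.max_points
    )
    cs = std["sodium"]
    components["sodium"] = score_moderation_component(
        record.sodium, cs.standard, cs.worst, cs.max_points
    )
    cs = std["empty_calories"]
    components["empty_calories"] = score_moderation_component(
        record.empty_calorie_pct, cs.standard, cs.worst, cs.max_points
    )

    adequacy = sum(components[c] for c in ADEQUACY_COMPONENTS)
    moderation = sum(components[c] for c in MODERATION_COMPONENTS)
    return HEIResult(components, adequacy, moderation, adequacy + moderation)


def score_hei_table(
    diet: pd.DataFrame,
    age: pd.Series,
    sex: pd.Series,
    standards: ScoringStandards | None = None,
) -> pd.DataFrame:
    """Vectorised convenience wrapper: one HEI-C result row per subject."""
    rows = []
    fields = [
        "fruit_and_vegetables", "whole_fruit", "greens_and_beans", "whole_grains",
        "dairy", "total_protein", "seafood_plant_protein", "refined_grains",
        "fatty_acid_ratio", "sodium", "empty_calorie_pct", "total_energy",
        "alcohol_energy",
    ]
    aliases = {"total_energy": "energy", "alcohol_energy": "alcohol"}
    for idx, row in diet.iterrows():
        vals = {}
        for f in fields:
            v = row.get(f, row.get(aliases.get(f), 0.0))
            vals[f] = 0.0 if pd.isna(v) else float(v)
        if vals["total_energy"] <= 0:  # energy itself is not scored
            vals["total_energy"] = 1.0
        rec = DietRecord(**vals)
        res = score_hei(rec, float(age.loc[idx]), str(sex.loc[idx]), standards)
        out = dict(res.components)
        out["hei_adequacy"] = res.adequacy
        out["hei_moderation"] = res.moderation
        out["hei_total"] = res.total
        rows.append(out)
    return pd.DataFrame(rows, index=diet.index)


BMI_CATEGORIES = ("underweight", "healthy weight", "overweight", "obese")


def _norm_sex(sex: str) -> str:
    s = str(sex).strip().lower()
    if s in ("m", "male", "1"):
        return "male"
    if s in ("f", "female", "0", "2"):
        return "female"
    raise ValueError(f"unknown sex code: {sex!r}")


def classify_adiposity(bmi: float, waist: float, bodyfat_pct: float, sex: str) -> dict:
    """Adiposity categories from BMI, waist circumference and % body fat.

    BMI bands: underweight <18.5, healthy 18.5-24.9, overweight 25.0-29.9,
    obese >=30.0.  Waist circumference is flagged as elevated risk strictly
    above 102 cm (males) / 88 cm (females); % body fat marks obesity
    strictly above 25% (males) / 35% (females).
    """
    if min(bmi, waist, bodyfat_pct) <= 0:
        raise ValueError("measurements must be positive")
    s = _norm_sex(sex)
    if bmi < 18.5:
        cat = "underweight"
    elif bmi < 25.0:
        cat = "healthy weight"
    elif bmi < 30.0:
        cat = "overweight"
    else:
        cat = "obese"
    waist_cut = 102.0 if s == "male" else 88.0
    fat_cut = 25.0 if s == "male" else 35.0
    return {
        "bmi_category": cat,
        "waist_elevated": waist > waist_cut,
        "bodyfat_obese": bodyfat_pct > fat_cut,
    }


def classify_adiposity_table(df: pd.DataFrame) -> pd.DataFrame:
    """Row-wise adiposity classification for a cohort table.

    Expects columns ``bmi``, ``waist``, ``bodyfat_pct``, ``sex``; rows with
    any missing measurement get missing categories.
    """
    out = []
    for _, row in df.iterrows():
        vals = (row["bmi"], row["waist"], row["bodyfat_pct"])
        if any(pd.isna(v) for v in vals) or pd.isna(row["sex"]):
            out.append({"bmi_category": pd.NA, "waist_elevated": pd.NA, "bodyfat_obese": pd.NA})
        else:
            out.append(classify_adiposity(*[float(v) for v in vals], row["sex"]))
    return pd.DataFrame(out, index=df.index)
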