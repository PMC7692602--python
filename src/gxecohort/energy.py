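"""Energy-intake misreporting classification.

Self-reported energy intake (EI) is compared with predicted basal metabolic
rate (BMR): subjects whose EI:BMR ratio falls below a plausibility band are
under-reporters, above it over-reporters, and inside it plausible
reporters.  The band is a Goldberg-type confidence interval around an
assumed physical activity level (PAL), with width driven by the day-to-day
CV of intake reporting, the CV of the BMR prediction, and between-subject
variation in PAL.  Misreporter status is used downstream as a covariate
(never an exclusion) because heavier subjects tend to under-report intake.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

# Mifflin-St Jeor coefficients: kcal/day = 10*kg + 6.25*cm - 5*age + offset
BMR_COEFFS = {"weight": 10.0, "height": 6.25, "age": -5.0,
              "offset_male": 5.0, "offset_female": -161.0}

CATEGORIES = ("under", "plausible", "over")


def predict_bmr(sex: str, age: float, weight_kg: float, height_cm: float,
                coeffs: dict | None = None) -> float:
    """Predicted basal metabolic rate (kcal/day) from a sex-specific linear
    equation in weight, height and age (Mifflin-St Jeor by default)."""
    import pandas as pd

    if any(pd.isna(v) for v in (age, weight_kg, height_cm)) or pd.isna(sex):
        raise ValueError("missing anthropometry; classify after imputation")
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    c = BMR_COEFFS if coeffs is None else coeffs
    from .diet import _norm_sex

    offset = c["offset_male"] if _norm_sex(sex) == "male" else c["offset_female"]
    bmr = c["weight"] * weight_kg + c["height"] * height_cm + c["age"] * age + offset
    return max(bmr, 1.0)


@dataclass(frozen=True)
class ReporterCutoffs:
    """EI:BMR plausibility band; ``lower < upper``."""

    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("cutoffs must satisfy lower < upper")


def goldberg_cutoffs(pal: float = 1.55, cv_ei: float = 23.0, cv_bmr: float = 8.5,
                     cv_pal: float = 15.0, n_days: float = 1.0,
                     z: float = 1.96) -> ReporterCutoffs:
    """Goldberg-type confidence limits on the EI:BMR ratio.

    ``pal * exp(+-z * S / 100)`` with ``S = sqrt(cv_ei^2/n_days + cv_bmr^2 +
    cv_pal^2)``.  The defaults (PAL 1.55, CVs 23/8.5/15 %, one reporting
    day) give the familiar adult band of roughly 0.88-2.72.
    """
    s = math.sqrt(cv_ei**2 / n_days + cv_bmr**2 + cv_pal**2) / 100.0
    return ReporterCutoffs(pal * math.exp(-z * s), pal * math.exp(z * s))


def classify_reporter(energy_intake: float, bmr: float,
                      cutoffs: ReporterCutoffs | None = None) -> str:
    """Classify one subject as ``under`` / ``plausible`` / ``over``.

    Boundary values are inclusive to ``plausible``.  Non-positive intake is
    classified ``under`` by convention (the ratio is degenerate, not the
    classification).
    """
    if bmr <= 0:
        raise ValueError("bmr must be positive")
    if cutoffs is None:
        cutoffs = goldberg_cutoffs()
    if energy_intake <= 0:
        return "under"
    ratio = energy_intake / bmr
    if ratio < cutoffs.lower:
        return "under"
    if ratio > cutoffs.upper:
        return "over"
    return "plausible"
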