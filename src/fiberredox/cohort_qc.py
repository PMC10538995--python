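"""Cohort screening computations: dietary plausibility and HOMA-IR.

Dietary records are screened with Goldberg cutoffs on the ratio of reported
energy intake to basal metabolic rate (EI:BMR), using the Black adjustment
that widens or narrows the plausible interval with the cohort's reporting
variability. The BMR itself is an input (measured or estimated from a
user-configured regression on age, sex, fat mass and fat-free mass); no BMR
equation is hard-coded here.
"""

from __future__ import annotations

import math

__all__ = [
    "classify_plausibility",
    "goldberg_cutoffs",
    "homa_ir",
    "INDIVIDUAL_CUTOFFS",
    "COHORT_CUTOFFS",
]

#: Default plausibility bounds on EI:BMR for individual-level screening.
INDIVIDUAL_CUTOFFS = (0.76, 2.41)
#: Default plausibility bounds on EI:BMR for cohort-level screening.
COHORT_CUTOFFS = (1.18, 1.55)


def classify_plausibility(
    ei_bmr: float,
    lower: float = INDIVIDUAL_CUTOFFS[0],
    upper: float = INDIVIDUAL_CUTOFFS[1],
) -> str:
    """Classify an EI:BMR ratio as 'under', 'plausible' or 'over'.

    Bounds are inclusive: a ratio exactly at a cutoff is plausible.
    """
    if not lower < upper:
        raise ValueError("lower cutoff must be below upper cutoff")
    if ei_bmr < lower:
        return "under"
    if ei_bmr > upper:
        return "over"
    return "plausible"


def goldberg_cutoffs(
    n: int,
    d: float,
    cv_ei: float,
    cv_bmr: float,
    cv_pal: float,
    pal: float,
    sd_limit: float = 2.0,
) -> tuple[float, float]:
    """Black-adjusted Goldberg confidence limits on EI:BMR.

    With S = sqrt(cv_ei^2 / d + cv_bmr^2 + cv_pal^2) (all CVs in percent, d =
    days of recording), the bounds are pal * exp(-+ sd_limit * S/100 / sqrt(n)).
    The interval collapses to ``pal`` when every CV is zero, narrows as n or d
    grows, and is reciprocal-symmetric about pal on the log scale
    (lower * upper = pal^2).
    """
    if pal <= 0:
        raise ValueError("pal must be > 0")
    if n < 1 or d < 1:
        raise ValueError("need n >= 1 subjects and d >= 1 days")
    if min(cv_ei, cv_bmr, cv_pal) < 0:
        raise ValueError("CVs must be >= 0")
    s = math.sqrt(cv_ei**2 / d + cv_bmr**2 + cv_pal**2)
    half_width = sd_limit * s / 100.0 / math.sqrt(n)
    return pal * math.exp(-half_width), pal * math.exp(half_width)


def homa_ir(glucose_mg_dl: float, insulin_mu_l: float) -> float:
    """Homeostatic model assessment of insulin resistance.

    Mass-unit convention: fasting glucose (mg/dL) x fasting insulin (mU/L)
    / 405, numerically equivalent to the molar form glucose (mmol/L) x
    insulin / 22.5.
    """
    if glucose_mg_dl <= 0 or insulin_mu_l <= 0:
        raise ValueError("glucose and insulin must be > 0")
    return glucose_mg_dl * insulin_mu_l / 405.0
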