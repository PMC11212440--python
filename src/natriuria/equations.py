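"""Prediction equations for 24h urinary sodium excretion from spot urine.

Three published estimators are implemented exactly as printed in their
source publications: the Kawasaki equation (second-morning-void spot urine,
sex-specific body-size term, square-root form), the Tanaka equation (single
form for men and women, 0.392-power form) and the INTERSALT equation
(sex-specific linear predictor, quadratic in age for women).  Kawasaki and
Tanaka predict from the spot Na/creatinine ratio scaled by an estimate of
daily creatinine excretion; INTERSALT is a direct linear model on spot
concentrations, BMI and age.

All estimators return milligrams of sodium per day together with the
mmol/d equivalent using the conventional molar factor 23 mg/mmol that the
printed equations embed (not the exact atomic mass); the sodium-to-salt
conversion, by contrast, uses exact molar masses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

__all__ = [
    "Anthropometry",
    "SpotSample",
    "SodiumEstimate",
    "estimate_kawasaki",
    "estimate_tanaka",
    "estimate_intersalt",
    "na_to_salt",
    "convert_creatinine",
    "NA_MG_PER_MMOL",
    "SALT_PER_SODIUM",
]

Sex = Literal["male", "female"]
Timing = Literal["AM", "PM", "AVG"]

#: Molar factor embedded in the printed equations (mg sodium per mmol).
NA_MG_PER_MMOL = 23.0

_NACL_MOLAR_MASS = 58.443  # g/mol
_NA_MOLAR_MASS = 22.98977  # g/mol
_CREA_MOLAR_MASS = 113.12  # g/mol

#: Grams of NaCl per gram of sodium (≈ 2.54 at 3 significant figures).
SALT_PER_SODIUM = _NACL_MOLAR_MASS / _NA_MOLAR_MASS


class IneligibleTimingError(ValueError):
    """Raised when a spot sample's timing is not valid for an equation."""


@dataclass(frozen=True)
class Anthropometry:
    """Demographic and body-size predictors shared by all three equations.

    Parameters
    ----------
    sex : {"male", "female"}
    age : float
        Age in years; must be positive.
    weight : float
        Body weight in kg.
    height : float
        Body height in cm.
    bmi : float, optional
        Body mass index in kg/m².  When omitted it is derived from weight
        and height; when supplied it takes precedence (the INTERSALT
        equation consumes BMI directly).
    """

    sex: Sex
    age: float
    weight: float
    height: float
    bmi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.age > 0:
            raise ValueError("age must be positive")
        if not self.weight > 0:
            raise ValueError("weight must be positive")
        if not self.height > 0:
            raise ValueError("height must be positive")

    @property
    def bmi_value(self) -> float:
        """BMI in kg/m²: supplied value if given, else weight/(height/100)²."""
        if self.bmi is not None:
            return self.bmi
        return self.weight / (self.height / 100.0) ** 2


@dataclass(frozen=True)
class SpotSample:
    """A single timed spot-urine specimen.

    Attributes
    ----------
    timing : {"AM", "PM", "AVG"}
        AM = second morning void, PM = pre-dinner void, AVG = the
        component-wise mean of an AM/PM pair.
    una : float
        Sodium concentration, mmol/l.
    ucrea_mg_dl : float
        Creatinine concentration, mg/dl.
    uk : float, optional
        Potassium concentration, mmol/l (required only by INTERSALT).
    """

    timing: Timing
    una: float
    ucrea_mg_dl: float
    uk: Optional[float] = None

    def __post_init__(self) -> None:
        if self.timing not in ("AM", "PM", "AVG"):
            raise ValueError(f"timing must be AM, PM or AVG, got {self.timing!r}")
        if self.una < 0:
            raise ValueError("urinary sodium concentration must be >= 0")
        if not self.ucrea_mg_dl > 0:
            raise ValueError("urinary creatinine concentration must be > 0")
        if self.uk is not None and self.uk < 0:
            raise ValueError("urinary potassium concentration must be >= 0")


@dataclass(frozen=True)
class SodiumEstimate:
    """A formula's predicted 24h sodium excretion with provenance."""

    na_mg_per_day: float
    formula_id: Literal["kawasaki", "tanaka", "intersalt"]
    timing: Timing
    flags: frozenset = field(default_factory=frozenset)

    @property
    def na_mmol_per_day(self) -> float:
        return self.na_mg_per_day / NA_MG_PER_MMOL

    @property
    def na_g_per_day(self) -> float:
        return self.na_mg_per_day / 1000.0

    @property
    def salt_g_per_day(self) -> float:
        """Equivalent NaCl intake, g/d (undefined for negative estimates)."""
        return na_to_salt(max(self.na_g_per_day, 0.0))


def _na_crea_ratio(spot: SpotSample) -> float:
    # The printed "×10" converts creatinine mg/dl to mg/l; kept literal so
    # the code reads like the published equation.
    return spot.una / (spot.ucrea_mg_dl * 10.0)


def estimate_kawasaki(
    spot: SpotSample, anthro: Anthropometry, *, allow_pm: bool = False
) -> SodiumEstimate:
    """Kawasaki estimate of 24h sodium excretion (mg/d) from a morning spot.

    e24hUNa = 23 × 16.3 × sqrt( (SpotUNa / (SpotUCrea[mg/dl] × 10)) × B )
    with the sex-specific body-size term

    B(men)   = 15.12·weight + 7.39·height − 12.63·age − 79.9
    B(women) =  8.58·weight + 5.09·height −  4.72·age − 74.5

    The equation was designed for second-morning-void samples; PM samples
    are rejected unless ``allow_pm=True``, in which case the returned
    estimate carries the ``ineligible_timing`` flag.
    """
    flags = set()
    if spot.timing != "AM":
        if not allow_pm:
            raise IneligibleTimingError(
                "the Kawasaki equation applies to AM (second morning void) "
                "spot urine only; pass allow_pm=True for exploratory use"
            )
        flags.add("ineligible_timing")
    a = anthro
    if a.sex == "male":
        body = 15.12 * a.weight + 7.39 * a.height - 12.63 * a.age - 79.9
    else:
        body = 8.58 * a.weight + 5.09 * a.height - 4.72 * a.age - 74.5
    if body <= 0:
        raise ValueError("Kawasaki body-size term must be positive")
    mg = NA_MG_PER_MMOL * 16.3 * math.sqrt(_na_crea_ratio(spot) * body)
    return SodiumEstimate(mg, "kawasaki", spot.timing, frozenset(flags))


def estimate_tanaka(spot: SpotSample, anthro: Anthropometry) -> SodiumEstimate:
    """Tanaka estimate of 24h sodium excretion (mg/d), men and women alike.

    e24hUNa = 23 × 21.98 × [ (SpotUNa / (SpotUCrea[mg/dl] × 10)) × B ]^0.392
    with B = −2.04·age + 14.89·weight + 16.14·height − 2244.45.

    Applicable to both AM and PM samples.
    """
    a = anthro
    body = -2.04 * a.age + 14.89 * a.weight + 16.14 * a.height - 2244.45
    if body <= 0:
        raise ValueError("Tanaka body-size term must be positive")
    mg = NA_MG_PER_MMOL * 21.98 * (_na_crea_ratio(spot) * body) ** 0.392
    return SodiumEstimate(mg, "tanaka", spot.timing)


def estimate_intersalt(spot: SpotSample, anthro: Anthropometry) -> SodiumEstimate:
    """INTERSALT estimate of 24h sodium excretion (mg/d).

    Sex-specific linear predictor in mmol/d, converted to mg/d with the
    printed ×23 factor.  Creatinine enters in mmol/l; potassium and BMI are
    required.  Men:

        25.46 + 0.46·UNa − 2.75·UCrea − 0.13·UK + 4.10·BMI + 0.26·age

    Women (quadratic in age):

        5.07 + 0.34·UNa − 2.16·UCrea − 0.09·UK + 2.39·BMI + 2.35·age
             − 0.03·age²

    Negative predictions are possible for dilute urine in small, young
    subjects; they are returned flagged ``negative_estimate`` rather than
    clamped, so agreement analyses see the raw model output.
    """
    if spot.uk is None:
        raise ValueError("the INTERSALT equation requires spot potassium (uk)")
    ucrea_mmol_l = convert_creatinine(spot.ucrea_mg_dl, "mg/dl", "mmol/l")
    a = anthro
    bmi = a.bmi_value
    if a.sex == "male":
        mmol = (
            25.46
            + 0.46 * spot.una
            - 2.75 * ucrea_mmol_l
            - 0.13 * spot.uk
            + 4.10 * bmi
            + 0.26 * a.age
        )
    else:
        mmol = (
            5.07
            + 0.34 * spot.una
            - 2.16 * ucrea_mmol_l
            - 0.09 * spot.uk
            + 2.39 * bmi
            + 2.35 * a.age
            - 0.03 * a.age**2
        )
    flags = frozenset({"negative_estimate"}) if mmol < 0 else frozenset()
    return SodiumEstimate(NA_MG_PER_MMOL * mmol, "intersalt", spot.timing, flags)


def na_to_salt(na_g: float) -> float:
    """Convert grams of sodium to grams of salt (NaCl) via exact molar masses.

    1 g Na corresponds to 58.443/22.98977 ≈ 2.54 g NaCl, the factor behind
    the guideline correspondence 2 g/d sodium ↔ 5 g/d salt.
    """
    if na_g < 0:
        raise ValueError("sodium mass must be >= 0")
    return na_g * SALT_PER_SODIUM


def convert_creatinine(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a creatinine concentration between mg/dl and mmol/l.

    Uses the creatinine molar mass 113.12 g/mol, i.e. mg/dl × 0.0884 ≈
    mmol/l.  The round trip is exact.
    """
    units = {"mg/dl", "mmol/l"}
    if from_unit not in units or to_unit not in units:
        raise ValueError(f"units must be one of {sorted(units)}")
    if from_unit == to_unit:
        return value
    if from_unit == "mg/dl":  # mg/dl -> mg/l -> mmol/l
        return value * 10.0 / _CREA_MOLAR_MASS
    return value * _CREA_MOLAR_MASS / 10.0
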