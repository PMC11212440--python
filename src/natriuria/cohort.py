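"""Cohort data model, collection screening and preprocessing.

Implements the 24h-collection validity rules of the study protocol
(collections rejected below a daily volume of 250 ml or outside the 20-28 h
window), the correction of off-24h collections to a 24 h basis by linear
rescaling, the averaging of AM/PM spot samples, and the adjustment of spot
sodium to urinary creatinine.  Cohort files are flat CSV, one row per
participant; empty fields are missing and propagate as pairwise-complete
data, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .equations import NA_MG_PER_MMOL, Anthropometry, SpotSample

__all__ = [
    "Collection24h",
    "Excretion24h",
    "Participant",
    "ValidationResult",
    "validate_collection",
    "normalize_to_24h",
    "average_spot",
    "creatinine_adjust",
    "COHORT_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
    "participants_from_frame",
]

#: Canonical cohort CSV schema (header order).
COHORT_COLUMNS = [
    "id",
    "sex",
    "age_y",
    "weight_kg",
    "height_cm",
    "bmi",
    "serum_crea_mg_dl",
    "diuretic",
    "egfr_ml_min",
    "am_una_mmol_l",
    "am_uk_mmol_l",
    "am_ucrea_mg_dl",
    "pm_una_mmol_l",
    "pm_uk_mmol_l",
    "pm_ucrea_mg_dl",
    "dur_h",
    "vol_ml",
    "u24_una_mmol_l",
    "u24_uk_mmol_l",
    "u24_ucrea_mg_dl",
]

MIN_DAILY_VOLUME_ML = 250.0
MIN_DURATION_H = 20.0
MAX_DURATION_H = 28.0


@dataclass(frozen=True)
class Collection24h:
    """A timed urine collection before normalization to 24 h."""

    duration: float  # h
    volume: float  # ml
    una: float  # mmol/l
    uk: float  # mmol/l
    ucrea_mg_dl: float  # mg/dl

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("collection duration must be positive")
        if self.volume < 0:
            raise ValueError("collection volume must be >= 0")


@dataclass(frozen=True)
class Excretion24h:
    """Daily excretion rates after correction to a 24 h basis."""

    na_mmol_d: float
    k_mmol_d: float
    crea_g_d: float
    normalized: bool  # True when the collection duration was not exactly 24 h

    @property
    def na_mg_d(self) -> float:
        return NA_MG_PER_MMOL * self.na_mmol_d

    @property
    def na_g_d(self) -> float:
        return self.na_mg_d / 1000.0


@dataclass(frozen=True)
class ValidationResult:
    accepted: bool
    reason: Optional[str] = None

    def __bool__(self) -> bool:
        return self.accepted


@dataclass(frozen=True)
class Participant:
    id: str
    anthro: Anthropometry
    serum_creatinine: float  # mg/dl
    diuretic_use: bool
    ckd_stage: str  # G1, G2, G3a, G3b, G4, G5
    am: Optional[SpotSample]
    pm: Optional[SpotSample]
    collection: Collection24h
    serum_sodium: Optional[float] = None  # mmol/l, carried but unused downstream

    def __post_init__(self) -> None:
        if self.am is not None and self.am.timing != "AM":
            raise ValueError("am sample must have timing AM")
        if self.pm is not None and self.pm.timing != "PM":
            raise ValueError("pm sample must have timing PM")


def validate_collection(c: Collection24h) -> ValidationResult:
    """Screen a 24h collection against the protocol's exclusion rules.

    Rejects collections shorter than 20 h or longer than 28 h, and
    collections whose volume, once normalized to a daily rate, is below
    250 ml/d.  Boundary values are accepted (the rules are "below"/"above").
    """
    if c.duration < MIN_DURATION_H:
        return ValidationResult(False, f"duration {c.duration:g} h below {MIN_DURATION_H:g} h")
    if c.duration > MAX_DURATION_H:
        return ValidationResult(False, f"duration {c.duration:g} h above {MAX_DURATION_H:g} h")
    daily_volume = c.volume * 24.0 / c.duration
    if daily_volume < MIN_DAILY_VOLUME_ML:
        return ValidationResult(
            False, f"daily volume {daily_volume:g} ml/d below {MIN_DAILY_VOLUME_ML:g} ml/d"
        )
    return ValidationResult(True)


def normalize_to_24h(c: Collection24h) -> Excretion24h:
    """Correct a valid collection to a 24 h basis by linear rescaling.

    Total excretion (concentration × volume) is multiplied by 24/duration.
    For a collection of exactly 24 h this is the identity.
    """
    result = validate_collection(c)
    if not result:
        raise ValueError(f"collection fails validity screening: {result.reason}")
    scale = 24.0 / c.duration
    litres = c.volume / 1000.0
    return Excretion24h(
        na_mmol_d=c.una * litres * scale,
        k_mmol_d=c.uk * litres * scale,
        # mg/dl -> g/l is /100; × litres × scale gives g/d
        crea_g_d=c.ucrea_mg_dl / 100.0 * litres * scale,
        normalized=(c.duration != 24.0),
    )


def average_spot(am: Optional[SpotSample], pm: Optional[SpotSample]) -> Optional[SpotSample]:
    """Component-wise mean of the AM and PM spot samples, (AM+PM)/2.

    Returns None when either sample is missing (pairwise-complete analysis;
    missingness propagates, it is never imputed).  Potassium is averaged
    only when present in both samples.
    """
    if am is None or pm is None:
        return None
    uk = None
    if am.uk is not None and pm.uk is not None:
        uk = (am.uk + pm.uk) / 2.0
    return SpotSample(
        timing="AVG",
        una=(am.una + pm.una) / 2.0,
        ucrea_mg_dl=(am.ucrea_mg_dl + pm.ucrea_mg_dl) / 2.0,
        uk=uk,
    )


def creatinine_adjust(s: SpotSample) -> float:
    """Spot sodium per gram of creatinine, mmol Na / g creatinine.

    una[mmol/l] / (ucrea[mg/dl] / 100)[g/l]; both concentrations are per
    litre so the litres cancel.
    """
    if not s.ucrea_mg_dl > 0:
        raise ValueError("creatinine concentration must be positive")
    return s.una / (s.ucrea_mg_dl / 100.0)


# ---------------------------------------------------------------------------
# CSV <-> dataframe <-> Participant plumbing


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV (schema COHORT_COLUMNS), tolerating comment lines."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    return df


def write_cohort_csv(df: pd.DataFrame, path, *, header_comment: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, columns=COHORT_COLUMNS)


def _spot_from_row(row, prefix: str, timing: str) -> Optional[SpotSample]:
    una = row[f"{prefix}_una_mmol_l"]
    ucrea = row[f"{prefix}_ucrea_mg_dl"]
    if _is_missing(una) or _is_missing(ucrea):
        return None
    uk = row[f"{prefix}_uk_mmol_l"]
    return SpotSample(
        timing=timing,
        una=float(una),
        ucrea_mg_dl=float(ucrea),
        uk=None if _is_missing(uk) else float(uk),
    )


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def participants_from_frame(df: pd.DataFrame) -> list[Participant]:
    """Build Participant records from a cohort dataframe.

    Schema violations are reported with the offending row number.  CKD stage
    is assigned from the eGFR column (KDIGO bands).
    """
    from .syncohort import stage_from_egfr  # local import avoids a cycle

    out: list[Participant] = []
    for idx, row in df.iterrows():
        try:
            anthro = Anthropometry(
                sex=str(row["sex"]),
                age=float(row["age_y"]),
                weight=float(row["weight_kg"]),
                height=float(row["height_cm"]),
                bmi=None if _is_missing(row["bmi"]) else float(row["bmi"]),
            )
            collection = Collection24h(
                duration=float(row["dur_h"]),
                volume=float(row["vol_ml"]),
                una=float(row["u24_una_mmol_l"]),
                uk=float(row["u24_uk_mmol_l"]),
                ucrea_mg_dl=float(row["u24_ucrea_mg_dl"]),
            )
            out.append(
                Participant(
                    id=str(row["id"]),
                    anthro=anthro,
                    serum_creatinine=float(row["serum_crea_mg_dl"]),
                    diuretic_use=bool(int(row["diuretic"])),
                    ckd_stage=stage_from_egfr(float(row["egfr_ml_min"])),
                    am=_spot_from_row(row, "am", "AM"),
                    pm=_spot_from_row(row, "pm", "PM"),
                    collection=collection,
                )
            )
        except (ValueError, KeyError, TypeError) as exc:
            raise ValueError(f"cohort row {idx}: {exc}") from exc
    return out
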