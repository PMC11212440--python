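"""Seedable synthetic CKD-cohort generator.

Emulates the marginal distributions of a German CKD sub-cohort (n = 108;
66 men / 42 women; age 62.2 ± 11.9 y on [19, 74]; BMI 29.7 ± 6.2; serum
creatinine 1.56 ± 0.5 mg/dl; 24h collection time 24.2 ± 1.0 h on
[20.8, 26.7]; urine volume mean 2511 ml on [500, 6500]; 24h sodium
excretion mean ≈ 183 mmol/d on [19, 437]; 54.6% diuretic users) and links
the AM/PM spot-urine sodium concentrations to the latent 24h excretion
through a Gaussian copula so that the spot-vs-24h Spearman correlations hit
configurable targets (defaults 0.234 for AM, 0.463 for PM).

Marginal calibration notes
--------------------------
* BMI, collection duration and serum creatinine are truncated normals whose
  underlying (mu, sigma) are solved numerically so that the *truncated*
  mean and SD equal the stated ones.
* Age cannot be a truncated normal: no truncated normal supported on
  [19, 74] attains SD 11.9 at mean 62.2 (the supremum is about 11.2).  Age
  is instead a beta distribution rescaled to [19, 74] and moment-matched
  exactly; the resulting shape is upper-edge-heavy, consistent with an
  elderly CKD cohort.
* 24h sodium excretion and urine volume are lognormals matched to the
  stated means and clipped to the stated observed ranges.

Because the clipped ranges for duration and volume sit strictly inside the
protocol's exclusion rules (20-28 h, >= 250 ml/d), a generated cohort never
loses participants to validity screening, mirroring the study in which no
participant had to be excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .cohort import COHORT_COLUMNS, Collection24h, Participant, write_cohort_csv
from .equations import Anthropometry, SpotSample

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "generate",
    "egfr_mdrd",
    "stage_from_egfr",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Calibration of the synthetic cohort; defaults are the study's values."""

    n: int = 108
    frac_male: float = 66 / 108
    age_mean: float = 62.2
    age_sd: float = 11.9
    age_range: tuple = (19.0, 74.0)
    bmi_mean: float = 29.7
    bmi_sd: float = 6.2
    bmi_range: tuple = (16.0, 55.0)
    scr_mean: float = 1.56
    scr_sd: float = 0.5
    scr_range: tuple = (0.6, 3.5)
    dur_mean: float = 24.2
    dur_sd: float = 1.0
    dur_range: tuple = (20.8, 26.7)
    vol_mean: float = 2511.0
    vol_range: tuple = (500.0, 6500.0)
    vol_log_sd: float = 0.42
    # mean 24h Na excretion: 10.7 g/d salt / 2.54 (g salt per g Na) / 23 mg/mmol
    na24_mean: float = 10.7 / 2.54 / 23.0 * 1000.0
    na24_range: tuple = (19.0, 437.0)
    na24_log_sd: float = 0.55
    k24_mean: float = 70.0  # mmol/d, typical adult urinary potassium
    k24_log_sd: float = 0.35
    target_rho_am: float = 0.234
    target_rho_pm: float = 0.463
    spot_log_sd: float = 0.5  # dispersion of spot Na concentration marginals
    crea_noise_log_sd: float = 0.3  # spot-vs-daily creatinine concentration noise
    frac_diuretic: float = 0.546
    serum_na_mean: float = 145.0
    serum_na_sd: float = 4.8
    missing_pm: int = 1  # study had 107 PM samples for 108 participants
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("age_sd", "bmi_sd", "scr_sd", "dur_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("frac_male", "frac_diuretic"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("target_rho_am", "target_rho_pm"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"{name} must lie in (-1, 1)")


@dataclass(frozen=True)
class SyntheticCohort:
    participants: list
    config: GeneratorConfig
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            rows.append(
                {
                    "id": p.id,
                    "sex": p.anthro.sex,
                    "age_y": p.anthro.age,
                    "weight_kg": p.anthro.weight,
                    "height_cm": p.anthro.height,
                    "bmi": p.anthro.bmi,
                    "serum_crea_mg_dl": p.serum_creatinine,
                    "diuretic": int(p.diuretic_use),
                    "egfr_ml_min": egfr_mdrd(
                        p.serum_creatinine, p.anthro.age, p.anthro.sex
                    ),
                    "am_una_mmol_l": p.am.una if p.am else np.nan,
                    "am_uk_mmol_l": p.am.uk if p.am else np.nan,
                    "am_ucrea_mg_dl": p.am.ucrea_mg_dl if p.am else np.nan,
                    "pm_una_mmol_l": p.pm.una if p.pm else np.nan,
                    "pm_uk_mmol_l": p.pm.uk if p.pm else np.nan,
                    "pm_ucrea_mg_dl": p.pm.ucrea_mg_dl if p.pm else np.nan,
                    "dur_h": p.collection.duration,
                    "vol_ml": p.collection.volume,
                    "u24_una_mmol_l": p.collection.una,
                    "u24_uk_mmol_l": p.collection.uk,
                    "u24_ucrea_mg_dl": p.collection.ucrea_mg_dl,
                }
            )
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)

    def write_csv(self, path) -> None:
        write_cohort_csv(
            self.to_frame(), path, header_comment=f"synthetic cohort, seed={self.seed}"
        )


def egfr_mdrd(scr: float, age: float, sex: str) -> float:
    """Estimated GFR (ml/min/1.73 m²), 4-variable MDRD, 175-based.

    eGFR = 175 × Scr^-1.154 × age^-0.203 × (0.742 if female).
    """
    if not scr > 0 or not age > 0:
        raise ValueError("serum creatinine and age must be positive")
    egfr = 175.0 * scr**-1.154 * age**-0.203
    if sex == "female":
        egfr *= 0.742
    elif sex != "male":
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    return egfr


def stage_from_egfr(egfr: float) -> str:
    """KDIGO CKD G-stage from eGFR, with G3 split at 45 into G3a/G3b."""
    if egfr >= 90:
        return "G1"
    if egfr >= 60:
        return "G2"
    if egfr >= 45:
        return "G3a"
    if egfr >= 30:
        return "G3b"
    if egfr >= 15:
        return "G4"
    return "G5"


@lru_cache(maxsize=None)
def _truncnorm_params(mean: float, sd: float, lo: float, hi: float):
    """Solve for (mu, sigma) so truncnorm on [lo, hi] has the given moments."""

    def resid(p):
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = sps.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.least_squares(resid, [mean, math.log(sd)], xtol=1e-13, ftol=1e-13)
    mu, sigma = sol.x[0], math.exp(sol.x[1])
    return mu, sigma


def _truncnorm_sample(rng, n, mean, sd, lo, hi):
    mu, sigma = _truncnorm_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return sps.truncnorm.ppf(rng.uniform(size=n), a, b, loc=mu, scale=sigma)


def _beta_sample(rng, n, mean, sd, lo, hi):
    """Moment-matched beta on [lo, hi] (used where a truncnorm is infeasible)."""
    m = (mean - lo) / (hi - lo)
    v = (sd / (hi - lo)) ** 2
    if v >= m * (1 - m):
        raise ValueError("infeasible beta moments")
    c = m * (1 - m) / v - 1.0
    return lo + (hi - lo) * sps.beta.ppf(rng.uniform(size=n), m * c, (1 - m) * c)


def _rho_gauss(rho_spearman: float) -> float:
    """Gaussian-copula correlation that induces a given Spearman rho."""
    return 2.0 * math.sin(math.pi * rho_spearman / 6.0)


def generate(config: Optional[GeneratorConfig] = None, *, seed: Optional[int] = None) -> SyntheticCohort:
    """Generate a synthetic cohort; bit-for-bit reproducible given (config, seed).

    ``seed`` overrides ``config.seed`` when given.
    """
    cfg = config or GeneratorConfig()
    if seed is not None:
        cfg = GeneratorConfig(**{**asdict(cfg), "seed": int(seed)})
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    # -- demographics ------------------------------------------------------
    n_male = int(round(n * cfg.frac_male))
    sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sexes)
    male = sexes == "male"

    age = _beta_sample(rng, n, cfg.age_mean, cfg.age_sd, *cfg.age_range)
    bmi = _truncnorm_sample(rng, n, cfg.bmi_mean, cfg.bmi_sd, *cfg.bmi_range)
    height = np.where(
        male, rng.normal(176.0, 7.0, n), rng.normal(163.0, 6.5, n)
    ).clip(145.0, 205.0)
    weight = bmi * (height / 100.0) ** 2
    scr = _truncnorm_sample(rng, n, cfg.scr_mean, cfg.scr_sd, *cfg.scr_range)
    serum_na = rng.normal(cfg.serum_na_mean, cfg.serum_na_sd, n)
    diuretic = rng.uniform(size=n) < cfg.frac_diuretic

    # -- collection timing and volume -------------------------------------
    duration = _truncnorm_sample(rng, n, cfg.dur_mean, cfg.dur_sd, *cfg.dur_range)
    mu_vol = math.log(cfg.vol_mean) - cfg.vol_log_sd**2 / 2.0
    volume = np.exp(rng.normal(mu_vol, cfg.vol_log_sd, n)).clip(*cfg.vol_range)
    vol_l = volume / 1000.0
    daily_vol_l = vol_l * 24.0 / duration

    # -- latent 24h excretion and copula-linked spot concentrations --------
    r_am = _rho_gauss(cfg.target_rho_am)
    r_pm = _rho_gauss(cfg.target_rho_pm)
    cov = np.array(
        [
            [1.0, r_am, r_pm],
            [r_am, 1.0, r_am * r_pm],  # AM & PM conditionally independent
            [r_pm, r_am * r_pm, 1.0],
        ]
    )
    z = rng.multivariate_normal(np.zeros(3), cov, size=n, method="cholesky")
    z24, z_am, z_pm = z[:, 0], z[:, 1], z[:, 2]

    mu_na = math.log(cfg.na24_mean) - cfg.na24_log_sd**2 / 2.0
    na24 = np.exp(mu_na + cfg.na24_log_sd * z24).clip(*cfg.na24_range)  # mmol/d

    # spot Na concentration marginal: lognormal with median at the cohort's
    # excretion-over-volume scale, dispersion covering circadian variation
    spot_median = cfg.na24_mean / (cfg.vol_mean / 1000.0)
    mu_spot = math.log(spot_median)
    am_una = np.exp(mu_spot + cfg.spot_log_sd * z_am)
    pm_una = np.exp(mu_spot + cfg.spot_log_sd * z_pm)

    # -- creatinine and potassium ------------------------------------------
    crea_rate = np.where(male, 20.0, 15.0)  # mg/kg/d
    crea_rate = crea_rate * (1.0 - 0.02 * np.maximum(age - 50.0, 0.0))
    crea_daily_mg = crea_rate * weight
    u24_ucrea = crea_daily_mg * (duration / 24.0) / vol_l / 10.0  # mg/dl
    am_ucrea = crea_daily_mg / daily_vol_l / 10.0 * np.exp(
        rng.normal(0.0, cfg.crea_noise_log_sd, n)
    )
    pm_ucrea = crea_daily_mg / daily_vol_l / 10.0 * np.exp(
        rng.normal(0.0, cfg.crea_noise_log_sd, n)
    )

    mu_k = math.log(cfg.k24_mean) - cfg.k24_log_sd**2 / 2.0
    k24 = np.exp(rng.normal(mu_k, cfg.k24_log_sd, n))  # mmol/d
    u24_uk = k24 * (duration / 24.0) / vol_l
    am_uk = k24 / daily_vol_l * np.exp(rng.normal(0.0, cfg.crea_noise_log_sd, n))
    pm_uk = k24 / daily_vol_l * np.exp(rng.normal(0.0, cfg.crea_noise_log_sd, n))

    # 24h concentrations chosen so normalization recovers the latent excretion
    u24_una = na24 * (duration / 24.0) / vol_l

    pm_missing = set(
        rng.choice(n, size=min(cfg.missing_pm, n), replace=False).tolist()
    )

    participants = []
    for i in range(n):
        anthro = Anthropometry(
            sex=str(sexes[i]),
            age=float(age[i]),
            weight=float(weight[i]),
            height=float(height[i]),
            bmi=float(bmi[i]),
        )
        am = SpotSample(
            timing="AM",
            una=float(am_una[i]),
            ucrea_mg_dl=float(am_ucrea[i]),
            uk=float(am_uk[i]),
        )
        pm = None
        if i not in pm_missing:
            pm = SpotSample(
                timing="PM",
                una=float(pm_una[i]),
                ucrea_mg_dl=float(pm_ucrea[i]),
                uk=float(pm_uk[i]),
            )
        collection = Collection24h(
            duration=float(duration[i]),
            volume=float(volume[i]),
            una=float(u24_una[i]),
            uk=float(u24_uk[i]),
            ucrea_mg_dl=float(u24_ucrea[i]),
        )
        egfr = egfr_mdrd(float(scr[i]), float(age[i]), str(sexes[i]))
        participants.append(
            Participant(
                id=f"S{i + 1:04d}",
                anthro=anthro,
                serum_creatinine=float(scr[i]),
                diuretic_use=bool(diuretic[i]),
                ckd_stage=stage_from_egfr(egfr),
                am=am,
                pm=pm,
                collection=collection,
                serum_sodium=float(serum_na[i]),
            )
        )
    return SyntheticCohort(participants=participants, config=cfg, seed=cfg.seed)
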