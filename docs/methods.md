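# Methods

## Problem and scope

A 24h urine collection measures daily sodium excretion (the accepted
surrogate for salt intake) directly; a spot urine sample measures only a
concentration at one moment. Prediction equations bridge the gap by
scaling the spot sodium/creatinine ratio by an anthropometric estimate of
daily creatinine excretion (Kawasaki, Tanaka) or by regressing daily
excretion on spot concentrations, BMI and age (INTERSALT). This package
implements those equations, the preprocessing a validation study applies
to its urine collections, the agreement statistics used to judge the
equations, a synthetic CKD cohort to exercise everything end to end, and
the pipeline that ties them together.

## Prediction equations

The three closed forms are implemented literally as published, including
the `×10` inside the Kawasaki/Tanaka ratio (which converts creatinine
mg/dl to mg/l) and the outer `×23` (mg of sodium per mmol). Keeping the
printed structure rather than algebraically simplifying makes the code
auditable against the sources; the test suite verifies agreement with an
independent 50-digit arbitrary-precision evaluation of the same forms to
at least 10 significant digits across the physiological input range.

Choices that were genuinely open:

- **Molar factor.** The equations' own `×23` is used for their outputs.
  The sodium↔salt conversion, which is not part of any printed equation,
  uses exact molar masses (58.443/22.990 ≈ 2.5421 g NaCl per g Na,
  2.54 at three significant figures).
- **Kawasaki timing.** The equation was derived for second-morning-void
  samples, so PM samples raise an error by default; `allow_pm=True`
  permits exploratory use and flags the estimate `ineligible_timing`.
  The analysis pipeline leaves the Kawasaki-PM cell intentionally empty.
- **Negative INTERSALT estimates** (possible for dilute urine in small,
  young subjects) are returned with a `negative_estimate` flag rather
  than clamped to zero: clamping would bias Bland–Altman statistics.
- **BMI precedence.** A supplied BMI wins over the weight/height-derived
  value; BMI is derived only when absent.
- **Creatinine units** convert by molar mass 113.12 g/mol
  (mg/dl × 10/113.12 = mmol/l ≈ the conventional 0.0884 factor), giving
  an exact round trip.

## Collection screening and normalization

Collections are rejected when the duration is below 20 h or above 28 h,
or when the volume expressed as a daily rate falls below 250 ml/d.
Boundary values are accepted because the rules are phrased strictly
("below"/"above"), and the volume rule is applied *after* normalizing to
a daily rate since 250 ml/d is a rate. "Correction to 24h" is a linear
rescaling of total excretion (concentration × volume) by 24/duration —
the simplest defensible reading; it is isolated in one function
(`normalize_to_24h`) so any alternative convention would be a one-line
change. Under linear rescaling only total excretions are affected, so
whether concentrations are also notionally rescaled is immaterial to
every downstream quantity.

Missing spot samples (e.g. a participant who skipped the PM void)
propagate as pairwise-complete analysis: each statistic uses every
participant with complete data for that statistic, and each reported
cell carries its own n.

## Agreement statistics

- **Spearman correlation** uses average ranks for ties and the
  t-approximation for p (n − 2 df), matching mainstream statistical
  software; an exhaustive brute-force rank oracle over small tied vectors
  backs it in the tests.
- **Fisher-Z comparison** uses the independent-samples formula
  `z = (atanh r₁ − atanh r₂)/√(1/(n₁−3)+1/(n₂−3))` even when the two
  correlations involve the same participants (AM vs PM): this is the
  procedure the validation-study design prescribes and it reproduces
  every published comparison in the correlation table to three decimals.
  A dependent-correlations variant (Steiger) is deliberately out of
  scope. The primary p-value is one-sided, Φ(−|z|), which is what the
  published p-values correspond to; a two-sided value is available on
  the result object.
- **Bland–Altman** differences are fixed as measured − estimated, so a
  positive bias means the formula underestimates; limits of agreement
  are bias ± 1.96 times the sample SD (ddof = 1) of the differences. The
  bias-significance test is a one-sample t-test of the differences
  against zero (the natural choice where no specific test is mandated).
- **P30** counts estimates within ±30% of the measured value, boundary
  inclusive.
- **Classification** at a sodium threshold uses strict `>` on both the
  measured and estimated sides; metrics with an empty denominator are
  reported as missing (`None`/absent), never as 0, and PPV satisfies the
  Bayes prevalence identity exactly on every confusion table (verified
  in rational arithmetic in the tests).

## Synthetic cohort generator

The generator emulates the *marginal* distributions of a 108-participant
German CKD sub-cohort and the *rank* dependence between spot
concentrations and 24h excretion. Defaults (all overridable via
`GeneratorConfig`):

| quantity | default | source of the value |
|---|---|---|
| n; fraction male | 108; 66/108 | cohort size and sex split |
| age | 62.2 ± 11.9 y on [19, 74] | cohort moments and enrollment bounds |
| BMI | 29.7 ± 6.2 kg/m² | cohort moments |
| serum creatinine | 1.56 ± 0.5 mg/dl | cohort moments |
| collection duration | 24.2 ± 1.0 h on [20.8, 26.7] | cohort moments and observed range |
| urine volume | lognormal, mean 2511 ml, clipped [500, 6500] | cohort mean and observed range |
| 24h U-Na | lognormal, mean ≈183 mmol/d, clipped [19, 437] | mean from 10.7 g/d salt ÷ 2.54 ÷ 23; observed range |
| Spearman(spot, 24h) | 0.234 (AM), 0.463 (PM) | the correlations under study |
| diuretic use | Bernoulli(0.546) | cohort fraction |
| daily creatinine excretion | 20 (men) / 15 (women) mg/kg/d, −2%/y after age 50 | standard physiology; no cohort model exists |
| urinary potassium | lognormal, mean 70 mmol/d | typical adult excretion |
| missing PM samples | 1 | the cohort had 107 PM samples for 108 participants |
| serum sodium | 145 ± 4.8 mmol/l | cohort value; generated but feeds nothing |

Mechanism and numerical choices:

- **Moment-matched truncated marginals.** For BMI, duration and serum
  creatinine the underlying (μ, σ) of a truncated normal are solved
  numerically so the *truncated* mean and SD equal the targets. For age
  this is infeasible — no truncated normal on [19, 74] reaches SD 11.9
  at mean 62.2 (the supremum is ≈ 11.2) — so age is a beta distribution
  rescaled to [19, 74] and moment-matched exactly; the resulting
  upper-edge-heavy shape is plausible for an elderly CKD cohort.
- **Gaussian copula dependence.** A trivariate standard normal links the
  latent 24h excretion with the AM and PM spot concentrations, with AM
  and PM conditionally independent given the latent excretion. The
  copula correlation is `ρ = 2·sin(π·ρₛ/6)`, the exact inversion of the
  Spearman correlation a Gaussian copula induces, so the rank targets
  are controlled directly (the acceptance surface is rank correlation).
  The spot-concentration marginals are lognormal with median at the
  cohort's excretion/volume scale; the marginal's dispersion plays the
  role of circadian and sampling noise.
- **Internal consistency.** 24h-collection concentrations are derived
  from the latent daily excretion, the drawn duration and the drawn
  volume, so normalizing a generated collection recovers the latent
  excretion exactly; eGFR and CKD stage are computed from the generated
  creatinine/age/sex via the 175-based 4-variable MDRD formula (KDIGO
  bands, G3 split at 45 ml/min/1.73 m²) rather than sampled
  independently, keeping strata coherent. Because the generated duration
  and volume ranges sit strictly inside the protocol's exclusion rules,
  screening excludes nobody — as in the emulated cohort.
- **Determinism.** All randomness flows through one `numpy` Generator
  seeded from the config; identical (config, seed) reproduce the cohort
  bit for bit. Sex counts are exact (66/42 at n = 108) with a shuffled
  assignment; the diuretic flag is Bernoulli.

What the generator does **not** emulate: day-to-day and infradian
intra-individual sodium variability, real circadian concentration
profiles (AM vs PM marginals are exchangeable up to their copula link),
medication effects on excretion, or any association between CKD stage or
diuretic use and the spot-vs-24h correlation (strata differ only by
sampling noise). Consequently, pipeline results on synthetic cohorts
demonstrate that the machinery is correct and deterministic — not that
any particular formula performs well or poorly in real CKD patients,
and synthetic stratified comparisons are expected to be null.

## Pipeline

Participants are sorted by id, screened, normalized, and analyzed; the
report is a plain JSON-serializable structure with every cell carrying
its n. Cells with fewer than 4 complete pairs are missing rather than
errors so small cohorts run. Strata are CKD stage G1–3a vs G3b–5 and
diuretics yes/no, each compared with Fisher's Z. Thresholds default to
2 and 4 g/d sodium. Outputs: `report.json` (sorted keys, so re-runs are
byte-identical), flat TSVs, and per-formula Bland–Altman plot data CSVs.

## Test and verification sizes

Monte-Carlo checks use n = 5000 cohorts for parameter and correlation
recovery (tolerance ±0.03 on Spearman targets, ±3% relative on moments),
n = 10⁵ normal differences for limits-of-agreement coverage (95 ± 2%),
1000 random physiological inputs for the arbitrary-precision equation
sweep, and exhaustive enumeration of tied vectors of lengths 3–4 over
{1..4} (with random sampling at lengths 5–7) for the Spearman oracle.

## Known limitations

- The independent-samples Fisher-Z comparison is anticonservative for
  correlations sharing participants; it is retained by design (see
  above) and should be interpreted accordingly.
- The equations are applied as published; no recalibration to CKD
  populations is attempted, and no other published estimators are
  included.
- The creatinine-excretion model is a population-level approximation;
  individual muscle-mass variation is represented only by lognormal
  noise.
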