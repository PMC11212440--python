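"""Estimate 24h sodium excretion for one patient from a morning spot urine.

Builds a typical CKD outpatient (male, 60 y, 80 kg, 170 cm) with a morning
spot urine of 100 mmol/l sodium, 100 mg/dl creatinine and 50 mmol/l
potassium, then applies all three prediction equations and converts the
results to daily salt intake.
"""

from natriuria import (
    Anthropometry,
    SpotSample,
    estimate_intersalt,
    estimate_kawasaki,
    estimate_tanaka,
    na_to_salt,
)

patient = Anthropometry(sex="male", age=60, weight=80, height=170)
spot = SpotSample(timing="AM", una=100.0, ucrea_mg_dl=100.0, uk=50.0)

for est in (
    estimate_kawasaki(spot, patient),
    estimate_tanaka(spot, patient),
    estimate_intersalt(spot, patient),
):
    salt = na_to_salt(est.na_g_per_day)
    print(
        f"{est.formula_id:>9}: {est.na_mg_per_day:7.1f} mg Na/d "
        f"({est.na_mmol_per_day:6.1f} mmol/d) ~ {salt:.1f} g salt/d"
    )

# The three equations disagree by >1 g Na/d for the same specimen — the
# spread itself is the clinically relevant message: spot-urine estimates
# carry large formula-dependent uncertainty for an individual patient.
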