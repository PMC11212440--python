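"""Screen 24h urine collections and correct them to a 24h basis.

Shows the protocol's validity rules (duration within 20-28 h, daily volume
at least 250 ml) and the linear time-correction of total excretion for a
collection that ran 26.7 h instead of 24 h.
"""

from natriuria import Collection24h, normalize_to_24h, validate_collection

collections = {
    "good 24.0h": Collection24h(duration=24.0, volume=2000, una=100, uk=50, ucrea_mg_dl=80),
    "long 26.7h": Collection24h(duration=26.7, volume=2670, una=100, uk=50, ucrea_mg_dl=80),
    "too short": Collection24h(duration=19.5, volume=2000, una=100, uk=50, ucrea_mg_dl=80),
    "too little": Collection24h(duration=24.0, volume=200, una=100, uk=50, ucrea_mg_dl=80),
}

for name, c in collections.items():
    res = validate_collection(c)
    if not res:
        print(f"{name:>10}: REJECTED ({res.reason})")
        continue
    e = normalize_to_24h(c)
    tag = "time-corrected" if e.normalized else "as collected"
    print(
        f"{name:>10}: accepted, {e.na_mmol_d:6.1f} mmol Na/d "
        f"({e.na_mg_d:7.0f} mg/d), creatinine {e.crea_g_d:.2f} g/d [{tag}]"
    )

# The 26.7h collection contains more urine than a 24h day; rescaling by
# 24/26.7 makes its daily sodium excretion comparable across participants.
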