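"""Run the complete validation analysis on a synthetic cohort.

Simulates the default cohort, runs the full pipeline (correlation table
with CKD/diuretic strata, Bland-Altman agreement per formula and timing,
P30, threshold classification) and prints the formula-evaluation summary.
"""

from natriuria import generate, run_analysis

report = run_analysis(generate(seed=1).to_frame())

print(f"analyzed {report['n_analyzed']} of {report['n_input']} participants\n")

corr = report["correlations"]["vs_24h_excretion_mmol_d"]
for timing in ("AM", "PM", "AVG"):
    cell = corr[timing]["all"]
    print(f"spot {timing:>3} U-Na vs 24h excretion: r = {cell['r']:+.3f} "
          f"(p = {cell['p']:.3g}, n = {cell['n']})")

print("\nformula      timing   n    bias mg/d   LoA mg/d            P30%")
for formula, timings in report["agreement"].items():
    for timing, cell in timings.items():
        if cell is None:
            print(f"{formula:<12} {timing:<6} (not eligible)")
            continue
        print(f"{formula:<12} {timing:<6} {cell['n']:>3}  {cell['mean_bias_mg_d']:+9.1f}"
              f"   [{cell['loa_low_mg_d']:+8.1f}, {cell['loa_high_mg_d']:+8.1f}]"
              f"  {cell['p30_pct']:5.1f}")

print("\nclassification at the 2 g/d sodium threshold (salt > 5 g/d):")
for formula, timings in report["classification"].items():
    for timing, cells in timings.items():
        if cells is None:
            continue
        c = cells["2"]
        fmt = lambda v: "  --" if v is None else f"{v:4.0f}"
        print(f"  {formula:<10} {timing}: sens {fmt(c['sensitivity_pct'])}  "
              f"spec {fmt(c['specificity_pct'])}  ppv {fmt(c['ppv_pct'])}  "
              f"npv {fmt(c['npv_pct'])}")

# Bias is measured minus estimated: positive means the formula
# underestimates. The wide limits of agreement are the study's core
# finding — group-level estimation is feasible, individual-level is not.
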