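"""Compute HOMA beta-cell-function and insulin-resistance indices.

The cohort records carry fasting glucose in mg/dL and insulin in mIE/L
(numerically uU/mL); the HOMA1 closed forms work in mmol/L, so glucose is
converted with 18.016 mg/dL per mmol/L.
"""

from diatraj import compute_homa, mgdl_to_mmol

print(f"126 mg/dL  = {mgdl_to_mmol(126.0):.4f} mmol/L  (fasting diagnostic threshold)")

for fpg, insulin, who in [
    (90.1, 10.0, "normoglycemic, normal insulin"),
    (126.0, 17.0, "at the diagnostic threshold, raised insulin"),
    (160.0, 8.0, "hyperglycemic with low insulin (beta-cell failure pattern)"),
]:
    r = compute_homa(fpg, insulin)
    print(
        f"FPG {fpg:6.1f} mg/dL, insulin {insulin:4.1f} mIE/L -> "
        f"HOMA-B {r.homa_b:6.1f} %   HOMA-IR {r.homa_ir:5.2f} a.u.   ({who})"
    )

print(
    "\nHOMA-B ~100% and HOMA-IR ~1 correspond to a reference healthy adult; "
    "low HOMA-B flags insulin deficiency (SIDD), high HOMA-IR flags insulin "
    "resistance (SIRD)."
)
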