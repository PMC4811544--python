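"""Evaluate the eGFR equations and clearance helpers on single patients.

Shows how the two creatinine-based estimating equations disagree for the
same laboratory value depending on the patient's age, and how a raw
inulin clearance is indexed to body surface area.
"""

from gfrcompare import (
    body_surface_area_dubois,
    convert_creatinine,
    egfr_ckd_epi,
    egfr_schwartz,
    normalize_to_bsa,
    uvp_clearance,
)
from gfrcompare.equations import ClearancePeriod, CreatinineValue

# A 10-year-old girl and a 30-year-old woman with the same creatinine.
pcr = 60.0  # μmol/l
child = dict(height_cm=138.0)
adult = dict(height_cm=165.0)

print(f"plasma creatinine: {pcr:.0f} umol/l "
      f"(= {convert_creatinine(CreatinineValue(pcr, 'umol_l'), 'mg_dl').value:.2f} mg/dl)")
print(f"child, 10 y  : Schwartz {egfr_schwartz(pcr, child['height_cm']):6.1f}  "
      f"CKD-EPI {egfr_ckd_epi(pcr, 10.0, 'F'):6.1f}  ml/min/1.73m2")
print(f"adult, 30 y  : Schwartz {egfr_schwartz(pcr, adult['height_cm']):6.1f}  "
      f"CKD-EPI {egfr_ckd_epi(pcr, 30.0, 'F'):6.1f}  ml/min/1.73m2")
print()
print("The adult equation, applied to a child, returns a far higher estimate:")
print("its age term encodes adult muscle-mass decline, not pediatric growth.")
print()

# Indexing a measured inulin clearance to 1.73 m².
periods = [
    ClearancePeriod(urine_concentration=120.0, urine_flow=2.1, plasma_concentration=2.4),
    ClearancePeriod(urine_concentration=110.0, urine_flow=2.3, plasma_concentration=2.5),
    ClearancePeriod(urine_concentration=125.0, urine_flow=2.0, plasma_concentration=2.4),
]
raw = uvp_clearance(periods)
bsa = body_surface_area_dubois(165.0, 58.0)
print(f"mean UV/P clearance over {len(periods)} periods: {raw:.1f} ml/min")
print(f"Dubois body surface area (165 cm, 58 kg):   {bsa:.3f} m2")
print(f"indexed measured GFR:                       "
      f"{normalize_to_bsa(raw, bsa):.1f} ml/min/1.73m2")
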