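"""ECV from four T1 values and a haematocrit.

The extracellular volume fraction compares the contrast-induced change in
relaxation rate (R1 = 1/T1) of liver tissue with that of blood, scaled by
the plasma fraction (1 - haematocrit).  Works for any consistent T1 unit.
"""

import hepecv as h

t1_liver_pre, t1_liver_post = 600.0, 450.0  # ms
t1_blood_pre, t1_blood_post = 1600.0, 600.0
haematocrit = 0.45

ecv = h.compute_ecv(t1_liver_pre, t1_liver_post, t1_blood_pre, t1_blood_post, haematocrit)

dr1_liver = 1 / t1_liver_post - 1 / t1_liver_pre
dr1_blood = 1 / t1_blood_post - 1 / t1_blood_pre
print(f"liver  dR1 : {1000 * dr1_liver:.4f} /s")
print(f"blood  dR1 : {1000 * dr1_blood:.4f} /s")
print(f"ECV        : {100 * ecv:.1f} %")
print("\nAn ECV near 18% is typical for healthy liver; values past ~25%")
print("indicate an expanded extracellular space, e.g. from fibrosis.")
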