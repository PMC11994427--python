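"""Compute thyroid secretory capacity (SPINA-GT) from a TSH/FT4 pair.

Run:  python examples/compute_capacity.py
"""

from thyrocap import GT_REFERENCE_RANGE, HormonePair, compute_gt, invert_gt

# group-mean measurements: euthyroid and subclinical-hypothyroid children
for label, tsh, ft4 in [("euthyroid means", 3.01, 16.3), ("SH means", 6.7, 15.7)]:
    result = compute_gt(HormonePair(tsh=tsh, ft4=ft4))
    flag = "in" if result.in_reference_range else "OUTSIDE"
    print(f"{label}: TSH {tsh} mIU/L, FT4 {ft4} pmol/L -> "
          f"GT = {result.gt:.3f} pmol/s ({flag} reference range "
          f"{GT_REFERENCE_RANGE[0]}-{GT_REFERENCE_RANGE[1]} pmol/s)")

# the formula inverts algebraically: which TSH would a 2.368 pmol/s gland
# need to sustain FT4 = 16.3 pmol/L?
tsh = invert_gt(2.368, 16.3)
print(f"a 2.368 pmol/s gland at FT4 16.3 pmol/L implies TSH = {tsh:.3f} mIU/L")

# GT falls as TSH rises at fixed FT4: a higher set point means the same
# FT4 is maintained only under stronger stimulation, i.e. less capacity.
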