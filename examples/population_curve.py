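"""Predicted TSH and predicted capacity from the population TSH-FT4 curve.

Run:  python examples/population_curve.py
"""

from thyrocap import predict_gt, predict_ln_tsh

print("FT4 (pmol/L)  branch    ln TSH   predicted TSH (mIU/L)  predicted GT (pmol/s)")
for ft4 in [7.0, 10.0, 11.9, 12.0, 16.3, 20.6, 24.0]:
    p = predict_ln_tsh(ft4)
    gt = predict_gt(ft4)
    print(f"{ft4:11.1f}  {p.branch:8s}  {p.ln_tsh:6.3f}   {p.tsh:20.3f}  {gt.gt:20.3f}")

# the jump between 11.9 and 12.0 is the published discontinuity where the
# fit switches sigmoid branches; predicted GT depends on FT4 alone, so a
# subject whose measured TSH sits above this curve necessarily has actual
# capacity below the predicted value.
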