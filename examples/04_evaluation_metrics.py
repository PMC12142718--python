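"""Error metrics and the train/test comparison statistics.

Shows the error definitions on three illustrative species-scale cases
(absolute error in years, relative error in percent of the known value),
then Fisher's z for comparing a training against a testing correlation and
the unpaired t-test for comparing residual distributions.
"""

import numpy as np

from finlife import error_metrics, fisher_z_compare, residual_t_test

cases = [("long-lived, badly underpredicted", 183.33, 33.07),
         ("perfect prediction", 12.5, 12.5),
         ("short-lived, overpredicted", 1.0, 8.97)]
for label, known, predicted in cases:
    abs_err, rel_err = error_metrics(known, predicted)
    print(f"{label:35s} known {known:7.2f}y predicted {predicted:6.2f}y "
          f"-> {abs_err:6.2f}y ({rel_err:.1f}%)")

# is a train correlation of .84 significantly better than a test correlation
# of .72, at 140 vs 60 species?
z, p = fisher_z_compare(0.84, 140, 0.72, 60)
print(f"\nFisher z comparing r_train=.84 (n=140) vs r_test=.72 (n=60): "
      f"z={z:.3f}, p={p:.3f}")
print("(p > .05 would mean no evidence of overfitting from correlations alone)")

rng = np.random.default_rng(0)
train_res = rng.normal(0.0, 0.5, size=140)
test_res = rng.normal(0.1, 0.6, size=60)
t, p = residual_t_test(train_res, test_res)
print(f"unpaired t-test on residuals: t={t:.3f}, p={p:.3f}")
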