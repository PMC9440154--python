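"""Cross-validated polygenic score: in-sample vs out-of-sample R^2.

Splits a cohort in half, ranks SNPs by training p-value, and grows a joint
OLS predictor one SNP at a time. In-sample fit rises monotonically by
construction; the held-out R^2 peaks once the informative SNPs are in and
then decays as noise predictors accumulate.
"""

from gxedyn import SimulationConfig, prs_curve, simulate_cohort, split_cohort

cfg = SimulationConfig(gamma=0.05)
cohort = simulate_cohort(cfg, 4000, seed=11, record_series=False)
train, test = split_cohort(cohort, test_fraction=0.5, seed=11)
curve = prs_curve(train, test, max_k=500)

print(f"train n = {train.n}, test n = {test.n}")
print(f"peak out-of-sample R^2 = {curve.peak_r2_test:.3f} at k = {curve.peak_k}")
print(f"out-of-sample R^2 at k = 500: {curve.r2_test[-1]:.3f}")
for k in (1, 5, 20, 50, 200, 500):
    print(f"  k={k:4d}  r2_train={curve.r2_train[k - 1]:.3f}  "
          f"r2_test={curve.r2_test[k - 1]:.3f}")
# The widening train/test gap with k is pure overfitting: each added null
# SNP buys ~1/n of in-sample R^2 and nothing out of sample.
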