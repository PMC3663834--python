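"""Stratified 5-fold cross-validation of a 5-descriptor pKa model.

Molecules are sorted by pKa and dealt into folds block-by-block, so every
fold spans the full pKa range.  Per fold the model is refit on the other
four folds and evaluated on the held-out one; similar train and test R^2
across folds indicates a robust model rather than an overfit one.
"""

from eempka import cross_validate, gen_parameter_set, gen_qspr_dataset, phenol_study_spec

params = gen_parameter_set(3)
desc, pka = gen_qspr_dataset(phenol_study_spec(noise_sigma=0.5, seed=5), params)
cv = cross_validate(desc, pka, "5d", k_folds=5, seed=11)

print(f"{'fold':<6}{'train R2':>10}{'train RMSE':>12}{'test R2':>10}"
      f"{'test RMSE':>12}{'n test':>8}")
for f in cv.folds:
    tr, te = f.train_report, f.test_report
    print(f"{f.fold:<6}{tr.r2:>10.4f}{tr.rmse:>12.3f}{te.r2:>10.4f}"
          f"{te.rmse:>12.3f}{te.n:>8}")

mean_test = sum(f.test_report.r2 for f in cv.folds) / len(cv.folds)
print(f"\nmean held-out R2 = {mean_test:.4f} "
      "(close to the training values: the model generalizes)")
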