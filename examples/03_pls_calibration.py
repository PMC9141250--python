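"""Calibrate a full-spectrum PLS model with CV-selected latent variables.

10-fold cross-validation on the calibration set picks the number of
latent variables minimising RMSECV (capped at 20); the model is then
scored on the held-back validation fruit.
"""

import peachspec as ps

cfg = ps.RunConfig().with_seed(1)
data = ps.generate_dataset(cfg.synth, orientations=[ps.Orientation.O1])

mat = ps.preprocess_pipeline(data, ps.Combination.S1S3)
cal, val = mat.subset("calibration"), mat.subset("validation")

cv = ps.select_lv_by_cv(cal.values, cal.ssc, max_lv=20, n_folds=10, seed=1)
print("RMSECV by LV count:",
      " ".join(f"{v:.3f}" for v in cv.rmsecv[:10]), "...")
print(f"chosen LVs: {cv.best_lv} (RMSECV {cv.best_rmsecv:.3f} %, RCV {cv.best_rcv:.3f})")

model = ps.fit_pls(cal.values, cal.ssc, cv.best_lv)
rp = ps.correlation(val.ssc, ps.predict(model, val.values))
rmsep = ps.rmse(val.ssc, ps.predict(model, val.values))
print(f"validation: RP {rp:.3f}, RMSEP {rmsep:.3f} %")
# RP near 0.93 and RMSEP near 0.55 % SSC: the model recovers the sugar
# signal up to the fruit-to-fruit response variability built into the
# generator.
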