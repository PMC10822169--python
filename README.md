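# jointangles

Marker-less estimation of upper-limb joint angles from depth-camera
skeleton tracking is an attractive basis for tele-rehabilitation: a patient
performs prescribed exercises at home in front of a commodity depth sensor,
and the system scores range of motion without markers, wearables or a
clinician in the room.  Before such a system can be trusted it has to be
validated against marker-based optical motion capture, the clinical gold
standard — and, because per-subject biases remain, calibrated per patient.

`jointangles` implements that validation and calibration pipeline for
shoulder-abduction exercises, together with a forward-kinematic simulator
that reproduces the statistical structure of such paired recordings (the
original participant recordings of this kind of study are typically not
shareable).  It is aimed at biomechanics and rehabilitation-engineering
researchers who want a reproducible, fully synthetic testbed for
agreement-analysis and calibration methodology.

## The angles

For each arm, from a set of tracked keypoints (ears, C7, chest/sternum,
shoulders, elbows, wrists), three angles are computed per frame:

* **α (shoulder abduction)** — angle between the upper-arm vector and the
  body-down direction: 0° with the arm hanging, 90° horizontal.  The arm
  vector originates at a **virtual shoulder joint** that takes the physical
  shoulder's lateral coordinate but the chest marker's height and depth, so
  a marker-based system (markers on the clavicle) and a skeleton tracker
  (joint centers) measure the same quantity.
* **β (elbow extension)** — angle at the elbow between the vectors to the
  shoulder and to the wrist; 180° when fully extended.
* **γ (arm–body transverse angle)** — angle between the arm vector and the
  normal of the subject's frontal plane; 90° while the exercise stays in
  the frontal plane.  This angle isolates the depth (z) axis, the component
  a depth camera contributes beyond an RGB pose estimator.

Frames where the tracker loses a joint (fast motion blurs the depth image)
are repaired by carrying the last valid observation forward (LOCF) before
any angle is computed.

Agreement between the tracker stream (30 fps) and the reference stream
(256 fps, downsampled) is quantified per trial by MAE, RMSE, R² (squared
Pearson correlation), Spearman rank correlation and Bland–Altman-style
difference plots, after cross-correlation synchronization.  Distance and
arm effects are tested with Friedman / Wilcoxon signed-rank tests;
normality of errors with Shapiro–Wilk and Kolmogorov–Smirnov.  Finally a
**personalized calibration** — a univariate regression from tracker α to
reference α fitted separately per subject × exercise × camera distance on
a shuffled 80/20 split — is compared across ten regressor families (OLS,
ridge, lasso, elastic net, linear SVR, decision tree, random forest,
gradient boosting, cubic polynomial, RBF SVR).

## Worked example

Three subjects of the packaged 14-subject cohort, left shoulder abduction
at the three camera distances:

```python
from jointangles.io import RunConfig
from jointangles.pipeline import run_agreement_analysis, calibration_datasets
from jointangles.calibration import run_model_comparison, family_summary

cfg = RunConfig(subjects=["S1", "S2", "S3"], exercises=["SAL"], seed=42)
res = run_agreement_analysis(cfg)
tab = res["table"]
print(tab[tab["angle"] == "alpha"].round(3).to_string(index=False))

grid = run_model_comparison(calibration_datasets(res["pairs"]), global_seed=42)
print(family_summary(grid).round(3).to_string(index=False))
```

prints (abbreviated):

```
angle arm  distance  mae_mean  mae_sd  rmse_mean  r2_mean  spearman_mean
alpha   L       2.0     2.300   0.121      2.760    0.995          0.966
alpha   L       2.5     2.483   0.177      3.092    0.992          0.960
alpha   L       3.5     3.506   0.157      4.510    0.980          0.941

    family  test_mae_mean  baseline_test_mae_mean
        LR          2.496                   2.744
        RR          2.496                   2.744
       LaR          2.496                   2.744
        ER          2.500                   2.744
...
```

Reading this: the shoulder-angle error grows with camera distance (2.30° →
3.51° MAE) while correlation stays high (R² ≥ 0.98) — the tracker follows
the movement but gets noisier farther away.  The four linear calibration
families perform identically (`test_mae_mean` 2.50°) and all ten reduce
error below the uncalibrated baseline (2.74°).  `res["distance_test"]`
holds the Friedman test across distances and `res["normality"]` the
(clearly rejected) normality checks on the errors.

The same pipeline is available from the shell:

```sh
jointangles simulate  --config cfg.yaml --outdir run/
jointangles angles    --config cfg.yaml --outdir run/
jointangles evaluate  --config cfg.yaml --outdir run/
jointangles calibrate --config cfg.yaml --outdir run/
jointangles report    --outdir run/
```

Every stage re-reads the previous stage's CSV outputs, so each emitted
table is re-derivable from stored intermediates, and reruns with the same
config and seed are byte-identical.

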