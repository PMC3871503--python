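# padrbf

Clinical decision support for **femoral peripheral arterial disease (PAD)**
treatment: given 16 clinical features of a patient (age, sex, Fontaine
symptom stage, TASC II lesion type, anesthesia sensitivity, distal runoff
bed, embolism percentage, LDL category, smoking history, hypertension,
blood-pressure stage, diabetes, other peripheral disease history, family
history, current medical treatment), predict whether the treatment decision
is **medical management (−1)** or **surgical/endovascular revascularisation
(+1)**.

The classifier is a Gaussian radial-basis-function network (RBFNN):

- hidden units `Φ_j(x) = exp(−‖x − μ_j‖² / 2σ²)` with centers `μ_j` placed by
  k-means clustering of the training features;
- a single shared variance from the spread heuristic `σ² = η·d²/2`, where `d`
  is the maximum inter-center distance and `η = 0.6` an empirical smoothness
  factor;
- output `y = w₀ + Σ_j w_j Φ_j(x)`, with weights solved in one shot as the
  least-squares / pseudoinverse solution `W = (HᵀH)⁻¹Hᵀy` of the hidden-layer
  design system against the −1/+1 labels;
- a decision cutoff on the rescaled score `p = clip((y+1)/2, 0, 1)`, chosen to
  maximize Youden's J (sensitivity + specificity − 1) on the training ROC.

Around the model sits the full evaluation protocol: stratified 10-fold
cross-validation, a hidden-node-count sweep (2–50) selected by mean
validation MSE, the confusion-matrix indicator suite (accuracy, sensitivity,
specificity, PPV, NPV, F-score, Youden index), trapezoidal ROC/AUC, the
Hosmer–Lemeshow calibration chi-square over deciles of risk, fold summaries
as mean ± SD with 95 % normal-approximation CIs, and two-tailed t-tests for
comparing models indicator-by-indicator at α = 0.05.

The original study cohort (186 single-hospital patient records) is private,
so the package ships a synthetic cohort generator that reproduces its
demographic structure — 114 men aged 53 ± 7 and 72 women aged 58 ± 5, with
89 medical vs 97 surgical decisions — and exposes a single `class_effect`
knob that moves the feature distributions of the surgical class toward
clinical severity, from an exact null (0) to near-separability (1).

## Worked example

```python
import numpy as np

from padrbf import (
    RBFConfig, cross_validate, default_spec, encode_record, generate,
    select_center_count, stratified_kfold, summarize_folds,
)
from padrbf.clinical_data import features_matrix

records = generate(default_spec())                  # 186 synthetic patients
X, y = features_matrix([encode_record(r) for r in records])

plan = stratified_kfold(y, k=10, seed=0)
sweep = select_center_count(X, y, counts=range(2, 51), plan=plan, seed=0)
print(f"selected hidden nodes: {sweep.best_count} "
      f"(CV MSE {min(sweep.mse_per_count):.3f})")

folds = cross_validate(RBFConfig(n_hidden=sweep.best_count, seed=0), X, y, plan)
for name in ("auc", "accuracy", "sensitivity", "specificity"):
    s = summarize_folds([getattr(f, name) for f in folds])
    print(f"{name:12s} {s.mean:.3f} +/- {s.sd:.3f}  "
          f"95% CI {s.ci_low:.3f}-{s.ci_high:.3f}")
```

prints

```
selected hidden nodes: 22 (CV MSE 0.411)
auc          0.951 +/- 0.060  95% CI 0.914-0.989
accuracy     0.876 +/- 0.094  95% CI 0.818-0.935
sensitivity  0.904 +/- 0.094  95% CI 0.846-0.963
specificity  0.843 +/- 0.140  95% CI 0.756-0.930
```

i.e. on the default moderately separable synthetic cohort, the MSE sweep
settles on 22 hidden units and the cross-validated network discriminates
surgical from medical cases with AUC ≈ 0.95; mean accuracy 0.88 means ~16 of
the 186 held-out decisions are misclassified across the 10 validation folds.
(The exact numbers are a pure function of the seeds shown.)

The same workflow is available from the shell:

```
padrbf simulate --out cohort.csv --seed 0
padrbf encode   --records cohort.csv --out features.csv
padrbf sweep    --features features.csv --out sweep.csv --k-min 2 --k-max 50
padrbf evaluate --features features.csv --out-prefix run1 --n-hidden 22
padrbf compare  --a run1_folds.csv --b run2_folds.csv --out comparison.csv
```

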