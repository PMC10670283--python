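# radaug

Dual-level augmentation radiomics for imbalanced tumor grading.

Radiomics models for predicting tumor grade from MRI are routinely built
on small, imbalanced single-center cohorts (on the order of 160 patients
with a ~4:1 low:high-grade ratio), where a pipeline that extracts
thousands of engineered features and then selects a handful is dominated
by selection noise and class imbalance. `radaug` implements and evaluates
a two-level answer:

* **IA — image-level augmentation**: each training case is expanded to
  the original plus 9 MRI-specific perturbed copies (3 random affine
  rotations, 1 elastic deformation, 1 motion ghosting, 1 bias field,
  1 noise, 1 blur, 1 gamma) *before* feature extraction, followed by an
  intraclass-correlation gate (ICC(2,1) ≥ 0.9 across the intensity-op
  replicates) that drops features which do not survive acquisition-style
  perturbation.
* **FA — feature-level augmentation**: SMOTE oversampling of the minority
  class in feature space (5 nearest neighbors, interpolation
  `x_i + u·(x_nbr − x_i)` with `u ~ U(0,1)`) to an exact 1:1 class ratio
  inside each training fold.

Around these sit a full radiomics feature extractor (14 shape features
per sequence plus 18 first-order and 75 texture features — 24 GLCM,
16 GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM — on each of 17 filter images:
1595 features per sequence, 3190 for a two-sequence case), a 7 × 8 × 13 =
728-setting selection/classifier grid, and repeated stratified k-fold
cross-validation scored by the **pooled CV-AUC**

    CV-AUC = AUC( [Prob_1; …; Prob_K], [Label_1; …; Label_K] ),

the single AUC of the concatenated held-out predictions of all K folds of
one repetition — deliberately distinct from the mean of per-fold AUCs,
which is reported alongside, as are sensitivity and specificity at the
Youden-optimal threshold. Four ablation modes (`None`, `FA`, `IA`,
`IAFA`) run on identical fold plans and are compared with DeLong's test,
paired t-tests and a linear trend test.

Because the motivating cohorts are private, the package ships a synthetic
3D phantom generator (`radaug.phantom`): two co-registered "sequences"
per case, ellipsoidal tumors with class-dependent intensity heterogeneity
and margin irregularity, per-case acquisition nuisance (bias field /
gamma / noise level), and counter-based seeding so cohorts are
bit-reproducible. All tests and the acceptance script run on phantoms.

## Worked example

```python
import numpy as np
from radaug import (
    generate_cohort, moderate_ablation_config,
    ablation_config, run_experiment, summarize, trend_test,
)

cohort = generate_cohort(moderate_ablation_config(master_seed=1))   # 48 low-grade : 12 high-grade
results = run_experiment(cohort, ablation_config(seed=1, repetitions=10))

series = {m: [t.cv_auc for t in results[m]] for m in results}
for mode in ("None", "FA", "IA", "IAFA"):
    print(f"{mode:5s} mean CV-AUC {np.mean(series[mode]):.3f}")
print("trend p:", trend_test([series[m] for m in ("None", "FA", "IA", "IAFA")]))
print(summarize(results["IAFA"]))
```

This runs the scaled ablation experiment — a 60-case imbalanced phantom
cohort on 24³ grids, the reduced CHSQ + LASSO + LR setting, 3-fold CV,
10 repetitions per mode — in a few minutes on one CPU and prints (seed 1):

```
None  mean CV-AUC 0.795
FA    mean CV-AUC 0.798
IA    mean CV-AUC 0.754
IAFA  mean CV-AUC 0.763
trend p: 0.026
{"setting": "CHSQ+LASSO+LR", "mode": "IAFA", "best_repetition": 9,
 "best_cv_auc": 0.866, "best_mean_auc": 0.870,
 "best_cv_sensitivity": 0.917, "best_cv_specificity": 0.729,
 "mean_cv_auc": 0.763, "ci95_cv_auc": [0.725, 0.800],
 "range_cv_auc": [0.694, 0.866], "n_repetitions": 10}
```

Two findings worth reading off these numbers. SMOTE tracks the raw
pipeline (`FA ≈ None`) — for a threshold-free metric like AUC,
rebalancing alone buys little, which the motivating clinical study also
observed. And on phantoms of this size the image-augmented modes sit a
few hundredths *below* the raw pipeline: augmentation noise compounds on
top of each case's own acquisition nuisance and attenuates the most
informative features (`docs/methods.md` discusses the decomposition and
the data regime in which the sign flips). On a null phantom (class dials
at zero) all four modes stay at CV-AUC ≈ 0.5 — augmentation manufactures
no signal in either direction.

## Command line

```bash
radaug simulate --seed 1 --out cohort/          # NIfTI volumes + manifest.csv
radaug augment  --manifest cohort/manifest.csv  # 9 augmented copies per case
radaug extract  --manifest cohort/manifest.csv  # features.csv + schema.json
radaug run-cv   --modes None,IAFA --folds 3 --repetitions 10 --out results/
radaug compare  --results results/results.csv   # paired t + trend tests
radaug report   --results results/results.csv   # best trial, mean, 95% CI, range
```

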