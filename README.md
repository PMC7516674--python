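# hypnohrv

Analysis toolkit for **hypnopompic heart-rate variability (HRV)** — the
beat-to-beat cardiac dynamics of the final hour of nocturnal sleep — and
its use in predicting cardiovascular-disease (CVD) outcomes.

Cardiovascular events cluster around the end of sleep and early morning,
a period of surging sympathetic activity. This package implements a full
desk-scale pipeline for studying whether the autonomic signature of that
window carries predictive information:

1. **ECG preprocessing** — zero-phase Butterworth band-pass (0.5–45 Hz),
   Pan–Tompkins R-peak detection, RR-interval computation, local-median
   ectopic/artifact flagging with cubic-spline correction, exclusion of
   recordings with >20 % artifacts, and extraction of the one-hour
   pre-awakening window.
2. **Linear HRV metrics** — SDNN and RMSSD on the full hour; spectral
   powers TP (0.003–0.4 Hz), LF (0.04–0.15 Hz), HF (0.15–0.4 Hz) and
   HFnorm = HF/(LF+HF)×100 per 5-minute segment, averaged over the 12
   segments.
3. **Entropy metrics** — sample entropy SampEn(m=2, r=0.15·SD), its
   multiscale profile MSE1..MSE10 by coarse-graining (tolerance fixed
   from the original series), and the tied-rank **modified permutation
   entropy** (MPE, m=4, base-2), which handles the tied RR values
   produced by finite ECG sampling rates. For m=4 there are 75 tied-rank
   patterns, so 0 ≤ MPE ≤ log₂75 bits.
4. **Cohort statistics** — Lilliefors-gated t / Mann–Whitney group
   comparisons, chi-square for categorical covariates, and two-sample
   Kolmogorov–Smirnov + Jensen–Shannon divergence similarity reports.
5. **Prediction** — 21-entry feature vectors (11 clinical covariates +
   10 HRV metrics: TP, LF, HF, HFnorm, SDNN, RMSSD, MSE1, MSE2, MSE10,
   MPE), under-sampling of the control group with distribution-similarity
   validation, stratified 5-fold cross-validated XGBoost classification,
   the six confusion-matrix measures (ACC, TPR, TNR, PPV, F1, MCC), and
   split-count feature importance.
6. **Synthetic data** — generators for ECG traces, RR tachograms with
   controllable LF/HF oscillatory power and 1/f^β broadband complexity,
   ectopic contamination, and two-group cohorts whose covariates and HRV
   dynamics are shifted the way a CVD-event group differs from controls.
   The entire pipeline is testable without any recorded data.

## Worked example

Simulate a cohort of 40 future-event subjects and 160 controls, compute
features, under-sample controls to 40, and run a 5-fold CV experiment:

```python
from hypnohrv.synthetic import CohortEffectConfig, generate_cohort
from hypnohrv.prediction import build_feature_table, ExperimentConfig, run_experiment

cfg = CohortEffectConfig.study_effects(n_cases=40, n_controls=160, seed=0, duration=900)
features = build_feature_table(generate_cohort(cfg))
result = run_experiment(features, ExperimentConfig(mode="short", k=5, seed=0))
print(result.report.as_frame().round(2))
print(result.importance.head(5).round(3).to_string(index=False))
```

```
            acc    tpr    tnr     ppv      f1   mcc
1-fold   100.00  100.0  100.0  100.00  100.00  1.00
2-fold   100.00  100.0  100.0  100.00  100.00  1.00
3-fold    93.75  100.0   87.5   88.89   94.12  0.88
4-fold   100.00  100.0  100.0  100.00  100.00  1.00
5-fold   100.00  100.0  100.0  100.00  100.00  1.00
average   98.75  100.0   97.5   97.78   98.82  0.98

feature  split_count  relative_importance
     hf        148.0                  0.8
     tp         37.0                  0.2
    bmi          0.0                  0.0
 gender          0.0                  0.0
    age          0.0                  0.0
```

Each fold row gives accuracy, sensitivity, specificity, precision,
F1-score (percent) and the Matthews correlation coefficient on that test
fold; the `average` row is the field-wise mean. The importance table
shows how often each feature was used to split a boosted-tree node,
normalised to sum 1 — here the spectral HF power dominates because the
synthetic case group's respiratory-band oscillation is strongly reduced.
Synthetic effect sizes are deliberately larger than real-cohort
contrasts, so cross-validated accuracies run higher than the ~81 %
reported on clinical data.

The same workflow is available from the shell:

```bash
hypnohrv simulate --out cohort/ --effects study --n-cases 40 --n-controls 160 --duration 900 --seed 0
hypnohrv features --cohort cohort/cohort.tsv --out features.tsv
hypnohrv compare  --features features.tsv --out comparison.tsv
hypnohrv predict  --features features.tsv --mode short --seed 0 --out run
```

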