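# metscreen

A reproducible analysis pipeline for two-group (case–control) metabolomics
cohorts: adaptive univariate screening with a jackknife robustness score,
per-feature ROC/AUC, Fisher-discriminant and logistic-regression panel
classification under leave-one-out cross-validation, and correlation-cluster
decomposition around the winning panel's core features. A synthetic-cohort
generator with known ground truth makes every stage testable without study
data.

## What it does

1. **Cohort model** (`metscreen.cohort`) — participants × features matrices
   with group labels, panel tags and below-detection-limit flags; CSV and
   sheet-per-lab Excel ingestion; BDL imputation (feature minimum / √2);
   nested analysis-subset assembly (targeted panel → +nutritional →
   +genotypes → +top-50 broad features by AUC).
2. **Synthetic cohorts** (`metscreen.synth`) — log-normal abundances driven
   by latent correlated clusters, multiplicative case/control mean-ratio
   effects, orphan (affected-but-independent) features, left-censoring and
   binary genotype columns; fully deterministic per seed.
3. **Univariate screen** (`metscreen.screen`) — per feature: Anderson-Darling
   normality → F-test or median-centered two-sample KS select one of pooled
   t / Welch / Mann-Whitney / Welch-anyway; a leave-k-out resampling "FDR"
   (fraction of recomputed p-values failing the level over every deletion of
   1..k participants); AUC via the Mann-Whitney identity; joint significance
   rule p ≤ α and FDR ≤ 0.1.
4. **Classifiers** (`metscreen.models`) — Fisher discriminant (closed-form
   scatter-inverse direction, unit norm) with a Gaussian-KDE decision
   boundary on the positive-group scores, confidence balanced to equalize
   type I/II errors; maximum-likelihood logistic regression with a ridge
   fallback under separation.
5. **Panel search** (`metscreen.panels`) — exhaustive or beam search over
   feature combinations, each scored by full LOOCV (standardization,
   boundary and balancing re-derived inside every fold — no leakage).
6. **Correlation structure** (`metscreen.correlate`) — Pearson clusters
   around core features over the pooled samples, core–core table, orphan
   detection.

## CLI

```bash
metscreen synth --config gen.yaml --seed 7 --out cohort_dir/
metscreen screen --cohort c.csv --meta features.csv --alpha 0.05 --depths 1,2 --out screen.csv
metscreen search --cohort c.csv --meta features.csv --subset iv --classifier logistic \
                 --sizes 2-5 --strategy beam --out panels.csv
metscreen correlate --cohort c.csv --meta features.csv --cores "f1,f2,f3" --out corr_dir/
metscreen run-all --cohort c.csv --meta features.csv --config run.yaml --out run_dir/
metscreen plot-scores --predictions run_dir/best_panel_predictions.csv --out scores.png
```

`run-all` executes impute → screen → subset assembly → panel search →
correlation decomposition, writing stage CSVs and a reproducibility manifest
(seed, config, input digest, stage outputs); identical seeds reproduce
byte-identical outputs.

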