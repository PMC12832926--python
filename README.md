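# cardiopso

Heart-disease diagnostic pipelines for tabular clinical cohorts: a
robust preprocessing suite, an **improved particle swarm optimizer
(IPSO)** for joint feature selection and classifier hyperparameter
tuning, a clinical diagnostic-accuracy metric panel, a synthetic cohort
generator with planted ground truth, and an experiment harness.

Built for researchers working with the 14-attribute UCI heart-disease
schema (`age, sex, cp, trestbps, chol, restecg, fbs, thalach, exang,
oldpeak, slope, ca, thal, target`), and for anyone who wants a seeded,
auditable wrapper-feature-selection pipeline on small clinical tables.

## What it computes

**Preprocessing** (fixed order, fully logged): forward-fill ("padding")
interpolation of missing cells → exact-duplicate removal → Tukey-fence
outlier imputation by the column median on continuous columns
(fences `Q1 − 1.5·IQR` and `Q3 + 1.5·IQR`) → robust scaling
`(x − median)/IQR`.

**Optimization**: a maximizing PSO over the unit hypercube with two
anti-stagnation improvements — linearly decaying inertia
`w(t) = w_max − (w_max − w_min)·t/T` (0.9 → 0.4) and per-particle
Gaussian mutation (`p = 0.1`, `σ = 0.1`):

```
v ← w(t)·v + c1·r1·(pbest − x) + c2·r2·(gbest − x)
x ← clip(x + v, 0, 1)
```

A particle encodes 13 feature-mask bits plus the hyperparameters of one
of five classifier families (LR, LDA, GNB, SVC, XGBoost); fitness is
the stratified-CV positive-class F1.

**Metrics**: from TP/TN/FP/FN — accuracy, balanced accuracy,
sensitivity (TPR), specificity (TNR), precision (PPV), F1, NPV, MCC,
FNR/FPR/FDR/FOR, informedness and markedness, plus the clinical trio
`LR+ = TPR/FPR`, `LR− = FNR/TNR`, `DOR = LR+/LR− = (TP·TN)/(FP·FN)`.

## Worked example

```python
>>> from cardiopso import ConfusionCounts, metric_panel, likelihood_ratios
>>> c = ConfusionCounts(tp=38, tn=46, fp=3, fn=5)   # a 92-patient held-out split
>>> panel = metric_panel(c)
>>> panel.to_percent(2)
{'accuracy': 91.3, 'balanced_accuracy': 91.12, 'sensitivity': 88.37,
 'specificity': 93.88, 'precision': 92.68, 'f1': 90.48, 'npv': 90.2,
 'mcc': 82.56, 'fnr': 11.63, 'fpr': 6.12, 'fdr': 7.32, 'for_rate': 9.8,
 'bm': 82.25, 'mk': 82.88}
>>> lrs = likelihood_ratios(c)
>>> round(lrs.lr_plus, 2), round(lrs.lr_minus, 4), round(lrs.dor, 2)
(14.43, 0.1239, 116.53)
```

Reading: of 92 test patients the classifier got 91.30% right; a
positive call multiplies the odds of disease ~14-fold (LR+), a negative
call divides them by ~8 (1/LR−), and the diagnostic odds ratio 116.53
summarizes both.

End-to-end on a synthetic cohort:

```python
from cardiopso import (CohortConfig, CorruptionPlan, generate_cohort,
                       corrupt_cohort, run_pipeline, SwarmConfig,
                       ExperimentPlan, run_optimized_grid)

table, truth = generate_cohort(CohortConfig(n_patients=1000, seed=0))
raw, ledger = corrupt_cohort(table, CorruptionPlan(seed=0))
clean, log = run_pipeline(raw)        # log counts match the ledger
plan = ExperimentPlan(ratios=("90:10",), families=("XGB",), mode="ipso")
report = run_optimized_grid(clean, plan, SwarmConfig(n_particles=15, max_iterations=20))
cell = report.cells[0]
print(cell.panel.to_percent(), cell.spec.selected_features, cell.leakage_free)
```

Or from the shell:

```bash
cardiopso simulate --n 1000 --seed 0 --corrupt -o cohort.csv --truth truth.json
cardiopso preprocess --data cohort.csv -o clean.csv --log-out pipeline.json
cardiopso metrics --counts 38 46 3 5
cardiopso tune --family xgb --data clean.csv --split 90:10 --seed 0 -o spec.json
cardiopso experiment --data clean.csv --mode ipso -o report.json
```

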