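# Methods

This note documents the models, procedures and numerical choices behind
`cardiopso`, and what its synthetic-cohort tests do and do not
demonstrate about real clinical data.

## Problem setting

The toolkit targets binary diagnosis of heart disease from the
14-attribute tabular schema shared by the public UCI heart-disease
cohorts (Cleveland, Statlog, Hungarian, Switzerland, Long Beach): five
continuous measurements (age, resting blood pressure `trestbps`, serum
cholesterol `chol`, maximum heart rate `thalach`, exercise ST
depression `oldpeak`), eight integer-coded attributes (`sex`, `cp`,
`restecg`, `fbs`, `exang`, `slope`, `ca`, `thal`) and a binary `target`
(1 = disease present). Real pooled versions of this table suffer three
pathologies that motivate the preprocessing suite: substantial blockwise
missingness (heaviest in `ca`, `thal`, `slope`), a large fraction of
exact duplicate records from pooling overlapping sources, and gross
measurement outliers (e.g. cholesterol entries far outside physiological
range).

## Preprocessing pipeline

Stages run in a fixed order; each stage's counts are recorded in a
`PipelineLog`.

1. **Padding (forward-fill) interpolation.** Each missing cell takes the
   nearest preceding observed value in its column. The method is
   undefined when a column's first value is missing; this raises a
   schema error naming the column rather than guessing. Forward fill is
   deliberately order-dependent; it models the "carry the last
   observation" convention and is exactly reproducible.
2. **Duplicate removal.** Exact row equality across all 14 columns,
   first occurrence kept, order preserved. Comparison happens on
   post-interpolation raw values, before any scaling.
3. **IQR outlier imputation.** Per continuous column, Tukey fences
   `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`; values strictly outside are replaced
   by the column median, computed once on the full pre-replacement
   column (the median always lies inside the fences, so the repaired
   column has no value outside the *input's* fences). Integer-coded
   columns are excluded: quartile fences on category codes are
   meaningless and imputation would corrupt their semantics.

   *Caveat — iterated fencing.* Re-running the imputation re-estimates
   quartiles on the repaired column; when the data's bulk reaches the
   fence (e.g. Gaussian tails), the tightened fence can flag new points,
   so the operation is a fixed point only in the gross-outlier regime
   (bounded bulk, distant spikes) that it is designed for and that the
   corruption model produces.
4. **Robust scaling.** `(x − median) / IQR` per column; the target is
   never scaled; zero-IQR columns are passed through and flagged as
   degenerate. Two fit modes: `whole` fits the scaler on the whole table
   before splitting (the protocol under which the published panels were
   produced), `safe` fits on training rows only and applies the frozen
   parameters to test rows. The experiment harness defaults to `safe` to
   avoid test-set leakage.

**Quartile convention.** All quartiles use linear interpolation between
order statistics ("type 7"), the default of numpy, pandas and R. The
choice matters at small n; it is recorded in the `PipelineLog`.

A two-sided neighbor-interpolation variant of the missing-value stage is
sometimes described alongside forward fill; this package implements the
forward-fill definition only, because it is the one with a
well-defined failure mode (leading missing value) and no dependence on
future rows.

## Diagnostic metrics

All metrics derive from `ConfusionCounts` (TP, TN, FP, FN; positive =
disease). The panel comprises accuracy, balanced accuracy
(= (TPR + TNR)/2), sensitivity, specificity, precision, F1, NPV, MCC,
the four error rates (FNR, FPR, FDR, FOR), bookmaker informedness
(BM = TPR + TNR − 1) and markedness (MK = PPV + NPV − 1). BM and MK use
the standard informedness/markedness definitions.

Clinical meta-analysis uses the likelihood ratios
`LR+ = TPR/FPR`, `LR− = FNR/TNR` and the diagnostic odds ratio
`DOR = LR+/LR−`, which collapses algebraically to `(TP·TN)/(FP·FN)` for
strictly positive counts (property-tested exhaustively on counts 1–10).

Numerical conventions:

* internal arithmetic is full double precision; percentages are rounded
  half-up only at report time (`round_half_up`), matching how printed
  clinical tables are formatted (2 dp for percentages; likelihood
  ratios at 2 dp, LR− at 4 dp);
* undefined ratios (zero denominators) either raise (`error`, default)
  or yield 0 with the metric name flagged (`zero-with-flag`);
* a zero FP or FN cell makes LR+ or DOR infinite; this is reported as
  `inf` with a flag, never silently corrected. The Haldane +0.5
  continuity correction is available behind an explicit switch.

ROC analysis delegates to scikit-learn; the AUC's
probability-of-correct-ranking interpretation (ties = ½) is verified in
tests against an O(n²) pairwise-comparison oracle.

## Improved particle swarm optimization

The engine maximizes an arbitrary fitness over the unit hypercube; all
search spaces are normalized to `[0, 1]` per dimension so one mutation
scale and one velocity clamp apply uniformly to heterogeneous
dimensions. Updates per particle *i*, dimension *d*:

    v ← w(t)·v + c1·r1·(pbest − x) + c2·r2·(gbest − x),   r1, r2 ~ U(0,1)
    x ← clip(x + v, 0, 1)

Two improvements over fixed-inertia PSO:

* **dynamic inertia** `w(t) = w_max − (w_max − w_min)·t/T`, default
  0.9 → 0.4 over 100 iterations;
* **Gaussian mutation**: with probability `p_mutation = 0.1` per
  particle per iteration, every coordinate is perturbed by i.i.d.
  `N(0, σ = 0.1)` and clipped.

Defaults (50 particles, 100 iterations, c1 = c2 = 2.0) are kept across
experiments. Further choices, made where the algorithm statement is
genuinely open:

* *Mutation granularity*: the Bernoulli trial fires once per particle
  per iteration; when it fires, all coordinates are perturbed
  independently. (The alternative — one scalar draw added to every
  coordinate — correlates the move across dimensions and explores less.)
* *r1, r2 per dimension*, the common convention.
* *Boundary handling*: clipping (not reflection/wrapping); velocity
  clamped elementwise to ±0.25 of the unit range.
* *Asynchronous gbest*: improvements found early in a sweep steer
  particles later in the same sweep; ties keep the first-found position.
* *Budget*: exactly `n_particles · (max_iterations + 1)` fitness
  evaluations (initial sweep + per-iteration sweeps); the gbest history
  is elitist, hence non-decreasing.
* *Standard-PSO baseline*: `SwarmConfig.standard_pso()` fixes
  `w = 0.9` and disables mutation. 0.9 is the classic constant-inertia
  setting that linearly decreasing schedules were introduced to
  improve upon; against it, the improved engine wins the paired-seed
  comparison on separable quadratic bowls decisively. (Against an
  aggressively exploitative constant like w = 0.7, a smooth unimodal
  bowl favors the constant — there are no local optima to escape; the
  improvements are aimed at rugged landscapes and are tested for weak
  dominance, not certainty.)

Reproducibility: a single `numpy` generator seeded from `config.seed`
drives initialization, updates and mutation, so identical inputs yield
bit-identical histories.

## Model search

A particle encodes 13 feature-mask bits (≥ 0.5 = selected; an all-off
mask is repaired to its argmax bit) followed by per-family
hyperparameters, decoded affinely — in log10 space for scale
parameters, rounded half-up for integer counts:

| family | dimensions |
|---|---|
| LR  | C ∈ log[1e−3, 1e3] |
| LDA | shrinkage ∈ [0, 1] (lsqr solver) |
| GNB | variance-smoothing exponent ∈ [−12, −3] |
| SVC | C, γ ∈ log[1e−3, 1e3], RBF kernel |
| XGB | trees ∈ [50, 500], depth ∈ [2, 10], learning rate ∈ log[1e−3, 0.5], subsample & colsample ∈ [0.5, 1] |

These ranges are package constants chosen to bracket each library's
default with roughly symmetric headroom on the parameter's natural
scale. Fitness is the mean positive-class F1 over stratified k-fold CV
(default k = 5), computed per fold then averaged (simpler variance
semantics than pooling predictions). Fitness evaluations are memoized
by decoded spec, since integer/mask collisions are common. Learners are
the established scikit-learn/XGBoost implementations with RNGs seeded
from the evaluation protocol.

## Synthetic cohorts

`generate_cohort` draws continuous features from truncated normals
(mid-range mean, range/6 SD, hard-bounded by the schema ranges;
integer-valued attributes rounded), categorical codes uniformly except
`sex` (76% male, the composite cohort's demographic), and the target
from `Bernoulli(sigmoid(b0 + Σ βj·zj + ε))` with z-scored informative
features, `ε ~ N(0, noise_scale)` and `b0` bisected so the mean
predicted probability equals the configured prevalence (default
52.86%). The truth record stores the planted coefficient set.

`corrupt_cohort` injects, in order: gross outliers (written
`magnitude × IQR` beyond the pre-injection Tukey fence, default 3×, so
detection is unambiguous), exact duplicate rows
(`round(fraction · n)` distinct sources copied and appended shuffled;
default fraction 22.69%), and MCAR missing cells (per-column counts
defaulting to the composite cohort's observed per-attribute rates).
Missing cells never land in the first row (forward fill needs a
starting value), nor in duplicated rows or outlier cells — this keeps
duplicate copies bit-identical through interpolation and makes every
planned pathology individually observable, so pipeline-log counts can
be checked against the corruption ledger *exactly* for missingness and
duplicates. Natural truncated-normal tails may add a few genuine
outliers beyond the planned ones, so the outlier-imputation count is
checked as ≥ the planned count.

**What this does not emulate:** the real cohorts' empirical marginals,
feature correlations (features are drawn independently), informative
missingness (real missingness is blockwise by source dataset, not
MCAR), or label noise structure. Passing tests demonstrate the
machinery — bookkeeping, optimization, recovery of planted signal —
not clinical performance on real patients.

## Experiment harness

Grids run family × ratio cells over the splits 70:30, 80:20 and 90:10
at a fixed stratified split seed (default 0, read from the "zero random
states" convention). Optimized cells search the joint space with CV
fitness **on the training portion only**, refit the global-best spec on
the full training portion and score the untouched test rows once. Every
cell stores its train/test row labels; `leakage_free` verifies
disjointness rather than asserting it.

The ablation at 90:10 compares four arms: A = mean imputation +
z-scoring with the default learner; B = the full refinement pipeline
with the default learner; C = A + standard-PSO optimization;
D = B + IPSO (the full framework). Arm A's "basic preprocessing" recipe
is the package's own reading of a conventional baseline.

The paired t-test is the closed form `t = mean(d)/(sd(d)/√n)`,
`df = n − 1`, two-sided p from the t distribution; zero-variance
differences raise rather than return a fabricated statistic. Repeated
splits use seeds `0..repeats−1` (default 10). Selection-frequency
analysis reports the per-feature fraction of runs whose global-best
mask selected it.

## Problem sizes used by the automated checks

The packaged acceptance checks run at desk scale, chosen to exercise
every property while staying quick on one core: restoration at
n = 2,000; selection recovery on a 1,000-patient cohort with 3
informative features (β = 1.2) and 10 decoys over seeded
reduced-budget swarms (LR family, 15 particles × 20 iterations); the
optimized-vs-default comparison on an 800-patient cohort across 10
seeded 90:10 splits with an 8 × 10 swarm and 5-fold CV — a budget at
which the tuned model reliably realizes its advantage (much smaller
search budgets under-train the optimized arm and the comparison
degenerates to split noise). The bowl benchmark runs the full default swarm
(50 × 100) against an equal-budget (5,050-probe) uniform random search.

## Known limitations

* Forward fill is row-order dependent; on shuffled data it is a
  different imputation. It presumes the table's row order is
  meaningful, as it is in pooled source-blocked cohorts.
* Tukey-fence imputation is not idempotent under re-estimated fences
  when the bulk reaches the fence (see above).
* The `whole` scaling mode reproduces a whole-table protocol that leaks
  test-row statistics into the scaler; it exists for comparability and
  is not the default.
* Selected-feature frequencies from a wrapper search are a stability
  diagnostic, not causal importance.
* Binary target only; multiclass disease subtypes are out of scope.
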