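# Methods

## Problem and data model

The task is binary tumour grading: predict GBM (positive) versus LGG
(negative) from 3 clinical predictors (gender, age at diagnosis, race) and
20 binary gene-mutation indicators. Two schemas are supported: the
TCGA-style schema with all 23 predictors and the CGGA-style schema without
race (22 predictors). Input tables arrive as CSV with mutation tokens
`mutated`/`not_mutated`, grades `LGG`/`GBM`, ages as `"<Y> years <D> days"`
strings, and the missing-value sentinels `--` and `not reported`.

Preprocessing removes any row carrying a sentinel in a *clinical* column
(a sentinel in a mutation column raises instead, because the molecular
matrix is assumed complete and silent row loss there would bias mutation
frequencies), converts ages to continuous years with the calendar-average
constant 365.25 days/year, one-hot encodes gender and race with the
lexicographically first level dropped (avoids collinearity for the linear
models), and maps mutations and grades to 0/1.

Age is the only continuous predictor. It is z-score standardised with
mean/SD **fitted on the training fold only** and applied to both splits —
fitting scope is a design choice here, made to prevent information leakage
across the cross-validation boundary. Population SD (`ddof=0`) is used; a
zero SD raises a degenerate-feature error.

## Phase (a): minimum-votes feature selection

Four selectors each produce per-feature importances and binary selected
flags; a feature is kept when it collects at least `min_votes` votes
(default 1). Selection runs inside every training fold. One-hot columns
vote through their source feature: a categorical feature is selected if
any of its dummy columns is, and its importance is the sum over columns,
so votes are counted on the 23 (or 22) schema features.

- **WOE / information value.** Per bin, `WOE = ln(pct_nonevents /
  pct_events)` with GBM as the event. Binary features use their two
  natural bins; age uses 10 quantile bins (tied boundaries merged; bin
  count configurable). Bins with a zero event or non-event count get +0.5
  added to both counts — the log ratio is undefined at zero cells.
  The per-feature importance is the information value
  `IV = Σ (pct_ne − pct_e)·WOE`, which is non-negative because both
  factors of each term share a sign. The vote rule is literal: IV > 0
  (an `iv_threshold` knob exists, default 0). IV is the standard
  single-number companion of WOE; no conventional cutoff (e.g. 0.02) is
  imposed.
- **RFE.** Hand-rolled backward elimination with an L2 logistic regression
  base model: refit, drop the feature with the smallest |coefficient|
  (ties broken by column order — the first minimum is dropped — for
  determinism), repeat until `n_keep` remain. `n_keep` defaults to
  `ceil(p/2)`, a neutral stopping size exposed in the configuration.
  Importance is the elimination rank (survivors share the top value).
- **Random forest.** Mean-decrease-impurity importances from a 100-tree
  Gini forest, normalised to sum to 1; vote iff importance > 0. Impurity
  importances are almost never exactly zero, so this selector's votes are
  near-vacuous under the literal rule; a threshold knob (default 0) allows
  stricter behaviour. This is why the per-fold mean selected-feature count
  on synthetic cohorts sits near the full predictor count at
  `min_votes=1`.
- **LASSO.** Predictors are standardised internally, the response is the
  0/1 grade, and the penalty is chosen by 10-fold cross-validation over
  100 log-spaced values from `λ_max` (the smallest penalty zeroing every
  coefficient, computed from the data) down to `10⁻⁴·λ_max`. Vote iff the
  coefficient at the chosen penalty is nonzero. A single-value grid
  bypasses CV (and `λ = 0` falls back to ordinary least squares), which
  the tests use for closed-form checks.

`min_votes` spans 0–4; the selected set is monotonically shrinking in the
threshold, equals the four-way intersection at 4, and equals "no
selection" at 0. Output ordering is votes-descending with schema order
breaking ties.

## Phase (b): soft-voting ensembles

Base models use library default hyperparameters (KNN: 5 neighbours,
Minkowski metric; SVM: RBF kernel, C = 1, gamma = 'scale'; LR: L2
penalty, C = 1; RF: 100 Gini trees; AdaBoost: 50 rounds, learning rate
1.0) with random state 0 throughout. Two deliberate deviations from bare
defaults, both required for soft voting to exist at all:

- the SVM is wrapped in cross-validated Platt calibration
  (`CalibratedClassifierCV(SVC(...), ensemble=False)`) because an RBF SVM
  has no native class probabilities;
- AdaBoost uses the SAMME boosting variant, the only one current
  scikit-learn provides.

KNN contributes neighbour-class fractions as probabilities. All subsets of
size ≥ 3 of the five models are enumerated in model-registry order within
each size — 16 sets for the canonical five — and each set averages its
members' probability matrices with uniform weights (no weighting, no
stacking, no hard voting). The predicted label is the class with the
larger mean probability; a mean of exactly 0.5 predicts GBM. The tie rule
is measure-zero in practice but fixed for determinism.

## Evaluation

Stratified 10-fold cross-validation (shuffled at the run seed;
stratification keeps per-fold class ratios within one sample and protects
the smaller CGGA-style cohorts from single-class folds). Per fold: fit
age standardisation on train, select features on train, restrict both
splits, fit members, soft-vote on test. Base models are fitted once per
fold and shared across the 16 ensembles, which makes the exhaustive sweep
cheap.

Metrics (GBM positive): ACC = (TP+TN)/n, PRE = TP/(TP+FP),
REC = TP/(TP+FN), SPEC = TN/(TN+FP), F1 = harmonic mean of PRE and REC,
and AUC computed as the Mann–Whitney rank statistic with 0.5 credit for
score ties (equal to trapezoidal ROC integration; cross-checked against
an independent implementation in the tests). A ratio with a zero
denominator is reported as 0 and flagged in the record's warning list.
Reported per-set values are unweighted means over the folds; pooled
confusion aggregation is available as a config option but off by default,
since fold-averaging is the convention for mean performance tables.
Report tables round half-even to 3 decimals and star the best value per
column, ties included.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes: grade drawn
Bernoulli(prevalence); per-gene mutations Bernoulli with class-conditional
rates; age normal per class, truncated at 1 year and emitted in the raw
string dialect; categorical gender/race; optional sentinel injection into
clinical values. The TCGA-like default is 839 samples at prevalence
352/839 with five planted informative genes — IDH1 (0.85 LGG vs 0.10
GBM), TP53 (0.60/0.30), ATRX (0.40/0.12), PTEN and EGFR (0.05/0.30) —
directionally consistent with glioma epidemiology (IDH1/TP53/ATRX enrich
in lower-grade tumours, EGFR/PTEN in glioblastoma), and the remaining 15
genes grade-independent on a geometrically decaying frequency profile.
Ages default to GBM 60 ± 12 and LGG 45 ± 13 years. All rates are invented
round numbers chosen once for structural realism; they are not fitted to
any database, so passing recovery tests demonstrates that the pipeline
detects planted class-conditional signal of these magnitudes — not that
it reproduces real-cohort accuracies, which depend on correlations,
linkage between mutations, and annotation noise the generator does not
model (mutations are drawn independently given grade).

The default TCGA-like parameter set uses `missing_rate = 0` because it
emulates the cohort *after* row removal; sentinel handling is exercised
separately with nonzero rates.

## Problem sizes and numerical choices

Acceptance-level checks run the full 16-set, 10-fold evaluation on one
839-sample cohort, vote recovery over 20 generator seeds, and a
label-permutation null control (20 seeds at n = 400, one ensemble set)
whose mean AUC must sit within 0.5 ± 0.08. These sizes give binomial
standard errors small enough for the stated margins while keeping a full
run in minutes on one CPU. Logistic regressions run up to 1000 iterations
for convergence on standardised inputs; soft-vote permutation invariance
holds to 1e-12 (float summation order), and determinism is byte-exact for
repeated runs at a fixed seed.

## Known limitations

- Real-cohort headline accuracies are out of reach by construction: the
  TCGA/CGGA extracts are not packaged, and the generator makes no attempt
  to match their marginals or inter-gene correlations.
- The literal importance-nonzero vote rule makes the RF (and usually WOE)
  selectors vote for nearly every feature, so at `min_votes = 1` the
  selected set is large; the threshold knobs exist for stricter regimes.
- No class-imbalance correction, no base-model hyperparameter tuning, no
  hard voting or stacking, and no significance testing between ensemble
  sets — all outside the method's scope.
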