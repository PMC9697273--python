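# gliovote

Binary glioma grading — lower-grade glioma (LGG) versus glioblastoma
(GBM) — from a small tabular cohort of clinical features (gender, age at
diagnosis, race) and twenty binary gene-mutation indicators (IDH1, TP53,
ATRX, …, PDGFRA). The package implements a two-phase hierarchical voting
scheme and is aimed at researchers evaluating ensemble feature selection
and soft-voting classifier combinations on TCGA/CGGA-style glioma extracts.

## Method

**Phase (a) — minimum-votes ensemble feature selection.** Four scorers rate
every predictor on the training fold:

- *Weight of evidence*, per bin `WOE = ln(% non-events / % events)` with
  GBM as the event class, summarised per feature by the information value
  `IV = Σ_bins (pct_ne − pct_e)·WOE ≥ 0`;
- *Recursive feature elimination*: repeatedly refit a logistic regression
  and drop the feature with the smallest |coefficient|;
- *Random forest* mean-decrease-impurity importance;
- *LASSO*, `β̂ = argmin ‖y − Xβ‖² + λ‖β‖₁` with λ chosen by 10-fold
  cross-validation over a log-spaced grid.

Each scorer votes for every feature with nonzero importance; a feature
survives when it collects at least `min_votes` votes (default 1).

**Phase (b) — exhaustive soft-voting model selection.** Five base
classifiers (logistic regression, RBF-kernel SVM with Platt-calibrated
probabilities, k-nearest neighbours, random forest, AdaBoost; library
default hyperparameters, fixed random state 0) are combined in every
subset of size 3, 4 or 5 — C(5,3)+C(5,4)+C(5,5) = 16 numbered ensembles.
Each ensemble averages its members' predicted class probabilities with
uniform weights and predicts the class with the larger mean (exact ties go
to GBM).

Everything is evaluated by stratified 10-fold cross-validation with six
metrics (ACC, AUC, F1, precision, recall, specificity; GBM positive).
Age standardisation and feature selection are re-fitted inside each
training fold, so no test-fold information leaks into model fitting.

A synthetic-cohort generator reproduces the data dialect end to end
(class-conditional Bernoulli mutations, grade-dependent age emitted as
`"51 years 108 days"` strings, `--`/`not reported` missing-value
sentinels), so the whole pipeline is testable without cohort downloads.

## Worked example

```
gliovote simulate --n 300 --seed 0 --output cohort.csv
gliovote select   --input cohort.csv --seed 0 --output selection.tsv
gliovote run      --input cohort.csv --sets 9,16 --folds 10 --seed 0 --output-dir out
```

`selection.tsv` lists per-feature importances, per-method votes and the
final selection; on this cohort the age feature earns all four votes
(information value 1.83, the strongest single predictor):

```
feature            WOE_importance  votes  selected
Gender             0.0017          2      1
Age_at_diagnosis   1.8325          4      1
Race               0.0945          4      1
```

`out/metrics_votes.tsv` holds the fold-mean metrics per ensemble set, the
best value per column starred:

```
Set  Models                          ACC     AUC     F1      PRE     REC     SPEC
9    SVM + RF + AdaBoost             0.887   0.957*  0.834   0.872   0.814   0.927
16   LR + SVM + KNN + RF + AdaBoost  0.897*  0.953   0.847*  0.885*  0.823*  0.937*
```

So on this synthetic cohort the five-model ensemble (set 16) grades 89.7%
of patients correctly, well above the 57% majority-class baseline, and
`out/selected_features.tsv` shows a mean of 22.9 of the 23 predictors
surviving selection per fold. `run --no-feature-selection` and
`run --lasso-only` reproduce the ablation tables for the same sets.

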