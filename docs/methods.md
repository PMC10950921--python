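# Methods

## Problem and pipeline

`amlrec` implements a decision-support workflow for adult acute myeloid
leukemia (AML): predict each patient's survival outcome (living / deceased)
from three data modalities — an 11-feature clinical table, a binary
gene-mutation matrix and a continuous gene-expression matrix — and recommend
the treatment-intensity protocol (`target`, `regular`, `low_intensity`,
`high_intensity`) that maximizes the predicted survival probability.

The workflow has six stages:

1. **Cleaning** (`preprocess`): keep adult AML records (diagnosis age ≥ 18,
   bone-marrow blasts ≥ 20%, both inclusive), drop records without a survival
   label, drop non-marrow and non-diagnosis samples, enforce one record per
   patient, binarize race to `is_white` (white ≈ 75% of the cohorts this
   emulates), prune mutation genes with zero events, and fill missing
   clinical cells by 3-nearest-neighbor imputation. Records violating several
   rules are attributed to the first rule in the fixed order; the cleaning
   report records per-rule counts and ids.
2. **Hold-out partitioning** (`modeling.split_holdout`): 70/10/10/10 into
   train / feature-selection / validation / test, each held-out fold of size
   ⌈0.1·n⌉. The feature-selection fold rejoins training after selection by
   default, so n = 272 gives the 216/28/28 training/validation/test split;
   the ensemble refit stage folds validation back into training (9:1).
3. **Feature selection** (`features`): clinical features come from an expert
   list (the 11 curated features); expression features from an L1-penalized
   linear SVM (squared hinge, C = 0.01, columns standardized — the penalty is
   scale-sensitive so a convention is mandatory); mutation features from
   per-gene 2×2 chi-square tests at p < 0.1, strict inequality, no
   continuity correction and no multiple-testing correction.
4. **Model training** (`modeling`): random forest, logistic regression and
   SVM per modality (nine models), each tuned by exhaustive grid search over
   the fixed hyperparameter grids, scored by support-weighted F1 on the
   validation fold, ties resolved by grid order. The deceased class is
   positive throughout.
5. **Ensemble** (`ensemble`): the best model per modality (ties: RF before LR
   before SVM) forms a committee; each member's integer ballot is

       vote(M) = ⌈ 1 / log₁₀(1 / F1(M)) ⌉

   with F1 its validation score. The committee label is the class with the
   larger summed ballot; its survival score is the ballot-weighted mean of
   the members' survival probabilities.
6. **Recommendation** (`recommend`): each patient is re-scored under all four
   protocols (only `treatment_intensity` is intervened on; everything else,
   including ELN risk, is held fixed) and the arg-max protocol is
   recommended, with the margin to the runner-up exposed.

## Numerical conventions and edge cases

- **Vote weights.** The ballot formula is singular at F1 = 1 and undefined at
  F1 = 0; weights are capped (default 100) and F1 = 0 silences a member —
  a model with zero validation F1 carries no evidence. The formula is
  evaluated with a 10⁻¹² snap-to-integer before the ceiling so exact powers
  of ten (F1 = 0.1 → weight exactly 1) do not drift to ⌈x + ε⌉.
- **Ties.** Committee weight-sum ties fall back to the survival score against
  0.5; a score of exactly 0.5 resolves to deceased (the conservative call).
  Protocol-score ties resolve to the earliest protocol in the canonical
  order `target < regular < low_intensity < high_intensity`, i.e. the less
  burdensome option under indifference, and are flagged.
- **Metrics.** ACC, precision, recall, F1 and MCC are computed from the
  confusion counts with deceased positive; the headline aggregate is the
  support-weighted mean of the per-class values (macro and per-class values
  are also emitted). Zero-denominator conventions: precision/recall/F1 = 0
  when undefined, MCC = 0 when a marginal is zero, each logged. AUC is the
  rank statistic (ties count one half); it needs a genuine score, so SVM
  decision values are passed through a logistic link fitted on the
  validation fold.
- **Chi-square.** Pearson statistic without Yates correction, df = 1,
  upper-tail p. A zero marginal returns (0, 1) with a degenerate flag.
- **KNN imputation.** Distances are Euclidean on z-scored numeric features
  plus simple matching (0/1) on categoricals, computed over the clinical
  features that are complete cohort-wide; numeric targets take the neighbor
  mean, categorical targets the neighbor majority with ties broken by the
  cohort-wide modal category. Neighbor-distance ties keep input order
  (stable sort). Fewer than k complete records for a target feature is an
  error naming the feature.
- **Selection fallbacks.** On small feature-selection folds the fixed
  penalties can reject every candidate; the pipeline then relaxes the L1
  penalty tenfold at a time (up to C = 10) until a feature survives, and
  keeps the single smallest-p gene if no mutation clears α. Both fallbacks
  are logged in the pipeline notes.

## Synthetic cohort generator

The generator (`synthetic`) emulates the processed cohort the pipeline
targets, at the published scale: 272 patients by default, the 11-feature
clinical schema, the 22-gene expression panel and 10-gene mutation panel
plus configurable decoy genes (defaults: 100 expression, 40 mutation
decoys — desk-scale stand-ins for the thousands of genes a real cohort
carries).

**Clinical marginals.** Continuous features are drawn by inverse-CDF
truncation so the published ranges hold exactly, with location parameters
solved so the truncated median matches the published median: diagnosis age
~ N(58.4, 15²) on [18, 88]; marrow blasts ~ N(77.5, 25²) on [20, 100];
peripheral blasts ~ N(33.8, 30²) on [0, 99.2]; WBC ~ logN(3.69, 1.1²) on
[0.4, 483] (heavy right tail); mutation count ~ rounded logN(2.21, 0.6²) on
[1, 34]. The published WBC summary prints median 39.44 alongside mean
18.04, which cannot both hold for one sample; the generator targets
min/max/median and leaves the discrepancy documented rather than resolved.
Gender is 55% male, race 75% white, ELN risk 25/50/25
favorable/intermediate/adverse.

**Outcome model.** The binary outcome is drawn from a logistic model on the
deceased log-odds with main effects for age, marrow blasts, log WBC,
mutation burden, gender, ELN risk, the 10 mutation and 22 expression signal
genes, and the protocol, plus protocol×covariate interactions: high-intensity
therapy grows riskier with age, low-intensity is relatively gentler for
older patients, and the targeted protocol's benefit scales with a designated
expression biomarker. Effect sizes were set once so that models trained on
generated cohorts land in the performance regime the published cohort
produced — per-modality F1 roughly 0.6–0.75 with expression the strongest
modality and an outcome rate near 60% deceased. With three *independent*
modality signals the per-modality F1 values cannot all reach the published
levels simultaneously (the signals would need more variance than the outcome
has); the ordering and the ensemble-vs-individual structure are the
emulated properties, not the absolute values. Treatment is assigned at
random by default (an ELN/age-dependent confounded policy is available as a
knob, off by default, because the recommender performs a direct model
intervention without confounding adjustment).

**Ground truth.** For every patient the generative survival probability
under each of the four protocols is stored, along with the arg-max protocol,
enabling parameter-recovery tests of the recommender.

**What the generator does not emulate:** gene–gene correlation, correlation
between modality signals (real clinical risk factors correlate with
mutations and expression), survival *time* (the label is binary), the raw
multi-sample registry structure (exercised only via the small dirty
fixture), and batch effects between source registries. Tests passing on
synthetic cohorts therefore validate the machinery and its statistical
behavior under the stated model, not clinical performance on real data.

## Study conditions for the property suites

Simulation studies are sized to run in minutes on one CPU:

- **Null selection rate:** 20 cohorts of 400 patients × 500 decoy genes with
  permuted labels; the fraction selected at α = 0.1 must sit within 3
  binomial standard errors of 0.1.
- **L1 signal recovery:** 20 cohorts of 400 patients × 200 genes with 5
  planted genes at 1.5 log-odds effect; median recovery must reach 80%
  (C = 0.05 here: at n = 400 the liblinear objective weights the loss by
  C·n, so the cohort-size-appropriate penalty differs from the fixed
  C = 0.01 used at the published scale).
- **Ensemble benefit:** 30 cohorts of 1000 patients; the committee's test F1
  must be within 0.02 of (or above) the best member's in ≥ 80% of seeds.
  Genetic panels are selected on the full feature tables in this study —
  the condition under which the original ensemble-vs-individual comparison
  was produced; fold-based selection degrades the genetic members and tests
  the fold, not the committee. A compact hyperparameter grid (a subset of
  the full grids) keeps the 90-model study tractable.
- **Recommendation recovery:** interaction strengths {1, 2, 3} × 20 cohorts
  of 1200 patients, using a recovery-specific outcome model in which the
  interactions pivot on clinically visible covariates (age, mutation
  burden) and genetic main effects are damped to 30%. This is deliberate:
  the counterfactual sweep intervenes on the clinical table only, so
  genetic members are protocol-constant and an optimum driven by an
  expression biomarker is unrecoverable by construction. Committees are
  random-forest-only here because the sweep needs a member family able to
  represent treatment×covariate interactions; a purely linear clinical
  member assigns every patient the same protocol ordering. Recovery
  accuracy must beat the best single-protocol baseline at the two stronger
  levels and increase monotonically across levels.
- **End-to-end smoke:** the full workflow (complete grids, nine models) at
  the published size n = 272.

## Known limitations

- At n = 272 the held-out test fold has 28 patients, so single-run test
  metrics carry sampling noise of several F1 points; the property suites
  use larger cohorts for that reason.
- The hard weighted vote can be outvoted by two mediocre members against one
  strong one; the ballot formula compresses F1 differences (0.70 → 7 votes,
  0.78 → 10), which bounds how much a dominant member can matter.
- The recommender is a direct model intervention; it inherits any
  confounding present in training data and performs no causal adjustment.
- The L1 selector's solution is non-unique under exactly collinear columns;
  duplicated features share weight arbitrarily.
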