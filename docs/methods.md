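# Methods

This note documents the models and procedures implemented in
`cohortoutliers`, the parameters that matter, the numerical choices
made where the design was genuinely open, and the limits of what the
synthetic benchmarks demonstrate.

## Data model

A cohort is one row per participant with typed columns: continuous
(float, NaN for missing) or categorical (opaque string tokens compared
by exact equality, no level ordering). On disk a cohort is a header-row
CSV in which both the empty field and `NA` mean missing; writing always
encodes missing as the empty field, so read∘write is the identity.
Per-variable metadata (YAML) declares kind, role (`feature`, `outcome`,
`outcome_derived`, `recategorization` with its source, `identifier`),
an optional risk-factor marker, and an optional gate rule for
structured missingness. Exactly one variable carries role `outcome` and
must be binary.

## Variable exclusion

Five rules are evaluated per variable in fixed order, first match wins,
so the exclusion log is unambiguous and row-order invariant:

1. declared variation/sub-categorization of the outcome;
2. missing fraction strictly greater than 0.50 — a variable exactly
   half missing is retained;
3. recategorization of a variable that is itself retained (if the
   source is dropped, the recategorization survives as an ordinary
   feature);
4. exactly one unique observed value;
5. modal value ≥ 99% of *all* rows (missing cells count in the
   denominator, a conservative reading of "of all observations").

The outcome and identifier are never dropped. One deliberate
refinement: rule 2 counts only *genuine* gaps. A cell that an
applicability gate will fill (e.g. cigarettes/day for a non-smoker) is
an answered question, not missing data — otherwise any follow-up
question asked of a minority subgroup would be discarded, defeating the
purpose of the gate fills that run immediately afterwards. Filtering
runs before gate fills and imputation.

## Missing data

Two tiers. First, gate rules fill structurally missing cells: where the
gate variable equals the gating value, a continuous target receives its
numeric sentinel (0 cigarettes/day) and a categorical target a dedicated
new token (`NOT_APPLICABLE`); a fill token colliding with an existing
level is rejected. Remaining gaps are treated as missing at random and
closed by iterated round-robin regression: missing cells are seeded
with the column mean/mode, then each incomplete variable in turn
(visited in order of increasing missingness) is regressed on all other
variables — ordinary least squares for continuous targets, multinomial
logistic regression for categorical targets, categorical predictors
one-hot expanded, continuous predictors standardized for solver
conditioning (predictions are invariant to that affine rescaling). The
cycle repeats for `n_iterations` rounds (default 10) and the final
round's predictions are returned. Observed cells are never modified,
the result contains zero missing cells, and the procedure is
deterministic given its configuration. A variable with no observed
values is a hard error. Imputation is fit on the full table before any
splitting; the (small) train/test leakage this implies is accepted as
part of the single-dataset design, and callers who care can impute per
split by composing the primitives themselves.

## Point outliers (isolation forest)

Features are encoded as a numeric matrix: columns in sorted-name order
— sklearn's tree randomization consumes feature indices, so canonical
ordering is what makes the flags invariant to the order columns appear
in the input file — categorical levels integer-coded lexicographically,
outcome and identifier excluded (the detector is unsupervised; an
`include_outcome` switch exists for users who want the outcome among
the features). The same persisted encoding is reused by the supervised
stage; an unseen level at transform time is a hard error.

Scores are oriented so larger = more anomalous, standardized against
the sample's own mean and SD, and flagged by the inclusive rule
|z| ≥ 3. Contamination (default 0.05) is set on the model as a stated
assumption but plays no part in flagging. If the raw-score SD is ≤ 1e-12
(all rows effectively identical) no outliers are flagged and a warning
is logged. Fixed non-tuned parameters: `bootstrap=False`,
`max_features=1.0`, `warm_start=False`, `random_state` default 2022.

Tuning scans each parameter's increasing grid (defaults: trees
100…1000 step 100 from origin 100; subsamples 256, 512, 700, 1024
capped at n) with the other held fixed, fitting `tuning_replicates`
(default 3) forests per candidate under distinct derived seeds.
"Stops varying" is operationalized as successive relative change below
`tuning_tolerance` (default 0.01) in *both* the score mean and SD; the
smallest qualifying candidate wins, and if none qualifies the largest
is returned with a warning. The per-candidate statistic ledger is
persisted so the choice can be re-derived by scanning it.

## Contextual outliers (random-forest extreme misclassification)

The cohort is partitioned into train/test/validation sets of exact
requested sizes by a seeded permutation (disjoint, exhaustive, split
prevalences logged). Hyperparameters come either from a caller-fixed
configuration or a two-phase search: a random phase sampling
`n_candidates` full configurations without replacement from the
per-dimension candidate lists, then a targeted phase exhaustively
scoring the random winner's immediate grid neighbours one dimension at
a time (so the targeted grid brackets the winner in every searched
dimension). Scoring is F1 on the positive class over the test set —
chosen because the outcome is rare and accuracy would reward the
trivial majority classifier. The full score ledger is persisted and the
returned configuration is its argmax. No class rebalancing is applied
by default: an imbalanced outcome yields the expected poor positive-
class recall, and that asymmetry (more outliers mislabelled as
outcome-absent than outcome-present) is reported rather than corrected.

Vote confidence is computed from per-tree hard predictions: the
fraction of trees voting for each class, summing to 1 by construction.
This is deliberately not `predict_proba`, which averages leaf
probabilities and can differ from the voting definition. The predicted
label is the vote-fraction argmax; an exact 50/50 tie goes to the
lexicographically smaller token (a tie can never be flagged anyway,
since no threshold below 0.5 is accepted). A row is a contextual
outlier iff predicted ≠ recorded AND the predicted class's vote
fraction is strictly greater than the threshold (default 0.90; the
boundary case equal to the threshold is not flagged). Flags are
computed over the entire table by default — in-sample votes are
optimistic, which is accepted because the goal is screening recorded
observations, not estimating generalization error — with a
`holdout_only` switch restricting flags to test+validation rows.
Per-class precision/recall are reportable on any row subset; a metric
with an empty denominator is undefined (NaN), never 0.

## Reporting

Characterization tables contrast the flagged subset with the full
cohort: continuous variables as mean (SD); integer-valued variables
with ≤ 12 distinct levels (gravidity-style counts) as median (IQR);
categorical variables as n (%), one row per level beyond two levels.
Any rendered count between 1 and 6 — subset or cohort side — is
replaced wholesale by `Suppressed`, percentage included, so no rendered
artifact allows recovering a small count; 0 and counts ≥ 7 render.
Case narratives are deterministic given cohort, flags and k: detector
provenance (z-score or vote fraction), declared risk-factor values, and
the top-k (default 5) continuous variables by |robust z|
((x − median)/(1.4826·MAD); MAD-zero variables skipped), which also
seed the editable "interesting variables" list. The assessment field is
born `unreviewed` and only a human changes it; run summaries count
potential-novelty/natural-deviation percentages over reviewed cases
only and report unreviewed cases separately.

## Synthetic cohort generator

The generator emulates the shape of an obstetric trial table: 6
continuous measurements (age 31.4 ± 5.3, weight 91.6 ± 24.8,
BMI 34.0 ± 11.2, last systolic/diastolic pressures, gestational age at
delivery), 5 Poisson counts (gravidity, term/preterm births, abortions,
living children), 11 binary risk factors and supplement indicators at
trial-like prevalences (e.g. chronic hypertension 18.6%, prior
preeclampsia 25.3%, folic acid 81.8%), defaults N = 2,301. All latent
variables share a Gaussian copula with a small set of clinically
motivated correlations (weight–BMI 0.8, SBP–DBP 0.7, age–gravidity 0.4,
…); the hand-set matrix is projected to the nearest positive-definite
correlation matrix if needed. Counts are Poisson quantile transforms of
their latent normals; binaries are threshold indicators.

The outcome is Bernoulli(expit(η)) with η linear in standardized
continuous variables and binary indicators (default log-odds: prior
preeclampsia 1.8, chronic hypertension 1.6, multiple pregnancy 1.0,
SBP 0.9 per SD, aspirin −0.5, …) and the intercept found by Brent
bisection so the cohort-mean probability hits the target prevalence
(default 14.1%; 7.4% fits a birth-cohort-like setting). An unattainable
target within intercept bounds ±30 is a hard error.

Missingness: gate rules blank cigarettes/day and smoking intensity for
non-smokers; MAR gaps hit every other non-protected column with a
probability that is a logistic function of age and weight (themselves
never missing), rescaled to the target average rate (default 5%) — so
the missing-at-random assumption holds exactly in the generator.

Planted truth: point outliers shift 3 randomly chosen continuous
features of randomly chosen rows by ±8 SD (alternating sign);
contextual outliers either flip the recorded outcome of rows in the top
decile of |η| (marginally typical, contextually contradictory) or draw
a hidden binary modifier reversing the odds of carriers and redraw
their outcomes — the modifier is recorded in the truth object, never
the table. Point and contextual truth sets are disjoint, and
everything (ids, mechanism parameters, intercept) is recorded for
recovery testing. Generation is fully reproducible from (spec, seed).

## Benchmark conditions and what they show

Two named benchmark specs freeze the recovery conditions:

* `point_recovery_spec` — n = 1,000, the continuous block only, 5 rows
  shifted 8 SD on 3 of 6 features, no missingness. The isolation
  forest detects marginal extremes; with many additional categorical
  columns the signal of a 3-feature extreme is diluted across split
  dimensions (a known masking regime), so the benchmark isolates the
  regime the detector is built for. Expectation: all planted rows in
  the top 1% by |z| in ≥ 9 of 10 seeds.
* `contextual_recovery_spec` — n = 3,000, the full mixed-type roster,
  coefficients scaled ×3 so the outcome is nearly deterministic given
  the features, 30 label flips (1%) in the top |η| decile, no
  missingness. Strong coefficients are what make a flipped label a
  *contradiction* rather than plausible noise: with the milder default
  mechanism, naturally unlucky draws (p ≈ 0.05 rows that drew the
  outcome anyway) are confidently mislabelled by any well-calibrated
  model and would dominate the flag set. The benchmark forest
  (`RECOVERY_FOREST_PARAMS`: 500 trees, depth 10, min leaf 5, sqrt
  features, no bootstrap) is deliberately smooth so trees generalize
  the mechanism instead of memorizing the planted flips in the training
  split. Expectation: median recall ≥ 0.6 and precision ≥ 0.5 at the
  strict 0.90 threshold over 10 seeds; in practice both run well above.

The benchmarks show the detectors recover the anomaly types they
target under a known mechanism; they do not show that real cohorts'
outliers are of these types, that the ×3 mechanism's near-determinism
holds in real outcomes (it mostly will not, so real precision will be
lower), or anything about the clinical value of a flag — that is the
human reviewer's question by design. The generator also omits
longitudinal measurements (serial blood pressures, laboratory series),
informative-missingness beyond the gate mechanism, and measurement
error in the outcome other than the planted contradictions.

## Pipeline, seeds, determinism

The pipeline runs one dataset at a time — a configuration listing
multiple datasets to pool is rejected. A master seed derives per-stage
seeds (synthetic / imputation / split / search / forest) as the first
four bytes of SHA-256("master:stage") mod 2³¹; the isolation forest
keeps its conventional fixed random state (2022) unless overridden.
The manifest records the config snapshot, all stage seeds, per-stage
row/column/flag counts, chosen hyperparameters and SHA-256 digests of
every output file; manifests contain no timestamps, so two runs with
the same config and master seed are byte-identical, manifest included.
Problem sizes in the shipped benchmarks (n = 1,000/3,000, 10 seeds,
2,301-row pipeline runs) were chosen so the full validation suite
completes in a few minutes on a single CPU while keeping every rate
estimated from ≥ 10⁴ simulated rows.

## Known limitations

* Single imputation only; no pooling across imputations, so downstream
  variance estimates (not produced here) would be optimistic.
* Full-dataset flagging means in-sample vote fractions; the
  `holdout_only` switch trades coverage for honesty.
* The two-phase search scores on a single test split (no CV), matching
  the pipeline's fixed-split design; with rare outcomes the selected
  configuration is noisy.
* Integer coding of categorical levels imposes an artificial order
  inside tree splits; with the shipped two-to-three-level variables the
  effect is negligible, but high-cardinality nominals would deserve a
  different encoding.
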