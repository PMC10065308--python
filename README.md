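# cohortoutliers

Outlier analysis for clinical cohort tables, aimed at *clinical
discovery*: instead of cleaning outliers away, the pipeline surfaces the
participants most worth a clinician's second look. It was designed
around hypertensive disorders of pregnancy (preeclampsia and related
outcomes) but works on any one-row-per-participant table with a binary
outcome.

Two complementary detectors are provided:

* **Point outliers — isolation forest.** An isolation forest assigns
  every participant an anomaly score (the ensemble-averaged, normalized
  path length needed to isolate the row). Scores are standardized
  within the sample and a participant is flagged when the z-score of
  their anomaly score satisfies the inclusive two-sided rule
  *z ≤ −3 or z ≥ 3*. The contamination parameter (default 0.05) is
  passed to the model only as the assumed upper bound on the outlier
  fraction; flags come from the z rule, never from the model's internal
  quantile cutoff. Hyperparameters (`n_estimators`, `max_samples`) can
  be tuned by a stabilization scan starting at 100 trees / 256
  subsamples: the first candidate beyond which the score mean and SD
  stop changing (relative change below a tolerance) is chosen.

* **Contextual outliers — random-forest extreme misclassification.** A
  random forest is trained to predict the recorded outcome
  (train/test/validation split; hyperparameters via random search then
  a targeted grid around the winner). The confidence of a prediction is
  the *vote fraction*: the proportion of base trees whose hard
  prediction is that class (not averaged leaf probabilities). A
  participant is flagged when the model *mislabels* them with vote
  fraction strictly greater than 0.90 — their features are individually
  ordinary, but their recorded outcome contradicts the pattern the
  model learned, which is exactly where an unmeasured mechanism may be
  hiding.

Around the detectors sit the supporting stages a real cohort needs:
five variable-exclusion rules (outcome-derived variables, >50% missing,
recategorizations of retained variables, constants, 99% near-constants),
two-tier missing-data handling (structured "not applicable" fills via
gate rules, then 10 rounds of round-robin regression imputation),
reviewer-facing characterization tables with small-cell suppression
(counts of 1–6 are never rendered), structured case narratives, and a
synthetic pregnancy-cohort generator with planted ground-truth outliers
so every stage is testable without access to any real trial data.

The final judgment — whether a flagged case is a *potential novelty* or
a *natural deviation* — is deliberately left to a human reviewer; the
package generates the evidence, not the verdict.

## Worked example

```python
from cohortoutliers import (IsolationConfig, detect_point_outliers,
                            generate_cohort, point_recovery_spec)

table, _, truth = generate_cohort(point_recovery_spec(n_rows=1000, n_outliers=5, seed=2022))
result, _ = detect_point_outliers(table, IsolationConfig(n_estimators=300, max_samples=256))
ranks = result.frame["z_score"].abs().rank(ascending=False)
print({p: int(ranks[p]) for p in truth.point_outlier_ids})
```

prints

```
{'P00180': 2, 'P00418': 1, 'P00560': 4, 'P00604': 3, 'P00698': 5}
```

— the five rows planted at 8 SD on three measurements occupy the top
five ranks by |z| and all are flagged by the z-rule. The contextual
detector is exercised the same way (`examples/detect_contextual_outliers.py`):
on a 3,000-row cohort with 30 label-flipped extreme-log-odds rows it
reports

```
flagged 39 rows; 30 were planted label flips
recall 0.87, precision 0.67
```

meaning 26 of the 30 planted contradictions were recovered at the
strict >0.90 vote threshold, and two thirds of everything flagged was a
genuine plant.

Each script in `examples/` is a short narrative of one capability:
simulation, preprocessing, both detectors, and the full pipeline. The
command-line interface mirrors the library:

```sh
cohort-outliers simulate --seed 7 --n-rows 2301 --out cohort.csv
cohort-outliers run --config config.yml --out run/
```

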