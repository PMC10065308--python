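"""Contextual outliers by random-forest extreme misclassification.

Thirty rows with extreme outcome log-odds have their recorded outcome
flipped: marginally they look typical, but their label contradicts the
learnable outcome mechanism.  A random forest is trained on the split
cohort and every row the model mislabels with a hard-vote fraction
strictly above 0.90 is flagged.
"""

from cohortoutliers import SplitSpec, contextual_recovery_spec, detect_contextual_outliers, generate_cohort
from cohortoutliers.synthetic import RECOVERY_FOREST_PARAMS

table, _, truth = generate_cohort(contextual_recovery_spec(n_rows=3000, n_flipped=30, seed=2022))
result, _, model = detect_contextual_outliers(
    table,
    SplitSpec(train_n=1560, test_n=1050, validation_n=390, seed=2022),
    fixed_params=RECOVERY_FOREST_PARAMS,
    threshold=0.90,
    seed=2022,
)

flagged = set(result.outlier_ids)
planted = set(truth.contextual_outlier_ids)
hit = flagged & planted
print(f"flagged {len(flagged)} rows; {len(planted)} were planted label flips")
print(f"recall {len(hit) / len(planted):.2f}, precision {len(hit) / len(flagged):.2f}")
worst = result.frame[result.frame.is_outlier].nlargest(3, "vote_fraction")
print("most confident mislabels:")
print(worst[["true_label", "predicted_label", "vote_fraction"]])
# A flagged row is one whose recorded outcome nearly every tree
# contradicts — in a real cohort, a candidate for expert case review.
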