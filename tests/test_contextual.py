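"""Random-forest extreme-misclassification stage."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from cohortoutliers import (
    ForestSearchSpec,
    SplitSpec,
    classification_report,
    contextual_recovery_spec,
    encode_features,
    flag_extreme_misclassification,
    generate_cohort,
    search_hyperparameters,
    split_dataset,
    vote_confidence,
)
from cohortoutliers.contextual import MisclassificationResult
from cohortoutliers.synthetic import RECOVERY_FOREST_PARAMS
from conftest import make_table


@pytest.fixture(scope="module")
def small_cohort():
    table, _, truth = generate_cohort(contextual_recovery_spec(n_rows=400, n_flipped=4, seed=5))
    return table, truth


@pytest.fixture(scope="module")
def fitted(small_cohort):
    table, _ = small_cohort
    x, enc = encode_features(table)
    y = table.data[table.outcome.column].astype(str).to_numpy(object)
    model = RandomForestClassifier(n_estimators=50, random_state=0, **{
        k: v for k, v in RECOVERY_FOREST_PARAMS.items() if k != "n_estimators"}).fit(x, y)
    return table, x, enc, model


class TestSplit:
    @pytest.mark.parametrize("n,sizes", [(2301, (1200, 800, 301)), (8085, (3600, 2400, 2085))])
    def test_study_split_sizes_exact(self, n, sizes):
        t = make_table({"x": list(np.arange(n, dtype=float)),
                        "out": ["yes", "no"] * (n // 2) + ["no"] * (n % 2)},
                       outcome="out")
        s = split_dataset(t, SplitSpec(*sizes, seed=1))
        assert (len(s.train_idx), len(s.test_idx), len(s.validation_idx)) == sizes
        allidx = np.concatenate([s.train_idx, s.test_idx, s.validation_idx])
        assert len(np.unique(allidx)) == n  # disjoint and exhaustive

    def test_same_seed_reproduces_partition(self, small_cohort):
        table, _ = small_cohort
        a = split_dataset(table, SplitSpec(200, 120, 80, seed=3))
        b = split_dataset(table, SplitSpec(200, 120, 80, seed=3))
        assert np.array_equal(a.train_idx, b.train_idx)
        assert np.array_equal(a.validation_idx, b.validation_idx)

    def test_sizes_must_sum_to_n(self, small_cohort):
        table, _ = small_cohort
        with pytest.raises(ValueError, match="sum"):
            split_dataset(table, SplitSpec(100, 100, 100, seed=0))


class TestVoteConfidence:
    def test_fractions_match_per_tree_loop_exactly(self, fitted):
        table, x, enc, model = fitted
        frac = vote_confidence(model, x).to_numpy()
        classes = list(model.classes_)
        for i in range(len(x)):  # brute-force per-tree tally
            votes = [classes[int(tree.predict(x[i : i + 1])[0])] for tree in model.estimators_]
            for k, c in enumerate(classes):
                assert frac[i, k] == votes.count(c) / len(votes)

    def test_fractions_sum_to_one(self, fitted):
        _, x, _, model = fitted
        assert np.allclose(vote_confidence(model, x).sum(axis=1), 1.0)

    def test_unanimous_vote_is_one(self):
        x = np.array([[0.0], [0.0], [10.0], [10.0]] * 10)
        y = np.array(["a", "a", "b", "b"] * 10, dtype=object)
        model = RandomForestClassifier(n_estimators=25, random_state=0).fit(x, y)
        frac = vote_confidence(model, np.array([[0.0], [10.0]]))
        assert frac.loc[0, "a"] == 1.0 and frac.loc[1, "b"] == 1.0


def _result_from(fracs_wrong, threshold=0.90):
    """MisclassificationResult built directly from wrong-class vote fractions."""
    frame = pd.DataFrame({
        "true_label": ["no"] * len(fracs_wrong),
        "predicted_label": ["yes"] * len(fracs_wrong),
        "vote_fraction": fracs_wrong,
    })
    frame["is_outlier"] = (frame.predicted_label != frame.true_label) & (
        frame.vote_fraction > threshold)
    return frame


class TestFlagRule:
    def test_wrong_with_095_flagged_exactly_090_not(self, fitted):
        table, x, enc, model = fitted
        res = flag_extreme_misclassification(model, table, enc, threshold=0.90)
        fr = res.frame
        wrong = fr.predicted_label != fr.true_label
        assert (fr.is_outlier == (wrong & (fr.vote_fraction > 0.90))).all()
        # boundary semantics on constructed fractions
        frame = _result_from([0.90, 0.95, 0.9000001])
        assert list(frame.is_outlier) == [False, True, True]

    def test_correct_prediction_never_flagged(self, fitted):
        table, x, enc, model = fitted
        res = flag_extreme_misclassification(model, table, enc, threshold=0.51)
        fr = res.frame
        assert not fr.loc[fr.predicted_label == fr.true_label, "is_outlier"].any()

    def test_threshold_monotonicity(self, fitted):
        table, x, enc, model = fitted
        prev = None
        for thr in (0.55, 0.7, 0.8, 0.9, 0.95, 1.0):
            ids = set(flag_extreme_misclassification(model, table, enc, threshold=thr).outlier_ids)
            if prev is not None:
                assert ids <= prev
            prev = ids

    def test_flags_subset_of_misclassified(self, fitted):
        table, x, enc, model = fitted
        res = flag_extreme_misclassification(model, table, enc)
        fr = res.frame
        assert set(res.outlier_ids) <= set(fr.index[fr.predicted_label != fr.true_label])

    def test_threshold_out_of_range_rejected(self, fitted):
        table, x, enc, model = fitted
        for bad in (0.5, 0.2, 1.1):
            with pytest.raises(ValueError):
                flag_extreme_misclassification(model, table, enc, threshold=bad)


class TestSearch:
    def test_degenerate_single_point_space(self, small_cohort):
        table, _ = small_cohort
        x, _ = encode_features(table)
        y = table.data[table.outcome.column].to_numpy(object)
        spec = ForestSearchSpec(
            n_candidates=5,
            distributions={"n_estimators": [50], "max_depth": [5]},
            seed=0,
        )
        res = search_hyperparameters(x[:300], y[:300], x[300:], y[300:], spec,
                                     positive_label="yes")
        assert res.best_params == {"n_estimators": 50, "max_depth": 5}

    def test_winner_is_argmax_of_persisted_ledger(self, small_cohort):
        table, _ = small_cohort
        x, _ = encode_features(table)
        y = table.data[table.outcome.column].to_numpy(object)
        spec = ForestSearchSpec(
            n_candidates=6,
            distributions={
                "n_estimators": [25, 50],
                "max_depth": [3, 6, 10],
                "min_samples_leaf": [2, 5],
            },
            seed=1,
        )
        res = search_hyperparameters(x[:300], y[:300], x[300:], y[300:], spec,
                                     positive_label="yes")
        led = res.ledger
        best = led.loc[led["score"].idxmax()]
        assert best["score"] == led["score"].max()
        dims = ["n_estimators", "max_depth", "min_samples_leaf"]
        assert {d: res.best_params[d] for d in dims} == {d: best[d] for d in dims}
        # the targeted grid brackets the random-phase winner in every dimension
        random_best = led[led.phase == "random"].loc[lambda d: d["score"].idxmax()]
        targeted = led[led.phase == "targeted"]
        for d in dims:
            assert random_best[d] in set(targeted[d])

    def test_single_class_training_outcome_is_error(self):
        x = np.random.default_rng(0).normal(size=(30, 2))
        y = np.array(["no"] * 30, dtype=object)
        with pytest.raises(ValueError, match="single-class"):
            search_hyperparameters(x, y, x, y, ForestSearchSpec(n_candidates=2))


class TestClassificationReport:
    def _result(self, true, pred):
        frame = pd.DataFrame({
            "true_label": true, "predicted_label": pred,
            "vote_fraction": [1.0] * len(true),
            "is_outlier": [False] * len(true),
        }, index=pd.Index([f"r{i}" for i in range(len(true))], name="participant_id"))
        return MisclassificationResult(frame=frame, threshold=0.9, params={})

    def test_perfect_predictions(self):
        r = self._result(["a", "b", "a"], ["a", "b", "a"])
        rep = classification_report(r)
        assert (rep["precision"] == 1.0).all() and (rep["recall"] == 1.0).all()

    def test_hand_confusion_counts(self):
        # positive class: TP=3, FP=1, FN=2 -> precision .75, recall .6
        true = ["p", "p", "p", "p", "p", "n", "n", "n"]
        pred = ["p", "p", "p", "n", "n", "p", "n", "n"]
        rep = classification_report(self._result(true, pred))
        assert rep.loc["p", "precision"] == pytest.approx(0.75)
        assert rep.loc["p", "recall"] == pytest.approx(0.6)

    def test_absent_class_metric_is_undefined_not_zero(self):
        r = self._result(["n", "n", "p"], ["n", "n", "p"])
        rep = classification_report(r, subset=["r0", "r1"])
        assert np.isnan(rep.loc["p", "recall"]) if "p" in rep.index else "p" not in rep.index
        # the positive class simply does not appear in the subset report
        assert "p" not in rep.index

    def test_never_predicted_class_precision_undefined(self):
        rep = classification_report(self._result(["p", "n"], ["n", "n"]))
        assert np.isnan(rep.loc["p", "precision"])
        assert rep.loc["p", "recall"] == 0.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classification_report(self._result(["a"], ["a"]), subset=[])
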