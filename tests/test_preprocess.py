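"""Exclusion rules, gated fills and round-robin imputation."""

import numpy as np
import pandas as pd
import pytest

from cohortoutliers import (
    CohortError,
    ImputationConfig,
    VariableMetadata,
    apply_gate_fills,
    filter_variables,
    impute_iterative,
)
from cohortoutliers.io import NotApplicableRule
from conftest import make_table


def _ladder(n, miss_frac):
    """Continuous column with the requested missing fraction, varying values."""
    k = int(round(n * miss_frac))
    return [np.nan] * k + [float(i) for i in range(n - k)]


@pytest.fixture
def crafted_table():
    """12-variable fixture exercising every exclusion rule and boundary."""
    n = 1000
    rng = np.random.default_rng(42)
    cols = {
        "age": rng.normal(30, 5, n).tolist(),                     # retained
        "weight": rng.normal(80, 10, n).tolist(),                 # retained
        "severity_score": rng.normal(0, 1, n).tolist(),           # rule 1 (declared)
        "mostly_missing": _ladder(n, 0.60),                       # rule 2
        "half_missing": _ladder(n, 0.50),                         # exactly 50%: retained
        "age_group": (["young"] * 500 + ["old"] * 500),           # rule 3 (age retained)
        "weight_group_src_gone": ["a"] * 600 + ["b"] * 400,       # recat of dropped var: retained
        "death": [0.0] * n,                                       # rule 4
        "near_constant": [1.0] * 995 + [2.0] * 5,                 # rule 5 (99.5%)
        "not_quite_constant": [1.0] * 985 + [2.0] * 15,           # 98.5%: retained
        "also_missing_and_derived": _ladder(n, 0.70),             # rules 1+2: rule 1 wins
        "outcome": (["yes"] * 140 + ["no"] * 860),                # never dropped
    }
    meta = {
        "severity_score": ("continuous", "outcome_derived"),
        "age_group": VariableMetadata("age_group", "categorical", role="recategorization",
                                      recategorization_of="age"),
        "weight_group_src_gone": VariableMetadata(
            "weight_group_src_gone", "categorical", role="recategorization",
            recategorization_of="mostly_missing"),
        "also_missing_and_derived": ("continuous", "outcome_derived"),
    }
    return make_table(cols, metadata=meta, outcome="outcome")


class TestFilterRules:
    def test_exactly_the_violating_variables_drop(self, crafted_table):
        _, log = filter_variables(crafted_table)
        assert dict((v, r) for v, r, _ in log.entries) == {
            "severity_score": 1,
            "mostly_missing": 2,
            "age_group": 3,
            "death": 4,
            "near_constant": 5,
            "also_missing_and_derived": 1,
        }

    def test_each_dropped_variable_logged_once_with_first_rule(self, crafted_table):
        _, log = filter_variables(crafted_table)
        names = log.dropped()
        assert len(names) == len(set(names))
        # a variable that is both outcome-derived and >50% missing logs rule 1
        assert ("also_missing_and_derived", 1) in [(v, r) for v, r, _ in log.entries]

    def test_boundaries_are_strict_and_inclusive(self, crafted_table):
        reduced, _ = filter_variables(crafted_table)
        assert "half_missing" in reduced.columns          # missing > 0.50 strict
        assert "not_quite_constant" in reduced.columns    # dominance >= 0.99 inclusive
        assert "weight_group_src_gone" in reduced.columns # source itself dropped

    def test_outcome_never_dropped_even_if_constant(self):
        t = make_table({"x": [1.0, 2.0, 3.0], "outcome": ["no", "no", "no"]},
                       outcome="outcome")
        reduced, log = filter_variables(t)
        assert "outcome" in reduced.columns
        assert "outcome" not in log.dropped()

    def test_row_order_does_not_change_decisions(self, crafted_table):
        _, log1 = filter_variables(crafted_table)
        shuffled = crafted_table.copy()
        perm = np.random.default_rng(7).permutation(len(shuffled.data))
        shuffled.data = shuffled.data.iloc[perm]
        _, log2 = filter_variables(shuffled)
        assert sorted(log1.entries, key=str) == sorted(log2.entries, key=str)


class TestGateFills:
    def _table(self):
        meta = {
            "cigs": VariableMetadata("cigs", "continuous",
                                     gate=NotApplicableRule("smoker", "no", 0.0)),
            "intensity": VariableMetadata("intensity", "categorical",
                                          gate=NotApplicableRule("smoker", "no", "NOT_APPLICABLE")),
        }
        return make_table(
            {
                "smoker": ["no", "yes", "no", "yes"],
                "cigs": [np.nan, np.nan, np.nan, 15.0],
                "intensity": [np.nan, "heavy", np.nan, np.nan],
            },
            metadata=meta,
        )

    def test_non_smoker_gets_zero(self):
        out = apply_gate_fills(self._table())
        assert out.data.loc["r0", "cigs"] == 0.0
        assert out.data.loc["r2", "cigs"] == 0.0

    def test_categorical_gets_new_token(self):
        out = apply_gate_fills(self._table())
        assert out.data.loc["r0", "intensity"] == "NOT_APPLICABLE"

    def test_smoker_with_missing_stays_missing(self):
        out = apply_gate_fills(self._table())
        assert np.isnan(out.data.loc["r1", "cigs"])        # goes to imputation
        assert pd.isna(out.data.loc["r3", "intensity"])

    def test_gate_referencing_absent_variable_is_hard_error(self):
        t = self._table().drop_columns(["smoker"])
        with pytest.raises(CohortError, match="smoker"):
            apply_gate_fills(t)

    def test_fill_token_colliding_with_existing_level_rejected(self):
        meta = {"q": VariableMetadata("q", "categorical",
                                      gate=NotApplicableRule("g", "no", "heavy"))}
        t = make_table({"g": ["no", "yes"], "q": [np.nan, "heavy"]}, metadata=meta)
        with pytest.raises(CohortError, match="heavy"):
            apply_gate_fills(t)


class TestImputation:
    def test_complete_table_returned_unchanged(self):
        t = make_table({"x": [1.0, 2.0], "y": [3.0, 4.0]})
        out = impute_iterative(t, ImputationConfig())
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_observed_cells_preserved_and_no_missing_left(self, rng):
        n = 60
        cols = {
            "a": np.where(rng.random(n) < 0.2, np.nan, rng.normal(0, 1, n)),
            "b": rng.normal(5, 2, n),
            "c": np.where(rng.random(n) < 0.3, np.nan, rng.normal(-2, 1, n)),
        }
        t = make_table({k: list(v) for k, v in cols.items()})
        before = t.data.copy()
        out = impute_iterative(t, ImputationConfig(n_iterations=10))
        assert out.n_missing() == 0
        obs = before.notna()
        for col in before.columns:
            pd.testing.assert_series_equal(
                out.data.loc[obs[col], col], before.loc[obs[col], col])

    def test_linear_relation_recovered_within_1e6(self):
        """y = 2x exactly on 19 complete rows; the held-out y must come
        back as the least-squares fit (2x) to within 1e-6."""
        x = [float(i) for i in range(20)]
        y = [2.0 * v for v in x]
        y[7] = np.nan
        t = make_table({"x": x, "y": y})
        out = impute_iterative(t, ImputationConfig(n_iterations=10))
        assert out.data.loc["r7", "y"] == pytest.approx(14.0, abs=1e-6)

    def test_majority_class_imputed_without_signal(self):
        """A categorical column 90% level 'A' with noise predictors imputes
        to 'A' in >= 80% of seeded runs (multinomial majority behavior)."""
        rng = np.random.default_rng(3)
        n = 50
        hits = 0
        runs = 50
        for seed in range(runs):
            r = np.random.default_rng(seed)
            lab = ["A"] * 36 + ["B"] * 4 + [np.nan] * 10
            t = make_table({
                "noise1": list(r.normal(size=n)),
                "noise2": list(r.normal(size=n)),
                "cat": lab,
            })
            out = impute_iterative(t, ImputationConfig(seed=seed))
            hits += (out.data["cat"].iloc[40:] == "A").mean() == 1.0
        assert hits / runs >= 0.8

    def test_all_missing_variable_is_hard_error(self):
        t = make_table({"x": [1.0, 2.0], "y": [np.nan, np.nan]})
        with pytest.raises(CohortError, match="zero observed"):
            impute_iterative(t, ImputationConfig())

    def test_reproducible_given_config(self, rng):
        n = 40
        vals = np.where(rng.random(n) < 0.25, np.nan, rng.normal(0, 1, n))
        t1 = make_table({"a": list(vals), "b": list(rng.normal(size=n))})
        t2 = t1.copy()
        o1 = impute_iterative(t1, ImputationConfig(seed=11))
        o2 = impute_iterative(t2, ImputationConfig(seed=11))
        pd.testing.assert_frame_equal(o1.data, o2.data)


def test_gated_structural_missingness_not_counted_by_missing_rule():
    """A question gated off for most participants is retained: its
    structurally missing cells are answered by the gate, so the >50%
    missing-data rule sees only genuine gaps."""
    meta = {
        "cigs": VariableMetadata("cigs", "continuous",
                                 gate=NotApplicableRule("smoker", "no", 0.0)),
    }
    n = 100
    t = make_table(
        {
            "smoker": ["no"] * 62 + ["yes"] * 38,
            "cigs": [np.nan] * 62 + [float(5 + i % 20) for i in range(38)],
            "age": list(np.linspace(20, 40, n)),
            "out": ["yes", "no"] * 50,
        },
        metadata=meta, outcome="out",
    )
    reduced, log = filter_variables(t)
    assert "cigs" in reduced.columns
    assert "cigs" not in log.dropped()
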