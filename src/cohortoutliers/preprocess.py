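"""Variable exclusion and two-tier missing-data handling.

Five exclusion rules are applied to every candidate variable, in fixed
order with first match winning, so the exclusion log is unambiguous:

1. the variable is a variation/sub-categorization of the outcome
   (declared role ``outcome_derived``);
2. more than 50% of its cells are missing (strictly greater);
3. it re-categorizes another variable that is itself retained;
4. it has exactly one unique non-missing value;
5. a single value accounts for >= 99% of all observations (missing
   cells count in the denominator).

The outcome and identifier are never dropped.

Missingness is then handled in two tiers.  Structurally missing cells —
questions never asked because an upstream gate answer made them not
applicable — are filled with the gate rule's sentinel (e.g. zero
cigarettes/day for non-smokers, or a dedicated category token).  All
remaining gaps are treated as missing at random and imputed by
iterated round-robin regression: each incomplete variable is regressed
in turn on all others (linear regression for continuous targets,
multinomial logistic for categorical ones, categorical predictors
one-hot expanded), missing cells are replaced by predictions, and the
cycle repeats for a fixed number of rounds (default 10); the result of
the final round is returned.  Observed cells are never altered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression

from .io import (
    KIND_CATEGORICAL,
    KIND_CONTINUOUS,
    ROLE_IDENTIFIER,
    ROLE_OUTCOME,
    ROLE_OUTCOME_DERIVED,
    ROLE_RECATEGORIZATION,
    CohortError,
    CohortTable,
    VariableMetadata,
)

logger = logging.getLogger(__name__)

RULE_OUTCOME_DERIVED = 1
RULE_MISSING_OVER_HALF = 2
RULE_RECATEGORIZATION = 3
RULE_SINGLE_VALUE = 4
RULE_NEAR_CONSTANT = 5

MISSING_THRESHOLD = 0.50   # strict: exactly 50% missing is retained
DOMINANCE_THRESHOLD = 0.99  # inclusive: modal fraction >= 0.99 drops


@dataclass
class ExclusionLog:
    """Which variables were dropped, by which rule, with the diagnostic
    value that triggered it (missing fraction, dominance fraction, ...)."""

    entries: list[tuple[str, int, float | str]] = field(default_factory=list)

    def dropped(self) -> list[str]:
        return [name for name, _, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["variable", "rule", "diagnostic"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _first_matching_rule(
    name: str,
    meta: VariableMetadata,
    col: pd.Series,
    n_rows: int,
    source_retained,
    gate_lookup=None,
) -> tuple[int, float | str] | None:
    """Evaluate rules 1..5 in order for one variable; rule 3 consults
    the (lazily resolved) retention status of the recategorized source."""
    if meta.role == ROLE_OUTCOME_DERIVED:
        return RULE_OUTCOME_DERIVED, "outcome_derived"
    missing = col.isna()
    if meta.gate is not None and gate_lookup is not None:
        gate_col = gate_lookup(meta.gate.gate_variable)
        if gate_col is not None:
            # cells the gate rule will fill are answered, not missing
            missing = missing & ~(gate_col.astype(str) == meta.gate.gate_value)
    miss_frac = float(missing.mean()) if n_rows else 0.0
    if miss_frac > MISSING_THRESHOLD:
        return RULE_MISSING_OVER_HALF, miss_frac
    if meta.role == ROLE_RECATEGORIZATION and source_retained(meta.recategorization_of):
        return RULE_RECATEGORIZATION, f"recategorizes {meta.recategorization_of}"
    observed = col.dropna()
    if observed.nunique() == 1:
        return RULE_SINGLE_VALUE, 1.0
    if n_rows and len(observed):
        modal_frac = float(observed.value_counts().iloc[0]) / n_rows
        if modal_frac >= DOMINANCE_THRESHOLD:
            return RULE_NEAR_CONSTANT, modal_frac
    return None


def filter_variables(table: CohortTable) -> tuple[CohortTable, ExclusionLog]:
    """Apply the five exclusion rules; returns the reduced table and log.

    Deterministic: rules are evaluated per variable in order 1->5 (first
    match wins) and variables in table column order; row order never
    affects the outcome.  An empty result table is legal and logged.
    """
    n_rows = len(table.data)
    decisions: dict[str, tuple[int, float | str] | None] = {}
    resolving: set[str] = set()

    def is_retained(name: str) -> bool:
        if name in resolving:  # recategorization cycle: treat as retained
            return True
        if name not in decisions:
            resolving.add(name)
            decisions[name] = _decide(name)
            resolving.discard(name)
        return decisions[name] is None

    def _decide(name: str) -> tuple[int, float | str] | None:
        meta = table.metadata[name]
        if meta.role in (ROLE_OUTCOME, ROLE_IDENTIFIER):
            return None
        return _first_matching_rule(
            name, meta, table.data[name], n_rows, is_retained,
            gate_lookup=lambda g: table.data[g] if g in table.data.columns else None,
        )

    for name in table.columns:
        is_retained(name)

    log = ExclusionLog()
    for name in table.columns:
        d = decisions[name]
        if d is not None:
            log.entries.append((name, d[0], d[1]))
    dropped = set(log.dropped())
    reduced = table.drop_columns([c for c in table.columns if c in dropped])
    if not reduced.feature_columns():
        logger.warning("all feature variables excluded; result table has no features")
    logger.info("filter_variables: dropped %d of %d variables", len(dropped), len(table.columns))
    return reduced, log


def apply_gate_fills(table: CohortTable) -> CohortTable:
    """Fill structurally missing ("not applicable") cells.

    A missing cell in a gated variable is replaced by the rule's fill
    value exactly when the row's gate variable equals the gate value.
    Other missing cells are untouched (they go to iterative imputation).
    A gate rule pointing at a dropped/absent variable is a hard error,
    as is a missing gate cell on a row where the rule must be consulted.
    """
    out = table.copy()
    for name, meta in table.metadata.items():
        if meta.gate is None:
            continue
        rule = meta.gate
        if rule.gate_variable not in out.data.columns:
            raise CohortError(
                f"gate rule of {name!r} references {rule.gate_variable!r}, "
                "which is not in the table (dropped or never present)"
            )
        target_missing = out.data[name].isna()
        gate_col = out.data[rule.gate_variable]
        if (gate_col.isna() & target_missing).any():
            raise CohortError(
                f"gate variable {rule.gate_variable!r} is missing on rows where "
                f"{name!r} needs gating"
            )
        gated = target_missing & (gate_col.astype(str) == rule.gate_value)
        if meta.kind == KIND_CONTINUOUS:
            out.data.loc[gated, name] = float(rule.fill)
        else:
            fill = str(rule.fill)
            observed_levels = set(table.data[name].dropna().unique())
            if fill in observed_levels:
                raise CohortError(
                    f"gate fill token {fill!r} collides with an existing level of {name!r}"
                )
            out.data.loc[gated, name] = fill
        logger.info("gate fill: %s <- %r on %d rows", name, rule.fill, int(gated.sum()))
    return out


@dataclass
class ImputationConfig:
    """Round-robin imputation settings.

    ``n_iterations`` rounds are run (default 10) and the final round's
    values are returned.  Continuous targets use ordinary least squares,
    categorical targets multinomial logistic regression; before round 1
    missing cells are seeded with the column mean (continuous) or mode
    (categorical).  Variables are visited in order of increasing
    missingness within each round.
    """

    n_iterations: int = 10
    seed: int = 0
    max_logistic_iter: int = 200

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def _design_matrix(data: pd.DataFrame, predictors: list[str], kinds: dict[str, str]) -> np.ndarray:
    """Numeric design matrix over complete (already seeded) data;
    categorical predictors one-hot expanded with fixed level order."""
    blocks = []
    for col in predictors:
        if kinds[col] == KIND_CONTINUOUS:
            v = data[col].to_numpy(float)
            sd = v.std()
            # standardize for solver conditioning; OLS/logistic predictions
            # are invariant to this affine rescaling
            blocks.append(((v - v.mean()) / (sd if sd > 0 else 1.0)).reshape(-1, 1))
        else:
            levels = sorted(map(str, pd.unique(data[col].astype(str))))
            vals = data[col].astype(str).to_numpy()
            blocks.append(np.stack([(vals == lev).astype(float) for lev in levels], axis=1))
    if not blocks:
        return np.zeros((len(data), 0))
    return np.concatenate(blocks, axis=1)


def impute_iterative(table: CohortTable, config: ImputationConfig | None = None) -> CohortTable:
    """Iterated round-robin regression imputation.

    Returns a table with zero missing cells in which every originally
    observed cell is identical to the input.  Deterministic given the
    configuration.  A variable with no observed values at all is a hard
    error — there is nothing to regress on.
    """
    config = config or ImputationConfig()
    out = table.copy()
    data = out.data
    kinds = {c: out.metadata[c].kind for c in data.columns}
    missing_mask = data.isna()
    incomplete = [c for c in data.columns if missing_mask[c].any()]
    if not incomplete:
        return out
    if len(data.columns) < 2:
        raise CohortError("imputation needs at least 2 variables")
    for col in incomplete:
        if missing_mask[col].all():
            raise CohortError(f"variable {col!r} has zero observed values; cannot impute")

    # initial fill: mean / mode
    for col in incomplete:
        if kinds[col] == KIND_CONTINUOUS:
            data.loc[missing_mask[col], col] = float(data[col].mean())
        else:
            mode = data[col].dropna().mode(dropna=True)
            data.loc[missing_mask[col], col] = str(mode.iloc[0])

    # visit order: increasing original missingness, ties by column order
    order = sorted(incomplete, key=lambda c: (float(missing_mask[c].mean()),
                                              list(data.columns).index(c)))

    for _ in range(config.n_iterations):
        for col in order:
            obs = ~missing_mask[col]
            mis = missing_mask[col]
            predictors = [c for c in data.columns if c != col]
            x_all = _design_matrix(data, predictors, kinds)
            if kinds[col] == KIND_CONTINUOUS:
                reg = LinearRegression()
                reg.fit(x_all[obs.to_numpy()], data.loc[obs, col].to_numpy(float))
                pred = reg.predict(x_all[mis.to_numpy()])
                data.loc[mis, col] = pred
            else:
                y_obs = data.loc[obs, col].astype(str).to_numpy()
                if len(np.unique(y_obs)) == 1:
                    data.loc[mis, col] = y_obs[0]
                    continue
                clf = LogisticRegression(
                    max_iter=config.max_logistic_iter,
                    random_state=config.seed,
                )
                clf.fit(x_all[obs.to_numpy()], y_obs)
                data.loc[mis, col] = clf.predict(x_all[mis.to_numpy()])

    for col in data.columns:
        if kinds[col] == KIND_CONTINUOUS:
            data[col] = data[col].astype(float)
    assert int(data.isna().sum().sum()) == 0
    return out
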