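"""Synthetic pregnancy-cohort generator with planted outliers.

Emulates the shape of an obstetric trial/cohort table: correlated
continuous measurements (age, weight, BMI, blood pressures, gestational
age at delivery), count variables (gravidity, parity, ...), binary risk
factors and supplement indicators, and a binary outcome (preeclampsia /
hypertensive disorder) drawn from a logistic model over those risk
factors with the intercept calibrated to a target prevalence.

Two missingness mechanisms are generated:

* gated ("not applicable") missingness — e.g. cigarettes/day is only
  asked of smokers, so non-smokers carry a structurally missing cell
  whose correct fill is 0;
* missing at random — the gap probability is a logistic function of two
  fully observed covariates (age, weight), so the MAR assumption holds
  exactly in the generator.

Two kinds of outliers can be planted, with ground truth recorded:

* point outliers — rows with several continuous features shifted by a
  large number of SDs (marginally extreme);
* contextual outliers — rows whose features are individually typical but
  whose outcome contradicts the generating mechanism, either by flipping
  the label of rows with extreme linear predictors or by drawing a
  hidden binary effect modifier that reverses the odds for carriers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm, poisson

from .io import (
    KIND_CATEGORICAL,
    KIND_CONTINUOUS,
    CohortTable,
    NotApplicableRule,
    OutcomeSpec,
    VariableMetadata,
)

logger = logging.getLogger(__name__)

MECHANISM_LABEL_FLIP = "label_flip_extreme"
MECHANISM_HIDDEN_MODIFIER = "hidden_modifier"

#: categorical token encoding for generated binary variables
NO, YES = "no", "yes"


@dataclass(frozen=True)
class GatedPair:
    """A gate variable and the dependent variable it switches off."""

    gate_variable: str
    gate_value: str
    dependent: str
    dependent_kind: str  # continuous | categorical
    fill: float | str


@dataclass
class SyntheticSpec:
    """Parameters of the generated cohort.

    Defaults emulate a folic-acid-trial-like high-risk obstetric cohort:
    N = 2,301, binary outcome at 14.1% prevalence, risk-factor
    prevalences and continuous means/SDs matching the published cohort
    characteristics of such trials.  ``outcome_coefficients`` are
    log-odds per SD (continuous) or per category switch (binary).
    """

    n_rows: int = 2301
    continuous_vars: list[tuple[str, float, float]] = field(
        default_factory=lambda: [
            ("age", 31.4, 5.3),
            ("weight", 91.6, 24.8),
            ("bmi", 34.0, 11.2),
            ("sbp_last", 136.1, 18.2),
            ("dbp_last", 81.5, 13.0),
            ("gest_age_delivery", 37.8, 2.8),
        ]
    )
    count_vars: list[tuple[str, float]] = field(
        default_factory=lambda: [
            ("gravidity", 2.7),
            ("term_births", 0.9),
            ("preterm_births", 0.3),
            ("abortions", 0.7),
            ("living_children", 1.1),
        ]
    )
    binary_vars: list[tuple[str, float]] = field(
        default_factory=lambda: [
            ("multiple_pregnancy", 0.186),
            ("art_pregnancy", 0.093),
            ("chronic_hypertension", 0.186),
            ("diabetes_history", 0.135),
            ("preeclampsia_history", 0.253),
            ("smoking_history", 0.399),
            ("alcohol_use", 0.021),
            ("folic_acid_supp", 0.818),
            ("aspirin", 0.289),
            ("calcium_supp", 0.085),
            ("other_medications", 0.704),
        ]
    )
    gated_pairs: list[GatedPair] = field(
        default_factory=lambda: [
            GatedPair("smoking_history", NO, "cigarettes_per_day", KIND_CONTINUOUS, 0.0),
            GatedPair("smoking_history", NO, "smoking_intensity", KIND_CATEGORICAL, "NOT_APPLICABLE"),
        ]
    )
    outcome_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.30,
            "bmi": 0.60,
            "sbp_last": 0.90,
            "dbp_last": 0.50,
            "chronic_hypertension": 1.60,
            "preeclampsia_history": 1.80,
            "diabetes_history": 0.70,
            "multiple_pregnancy": 1.00,
            "art_pregnancy": 0.40,
            "aspirin": -0.50,
            "folic_acid_supp": -0.30,
        }
    )
    outcome_name: str = "preeclampsia"
    target_prevalence: float = 0.141
    mar_missing_rate: float = 0.05
    n_point_outliers: int = 0
    point_magnitude: float = 8.0
    point_n_features: int = 3
    n_contextual_outliers: int = 0
    contextual_mechanism: str = MECHANISM_LABEL_FLIP
    seed: int = 2022

    def validate(self) -> None:
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must lie in (0, 1)")
        if self.n_point_outliers + self.n_contextual_outliers > self.n_rows:
            raise ValueError("planted outlier counts exceed n_rows")
        if self.contextual_mechanism not in (MECHANISM_LABEL_FLIP, MECHANISM_HIDDEN_MODIFIER):
            raise ValueError(f"unknown contextual mechanism {self.contextual_mechanism!r}")


@dataclass
class SyntheticTruth:
    """Ground truth of the generating mechanism, for recovery testing."""

    linear_predictor: np.ndarray
    intercept: float
    coefficients: dict[str, float]
    point_outlier_ids: list[str] = field(default_factory=list)
    contextual_outlier_ids: list[str] = field(default_factory=list)
    point_shifted_features: dict[str, list[str]] = field(default_factory=dict)
    hidden_modifier: dict[str, int] | None = None

    def to_json(self, path: str | Path) -> None:
        doc = {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "point_outlier_ids": self.point_outlier_ids,
            "contextual_outlier_ids": self.contextual_outlier_ids,
            "point_shifted_features": self.point_shifted_features,
            "hidden_modifier": self.hidden_modifier,
            "linear_predictor": [float(v) for v in self.linear_predictor],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


def point_recovery_spec(n_rows: int = 1000, n_outliers: int = 5, seed: int = 0) -> SyntheticSpec:
    """Benchmark condition for point-outlier recovery.

    A complete continuous-measurement table (no binaries, counts or
    missingness): isolation forests detect marginal extremes, and the
    benchmark isolates that regime — rows shifted 8 SD on 3 of the 6
    continuous measurements must surface in the top |z| ranks.
    """
    return SyntheticSpec(
        n_rows=n_rows,
        count_vars=[],
        binary_vars=[],
        gated_pairs=[],
        outcome_coefficients={"age": 0.30, "bmi": 0.60, "sbp_last": 0.90, "dbp_last": 0.50},
        mar_missing_rate=0.0,
        n_point_outliers=n_outliers,
        point_magnitude=8.0,
        point_n_features=3,
        seed=seed,
    )


#: forest used by the contextual-recovery benchmark: shallow and smooth so
#: trees generalize the outcome mechanism instead of memorizing the
#: planted contradictory labels in the training split
RECOVERY_FOREST_PARAMS = {
    "n_estimators": 500,
    "max_depth": 10,
    "min_samples_leaf": 5,
    "min_samples_split": 2,
    "max_features": "sqrt",
    "bootstrap": False,
}


def contextual_recovery_spec(n_rows: int = 3000, n_flipped: int = 30, seed: int = 0) -> SyntheticSpec:
    """Benchmark condition for contextual-outlier recovery.

    The full mixed-type roster with a steep (3x) logistic mechanism, so
    the outcome is close to deterministic given the features and a
    flipped label genuinely contradicts the learnable pattern; 1% of
    rows in the top decile of |linear predictor| have their outcome
    flipped.  No missingness, so the detector is tested in isolation.
    """
    strong = {k: 3.0 * v for k, v in SyntheticSpec().outcome_coefficients.items()}
    return SyntheticSpec(
        n_rows=n_rows,
        gated_pairs=[],
        outcome_coefficients=strong,
        mar_missing_rate=0.0,
        n_contextual_outliers=n_flipped,
        contextual_mechanism=MECHANISM_LABEL_FLIP,
        seed=seed,
    )


def _correlation_matrix(names: list[str], rho: dict[tuple[str, str], float]) -> np.ndarray:
    k = len(names)
    pos = {n: i for i, n in enumerate(names)}
    c = np.eye(k)
    for (a, b), r in rho.items():
        if a in pos and b in pos:
            c[pos[a], pos[b]] = c[pos[b], pos[a]] = r
    # nudge to the nearest PSD matrix if the hand-set correlations clash
    w, v = np.linalg.eigh(c)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        c = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
    return c


#: latent correlations of the copula; clinically motivated pairs only
_DEFAULT_RHO = {
    ("weight", "bmi"): 0.80,
    ("sbp_last", "dbp_last"): 0.70,
    ("bmi", "sbp_last"): 0.30,
    ("age", "gravidity"): 0.40,
    ("gravidity", "term_births"): 0.55,
    ("gravidity", "abortions"): 0.45,
    ("gravidity", "living_children"): 0.55,
    ("term_births", "living_children"): 0.70,
    ("chronic_hypertension", "sbp_last"): 0.35,
    ("chronic_hypertension", "preeclampsia_history"): 0.30,
    ("bmi", "diabetes_history"): 0.25,
}


def _calibrate_intercept(eta_no_intercept: np.ndarray, target: float) -> float:
    """Bisection for the logistic intercept giving mean expit == target."""

    def gap(b0: float) -> float:
        return float(expit(eta_no_intercept + b0).mean() - target)

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            "target prevalence unattainable for the given coefficients within "
            "intercept bounds [-30, 30]"
        )
    return float(brentq(gap, lo, hi, xtol=1e-10))


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[CohortTable, dict[str, VariableMetadata], SyntheticTruth]:
    """Draw a full synthetic cohort from ``spec``.

    Continuous, count and binary variables share a Gaussian copula with
    the module's clinically motivated latent correlations; counts are
    Poisson via quantile transform, binaries are threshold indicators at
    their target prevalence.  The outcome is Bernoulli(expit(eta)) with
    the intercept found by bisection so the empirical prevalence lands
    near ``target_prevalence``.  Planting of outliers is performed by
    :func:`plant_point_outliers` / :func:`plant_contextual_outliers`
    when the spec requests them.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rows

    cont_names = [v[0] for v in spec.continuous_vars]
    count_names = [v[0] for v in spec.count_vars]
    bin_names = [v[0] for v in spec.binary_vars]
    latent_names = cont_names + count_names + bin_names
    corr = _correlation_matrix(latent_names, _DEFAULT_RHO)
    z = rng.multivariate_normal(np.zeros(len(latent_names)), corr, size=n,
                                method="cholesky")
    u = norm.cdf(z)

    data = pd.DataFrame(index=pd.Index([f"P{i:05d}" for i in range(n)], name="participant_id"))
    meta: dict[str, VariableMetadata] = {}

    for j, (name, mean, sd) in enumerate(spec.continuous_vars):
        data[name] = mean + sd * z[:, j]
        meta[name] = VariableMetadata(name=name, kind=KIND_CONTINUOUS,
                                      risk_factor=name in spec.outcome_coefficients)
    off = len(cont_names)
    for j, (name, lam) in enumerate(spec.count_vars):
        data[name] = poisson.ppf(u[:, off + j], lam).astype(float)
        meta[name] = VariableMetadata(name=name, kind=KIND_CONTINUOUS)
    off = len(cont_names) + len(count_names)
    for j, (name, prev) in enumerate(spec.binary_vars):
        ind = (u[:, off + j] < prev)
        data[name] = np.where(ind, YES, NO).astype(object)
        meta[name] = VariableMetadata(name=name, kind=KIND_CATEGORICAL,
                                      risk_factor=name in spec.outcome_coefficients)

    # gated dependents, fully answered for now; gating applied below
    for gp in spec.gated_pairs:
        if gp.dependent_kind == KIND_CONTINUOUS:
            data[gp.dependent] = np.round(np.clip(rng.normal(9.0, 5.0, n), 0.5, None), 1)
        else:
            levels = np.array(["light", "moderate", "heavy"], dtype=object)
            data[gp.dependent] = levels[rng.integers(0, 3, n)]
        meta[gp.dependent] = VariableMetadata(
            name=gp.dependent,
            kind=gp.dependent_kind,
            gate=NotApplicableRule(gp.gate_variable, gp.gate_value, gp.fill),
        )

    # outcome: logistic over standardized continuous + binary indicators
    eta = np.zeros(n)
    for name, beta in spec.outcome_coefficients.items():
        if name in cont_names:
            mean, sd = next((m, s) for v, m, s in spec.continuous_vars if v == name)
            eta += beta * (data[name].to_numpy(float) - mean) / sd
        elif name in bin_names:
            eta += beta * (data[name].to_numpy() == YES)
        else:
            raise ValueError(f"outcome coefficient for unknown variable {name!r}")
    intercept = _calibrate_intercept(eta, spec.target_prevalence)
    eta = eta + intercept
    y = rng.random(n) < expit(eta)
    data[spec.outcome_name] = np.where(y, YES, NO).astype(object)
    meta[spec.outcome_name] = VariableMetadata(name=spec.outcome_name, kind=KIND_CATEGORICAL,
                                               role="outcome")

    truth = SyntheticTruth(
        linear_predictor=eta,
        intercept=intercept,
        coefficients=dict(spec.outcome_coefficients),
    )

    table = CohortTable(
        data=data,
        metadata=meta,
        outcome=OutcomeSpec(column=spec.outcome_name, positive_label=YES),
    )

    if spec.n_point_outliers:
        table, truth = plant_point_outliers(table, truth, spec, rng)
    if spec.n_contextual_outliers:
        table, truth = plant_contextual_outliers(table, truth, spec, rng)

    _apply_gated_missingness(table, spec)
    _apply_mar_missingness(table, spec, rng)
    return table, meta, truth


def _apply_gated_missingness(table: CohortTable, spec: SyntheticSpec) -> None:
    """Blank out gated dependents where the gate says 'not applicable'."""
    for gp in spec.gated_pairs:
        gated = table.data[gp.gate_variable].to_numpy() == gp.gate_value
        table.data.loc[gated, gp.dependent] = np.nan

def _apply_mar_missingness(table: CohortTable, spec: SyntheticSpec, rng: np.random.Generator) -> None:
    """MAR gaps: P(missing) is logistic in age and weight (never missing
    themselves), scaled so the average gap rate over eligible cells is
    ``mar_missing_rate``."""
    if spec.mar_missing_rate <= 0:
        return
    protected = {"age", "weight", spec.outcome_name}
    protected |= {gp.gate_variable for gp in spec.gated_pairs}
    protected |= {gp.dependent for gp in spec.gated_pairs}
    age = table.data["age"].to_numpy(float)
    wt = table.data["weight"].to_numpy(float)
    score = 0.6 * (age - age.mean()) / age.std() - 0.4 * (wt - wt.mean()) / wt.std()
    p = expit(score)
    p = p * (spec.mar_missing_rate / p.mean())
    p = np.clip(p, 0.0, 0.95)
    for col in table.data.columns:
        if col in protected:
            continue
        gaps = rng.random(len(p)) < p
        table.data.loc[gaps, col] = np.nan


def plant_point_outliers(
    table: CohortTable,
    truth: SyntheticTruth,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[CohortTable, SyntheticTruth]:
    """Shift ``point_n_features`` continuous features of randomly chosen
    rows by ``point_magnitude`` SDs (alternating sign), recording ids and
    shifted features in the truth object."""
    if spec.n_point_outliers <= 0:
        return table, truth
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    cont = [v for v in spec.continuous_vars]
    eligible = [i for i in range(len(table.data))]
    chosen = sorted(rng.choice(eligible, size=spec.n_point_outliers, replace=False).tolist())
    ids = [table.data.index[i] for i in chosen]
    for row_i, pid in zip(chosen, ids):
        feats = rng.choice(len(cont), size=min(spec.point_n_features, len(cont)), replace=False)
        shifted = []
        for k, fj in enumerate(feats):
            name, _, sd = cont[fj]
            sign = 1.0 if (k + row_i) % 2 == 0 else -1.0
            table.data.iloc[row_i, table.data.columns.get_loc(name)] += sign * spec.point_magnitude * sd
            shifted.append(name)
        truth.point_shifted_features[str(pid)] = shifted
    truth.point_outlier_ids = [str(p) for p in ids]
    return table, truth


def plant_contextual_outliers(
    table: CohortTable,
    truth: SyntheticTruth,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[CohortTable, SyntheticTruth]:
    """Plant outcome-contradicting rows that remain marginally typical.

    ``label_flip_extreme``: among rows in the top decile of |linear
    predictor| (centered), flip the recorded outcome of
    ``n_contextual_outliers`` rows not already planted as point
    outliers.  ``hidden_modifier``: draw an unrecorded binary modifier
    that reverses the outcome odds of carriers and redraw their
    outcomes; the modifier goes into the truth record, never the table.
    """
    if spec.n_contextual_outliers <= 0:
        return table, truth
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 2)
    n = len(table.data)
    eta = truth.linear_predictor
    point_set = set(truth.point_outlier_ids)

    if spec.contextual_mechanism == MECHANISM_LABEL_FLIP:
        dev = np.abs(eta)
        cutoff = np.quantile(dev, 0.9)
        stratum = [i for i in range(n)
                   if dev[i] >= cutoff and str(table.data.index[i]) not in point_set]
        if len(stratum) < spec.n_contextual_outliers:
            raise ValueError(
                f"eligible extreme-predictor stratum has {len(stratum)} rows, "
                f"fewer than n_contextual_outliers={spec.n_contextual_outliers}"
            )
        chosen = sorted(rng.choice(stratum, size=spec.n_contextual_outliers, replace=False).tolist())
        col = table.data.columns.get_loc(spec.outcome_name)
        for i in chosen:
            cur = table.data.iloc[i, col]
            table.data.iloc[i, col] = YES if cur == NO else NO
        truth.contextual_outlier_ids = [str(table.data.index[i]) for i in chosen]
    else:  # hidden modifier
        carriers = rng.choice(n, size=spec.n_contextual_outliers, replace=False)
        carriers = np.array(sorted(set(carriers) - {i for i in range(n)
                                                    if str(table.data.index[i]) in point_set}))
        modifier = np.zeros(n, dtype=int)
        modifier[carriers] = 1
        col = table.data.columns.get_loc(spec.outcome_name)
        for i in carriers:
            p_rev = expit(-eta[i])  # odds reversed for carriers
            table.data.iloc[i, col] = YES if rng.random() < p_rev else NO
        truth.hidden_modifier = {str(table.data.index[i]): int(modifier[i]) for i in range(n)}
        truth.contextual_outlier_ids = [str(table.data.index[i]) for i in carriers]
    return table, truth
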