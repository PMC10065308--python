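"""Random-forest extreme-misclassification contextual-outlier stage.

A random-forest classifier is trained on the binary study outcome
(train/test/validation split), its hyperparameters chosen by a random
search followed by a targeted grid bracketing the random-phase winner.
The confidence of a prediction is the vote fraction: the proportion of
base trees whose individual hard prediction is that class — not the
averaged leaf probabilities.  A participant is a contextual outlier iff
the model's predicted class differs from the recorded one AND the vote
fraction of the predicted class is strictly greater than the threshold
(default 0.90).  Flagging is applied over the full dataset by default;
per-class precision/recall can be reported on any subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score

from .io import CohortTable, OutcomeSpec
from .point import FeatureEncoding, encode_features

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Fixed-size train/test/validation partition."""

    train_n: int
    test_n: int
    validation_n: int
    seed: int = 2022


@dataclass
class DatasetSplit:
    train_idx: np.ndarray
    test_idx: np.ndarray
    validation_idx: np.ndarray


def split_dataset(table: CohortTable, spec: SplitSpec) -> DatasetSplit:
    """Disjoint, exhaustive, seed-reproducible random partition into
    train/test/validation of the exact requested sizes."""
    n = len(table.data)
    total = spec.train_n + spec.test_n + spec.validation_n
    if total != n:
        raise ValueError(f"split sizes sum to {total}, table has {n} rows")
    perm = np.random.default_rng(spec.seed).permutation(n)
    split = DatasetSplit(
        train_idx=np.sort(perm[: spec.train_n]),
        test_idx=np.sort(perm[spec.train_n : spec.train_n + spec.test_n]),
        validation_idx=np.sort(perm[spec.train_n + spec.test_n :]),
    )
    if table.outcome is not None:
        y = table.data[table.outcome.column].to_numpy()
        for name, idx in (("train", split.train_idx), ("test", split.test_idx),
                          ("validation", split.validation_idx)):
            if len(idx):
                prev = float(np.mean(y[idx] == table.outcome.positive_label))
                logger.info("split %s: n=%d outcome prevalence=%.3f", name, len(idx), prev)
    return split


# ---------------------------------------------------------------------------
# hyperparameter search: random phase, then targeted grid around the winner
# ---------------------------------------------------------------------------

@dataclass
class ForestSearchSpec:
    """Two-phase search specification.

    ``distributions`` maps each searched dimension to its ordered
    candidate list; the random phase samples ``n_candidates``
    configurations, the targeted phase exhaustively scores, one
    dimension at a time, the immediate grid neighbours of the
    random-phase winner (so the grid brackets the winner in every
    dimension).  Scoring is F1 on the positive class over the test set.
    """

    n_candidates: int = 20
    distributions: dict[str, list] = field(
        default_factory=lambda: {
            "n_estimators": [100, 200, 300, 400, 600, 800, 1000],
            "max_depth": [5, 10, 20, 40, 90, None],
            "max_features": ["sqrt", 0.2, 0.4, 0.6, 1.0],
            "min_samples_split": [2, 4, 6, 10],
            "min_samples_leaf": [1, 2, 4],
            "bootstrap": [False, True],
        }
    )
    seed: int = 2022


@dataclass
class SearchResult:
    best_params: dict
    ledger: pd.DataFrame  # columns: phase, score, one column per dimension


def _fit_forest(params: dict, x: np.ndarray, y: np.ndarray, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(random_state=seed, n_jobs=1, **params).fit(x, y)


def _score_params(params, x_tr, y_tr, x_te, y_te, positive, seed) -> float:
    model = _fit_forest(params, x_tr, y_tr, seed)
    pred = model.predict(x_te)
    return float(f1_score(y_te, pred, pos_label=positive, zero_division=0))


def search_hyperparameters(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    spec: ForestSearchSpec | None = None,
    positive_label: str = "yes",
) -> SearchResult:
    """Random search then targeted neighbour grid; returns the winner and
    the full persisted score ledger (the returned parameters are the
    argmax over that ledger)."""
    spec = spec or ForestSearchSpec()
    if len(np.unique(y_train)) < 2:
        raise ValueError("training outcome is single-class; cannot fit a classifier")
    dims = list(spec.distributions)
    rng = np.random.default_rng(spec.seed)

    space_size = int(np.prod([len(spec.distributions[d]) for d in dims]))
    records: list[dict] = []

    def evaluate(params: dict, phase: str) -> float:
        score = _score_params(params, x_train, y_train, x_test, y_test,
                              positive_label, spec.seed)
        records.append({"phase": phase, "score": score, **params})
        return score

    if space_size == 1:
        only = {d: spec.distributions[d][0] for d in dims}
        evaluate(only, "degenerate")
        ledger = pd.DataFrame(records)
        return SearchResult(best_params=only, ledger=ledger)

    # phase 1: random sampling without replacement of full configurations
    seen: set[tuple] = set()
    n_random = min(spec.n_candidates, space_size)
    while len(seen) < n_random:
        cand = tuple(spec.distributions[d][rng.integers(len(spec.distributions[d]))]
                     for d in dims)
        if cand in seen:
            continue
        seen.add(cand)
        evaluate(dict(zip(dims, cand)), "random")

    phase1 = pd.DataFrame(records)
    winner_row = phase1.loc[phase1["score"].idxmax()]
    winner = {d: winner_row[d] for d in dims}
    # pandas upcasts ints to float in mixed columns; restore candidate types
    for d in dims:
        for v in spec.distributions[d]:
            if v is None and pd.isna(winner[d]):
                winner[d] = None
            elif not pd.isna(winner[d]) and v is not None and str(v) == str(winner[d]):
                winner[d] = v
            elif (isinstance(v, (int, float)) and not isinstance(v, bool)
                  and isinstance(winner[d], float) and v == winner[d]):
                winner[d] = v

    # phase 2: for each dimension, score the winner with that dimension
    # moved to its immediate grid neighbours (and the winner itself)
    evaluate(dict(winner), "targeted")
    for d in dims:
        choices = spec.distributions[d]
        i = choices.index(winner[d])
        for j in (i - 1, i + 1):
            if 0 <= j < len(choices):
                cand = dict(winner)
                cand[d] = choices[j]
                evaluate(cand, "targeted")

    ledger = pd.DataFrame(records)
    best_i = int(ledger["score"].idxmax())
    best = {d: records[best_i][d] for d in dims}
    return SearchResult(best_params=best, ledger=ledger)


# ---------------------------------------------------------------------------
# vote-fraction confidence and extreme-misclassification flagging
# ---------------------------------------------------------------------------

def vote_confidence(model: RandomForestClassifier, x: np.ndarray) -> pd.DataFrame:
    """Per-class hard-vote fractions for each row.

    For every base tree the hard prediction is taken, and for each class
    the fraction of trees voting for it is reported; fractions sum to 1
    by construction.  This is deliberately NOT ``predict_proba`` (which
    averages leaf probabilities).
    """
    # trees predict encoded class indices; stack votes tree-by-tree
    votes = np.stack([tree.predict(x) for tree in model.estimators_]).astype(int)
    n_classes = len(model.classes_)
    counts = np.stack([(votes == k).sum(axis=0) for k in range(n_classes)], axis=1)
    frac = counts / votes.shape[0]
    return pd.DataFrame(frac, columns=[str(c) for c in model.classes_])


@dataclass
class MisclassificationResult:
    """Per-row labels, vote confidence and contextual-outlier flags."""

    frame: pd.DataFrame  # index participant_id; true_label, predicted_label,
                         # vote_fraction, is_outlier
    threshold: float
    params: dict

    @property
    def outlier_ids(self) -> list[str]:
        return list(self.frame.index[self.frame["is_outlier"]])


def flag_extreme_misclassification(
    model: RandomForestClassifier,
    table: CohortTable,
    encoding: FeatureEncoding,
    outcome: OutcomeSpec | None = None,
    threshold: float = 0.90,
    row_mask: np.ndarray | None = None,
) -> MisclassificationResult:
    """Flag rows mislabelled with vote fraction strictly above ``threshold``.

    Applied over the entire table by default (train, test and validation
    rows alike); pass ``row_mask`` to restrict to held-out rows.  The
    predicted label is the class with the larger vote fraction; an exact
    50/50 tie goes to the lexicographically smaller class token (a tie
    can never be flagged, as it cannot exceed any threshold above 0.5).
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    outcome = outcome or table.outcome
    if outcome is None:
        raise ValueError("an outcome specification is required")
    x = encoding.transform(table)
    frac = vote_confidence(model, x)
    classes = [str(c) for c in model.classes_]
    arr = frac.to_numpy()
    pred_pos = np.empty(len(arr), dtype=int)
    for i, row in enumerate(arr):
        # among argmax classes pick the lexicographically smallest token
        maxv = row.max()
        cand = [k for k in range(len(classes)) if row[k] == maxv]
        pred_pos[i] = min(cand, key=lambda k: classes[k])
    predicted = np.array([classes[k] for k in pred_pos], dtype=object)
    vote_fraction = arr[np.arange(len(arr)), pred_pos]
    true = table.data[outcome.column].astype(str).to_numpy(object)
    flags = (predicted != true) & (vote_fraction > threshold)
    if row_mask is not None:
        flags = flags & np.asarray(row_mask, dtype=bool)
    frame = pd.DataFrame(
        {
            "true_label": true,
            "predicted_label": predicted,
            "vote_fraction": vote_fraction,
            "is_outlier": flags,
        },
        index=pd.Index(table.participant_ids, name="participant_id"),
    )
    return MisclassificationResult(frame=frame, threshold=threshold,
                                   params=model.get_params())


def classification_report(
    result: MisclassificationResult, subset: np.ndarray | list[str] | None = None
) -> pd.DataFrame:
    """Per-class precision and recall over a row subset.

    ``subset`` may be a boolean mask or a list of participant ids; the
    default is all rows.  A metric whose denominator is empty (class
    absent, or never predicted) is reported as NaN — undefined, not 0.
    """
    frame = result.frame
    if subset is not None:
        if isinstance(subset, (list, tuple, pd.Index)):
            frame = frame.loc[list(subset)]
        else:
            frame = frame[np.asarray(subset, dtype=bool)]
    if len(frame) == 0:
        raise ValueError("subset is empty")
    true = frame["true_label"].to_numpy()
    pred = frame["predicted_label"].to_numpy()
    rows = []
    for cls in sorted(set(true) | set(pred)):
        tp = int(np.sum((pred == cls) & (true == cls)))
        fp = int(np.sum((pred == cls) & (true != cls)))
        fn = int(np.sum((pred != cls) & (true == cls)))
        precision = tp / (tp + fp) if tp + fp else float("nan")
        recall = tp / (tp + fn) if tp + fn else float("nan")
        rows.append({"class": cls, "precision": precision, "recall": recall,
                     "support": int(np.sum(true == cls))})
    return pd.DataFrame(rows).set_index("class")


def detect_contextual_outliers(
    table: CohortTable,
    split: SplitSpec,
    search: ForestSearchSpec | None = None,
    fixed_params: dict | None = None,
    threshold: float = 0.90,
    seed: int = 2022,
    holdout_only: bool = False,
) -> tuple[MisclassificationResult, SearchResult | None, RandomForestClassifier]:
    """End-to-end contextual stage on one cohort.

    Splits the table, finds hyperparameters (or uses ``fixed_params``),
    fits on the training split, and flags extreme misclassifications
    over the full table (or only test+validation rows when
    ``holdout_only``).
    """
    outcome = table.outcome
    if outcome is None:
        raise ValueError("table has no outcome specification")
    x, encoding = encode_features(table)
    y = table.data[outcome.column].astype(str).to_numpy(object)
    parts = split_dataset(table, split)
    search_result = None
    if fixed_params is None:
        search_result = search_hyperparameters(
            x[parts.train_idx], y[parts.train_idx],
            x[parts.test_idx], y[parts.test_idx],
            search, positive_label=outcome.positive_label,
        )
        params = search_result.best_params
    else:
        params = dict(fixed_params)
    model = _fit_forest(params, x[parts.train_idx], y[parts.train_idx], seed)
    mask = None
    if holdout_only:
        mask = np.zeros(len(y), dtype=bool)
        mask[parts.test_idx] = True
        mask[parts.validation_idx] = True
    result = flag_extreme_misclassification(
        model, table, encoding, outcome, threshold=threshold, row_mask=mask
    )
    return result, search_result, model
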