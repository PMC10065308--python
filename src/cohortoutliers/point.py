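"""Isolation-forest point-outlier stage.

Scores every participant with an isolation forest (ensemble-averaged,
normalized path length), standardizes the scores within the sample, and
flags rows whose anomaly-score z-score satisfies the inclusive two-sided
rule |z| >= 3.  The contamination parameter (default 0.05, the assumed
upper bound on the outlier fraction) is passed to the model as an
assumption but the flags come from the z rule only, never from the
model's internal contamination cutoff.

Hyperparameters are either given explicitly or tuned by the
stabilization heuristic: scan an increasing candidate grid (origin 100
trees / 256 subsamples), average the anomaly-score mean and SD over
replicate fits, and pick the first candidate beyond which both
statistics stop varying (successive relative change below a tolerance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest

from .io import KIND_CATEGORICAL, CohortTable, OutcomeSpec

logger = logging.getLogger(__name__)

Z_THRESHOLD = 3.0


class EncodingError(ValueError):
    """Raised when a table cannot be encoded with a given feature map."""


@dataclass(frozen=True)
class FeatureEncoding:
    """Persisted numeric encoding of cohort features.

    Columns are taken in sorted-name order (so results do not depend on
    the order columns appear in the file) and categorical variables are
    integer-coded by lexicographic level order.  The same encoding is
    reused by every downstream model stage.
    """

    columns: tuple[str, ...]
    level_maps: dict[str, dict[str, int]]

    def transform(self, table: CohortTable) -> np.ndarray:
        x = np.empty((len(table.data), len(self.columns)), dtype=float)
        for j, col in enumerate(self.columns):
            if col not in table.data.columns:
                raise EncodingError(f"column {col!r} absent from table")
            series = table.data[col]
            if col in self.level_maps:
                lm = self.level_maps[col]
                vals = series.to_numpy(object)
                unseen = sorted({v for v in vals if not pd.isna(v) and v not in lm})
                if unseen:
                    raise EncodingError(f"unseen level(s) {unseen} in column {col!r}")
                if pd.isna(vals).any():
                    raise EncodingError(f"missing cells in column {col!r}; impute first")
                x[:, j] = [lm[v] for v in vals]
            else:
                col_vals = series.to_numpy(float)
                if np.isnan(col_vals).any():
                    raise EncodingError(f"missing cells in column {col!r}; impute first")
                x[:, j] = col_vals
        return x


def encode_features(
    table: CohortTable, outcome: OutcomeSpec | None = None, include_outcome: bool = False
) -> tuple[np.ndarray, FeatureEncoding]:
    """Encode a complete (post-imputation) table as a numeric matrix.

    The outcome and identifier columns are excluded unless
    ``include_outcome`` is set.  Returns the matrix together with the
    reusable :class:`FeatureEncoding`.
    """
    outcome = outcome or table.outcome
    cols = sorted(table.feature_columns())
    if include_outcome and outcome is not None:
        cols = sorted(cols + [outcome.column])
    level_maps: dict[str, dict[str, int]] = {}
    for col in cols:
        if table.metadata[col].kind == KIND_CATEGORICAL:
            levels = sorted({v for v in table.data[col].dropna().unique()})
            level_maps[col] = {lev: i for i, lev in enumerate(levels)}
    enc = FeatureEncoding(columns=tuple(cols), level_maps=level_maps)
    return enc.transform(table), enc


@dataclass
class IsolationConfig:
    """Isolation-forest settings and tuning grids."""

    n_estimators: int = 100
    max_samples: int = 256
    contamination: float = 0.05
    random_state: int = 2022
    n_estimators_grid: tuple[int, ...] = tuple(range(100, 1001, 100))
    max_samples_grid: tuple[int, ...] = (256, 512, 700, 1024)
    tuning_replicates: int = 3
    tuning_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.contamination <= 0.5:
            raise ValueError("contamination must lie in (0, 0.5]")
        for grid in (self.n_estimators_grid, self.max_samples_grid):
            if any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValueError("tuning grids must be strictly increasing")


@dataclass
class TuningResult:
    """Chosen hyperparameters plus the per-candidate statistic ledger."""

    n_estimators: int
    max_samples: int
    ledger: pd.DataFrame  # columns: parameter, candidate, score_mean, score_sd


@dataclass
class AnomalyResult:
    """Per-row anomaly scores, z-scores and point-outlier flags."""

    frame: pd.DataFrame  # index participant_id; anomaly_score, z_score, is_outlier
    score_mean: float
    score_sd: float
    n_estimators: int
    max_samples: int
    random_state: int

    @property
    def outlier_ids(self) -> list[str]:
        return list(self.frame.index[self.frame["is_outlier"]])


def _fit_scores(
    x: np.ndarray, n_estimators: int, max_samples: int, contamination: float, seed: int
) -> np.ndarray:
    """Raw anomaly scores, oriented so larger = more anomalous."""
    forest = IsolationForest(
        n_estimators=n_estimators,
        max_samples=min(max_samples, x.shape[0]),
        contamination=contamination,
        random_state=seed,
        bootstrap=False,
        max_features=1.0,
        warm_start=False,
    ).fit(x)
    # score_samples is the negated normalized path-length score
    return -forest.score_samples(x)


def _first_stable(stats: list[tuple[int, float, float]], tol: float) -> tuple[int, bool]:
    """Smallest candidate whose mean AND SD change by < tol (relative)
    to the next candidate; falls back to the largest candidate."""
    for (cand, m0, s0), (_, m1, s1) in zip(stats, stats[1:]):
        dm = abs(m1 - m0) / max(abs(m0), 1e-12)
        ds = abs(s1 - s0) / max(abs(s0), 1e-12)
        if dm < tol and ds < tol:
            return cand, True
    return stats[-1][0], False


def tune_isolation(x: np.ndarray, config: IsolationConfig) -> TuningResult:
    """Stabilization tuning of (n_estimators, max_samples).

    Each parameter is scanned in turn (the other held at the grid
    origin / its chosen value), fitting ``tuning_replicates`` forests
    with distinct derived seeds per candidate and recording the mean and
    SD of the anomaly scores averaged over replicates.  The chosen value
    is the first candidate at which both statistics stabilize; if none
    does, the largest candidate is returned with a warning.
    """
    if config.tuning_replicates < 2:
        raise ValueError("tuning needs at least 2 replicates")
    rows = []

    def scan(param: str, grid: tuple[int, ...], fixed: dict[str, int]) -> int:
        if len(grid) == 1:
            logger.warning("tuning grid for %s has a single value %d", param, grid[0])
            rows.append((param, grid[0], np.nan, np.nan))
            return grid[0]
        stats = []
        for cand in grid:
            kw = dict(fixed)
            kw[param] = cand
            reps = [
                _fit_scores(
                    x,
                    kw["n_estimators"],
                    kw["max_samples"],
                    config.contamination,
                    config.random_state + 1000 * r + cand,
                )
                for r in range(config.tuning_replicates)
            ]
            m = float(np.mean([rep.mean() for rep in reps]))
            s = float(np.mean([rep.std(ddof=0) for rep in reps]))
            stats.append((cand, m, s))
            rows.append((param, cand, m, s))
        chosen, ok = _first_stable(stats, config.tuning_tolerance)
        if not ok:
            logger.warning("no %s candidate stabilized; returning largest (%d)", param, chosen)
        return chosen

    n_est = scan("n_estimators", config.n_estimators_grid,
                 {"max_samples": config.max_samples})
    grid_ms = tuple(sorted({min(g, x.shape[0]) for g in config.max_samples_grid}))
    max_samp = scan("max_samples", grid_ms, {"n_estimators": n_est})
    ledger = pd.DataFrame(rows, columns=["parameter", "candidate", "score_mean", "score_sd"])
    return TuningResult(n_estimators=n_est, max_samples=max_samp, ledger=ledger)


def flags_from_z(z: np.ndarray) -> np.ndarray:
    """The two-sided inclusive outlier rule: z <= -3 or z >= 3."""
    return (z <= -Z_THRESHOLD) | (z >= Z_THRESHOLD)


def score_anomalies(
    x: np.ndarray,
    config: IsolationConfig,
    participant_ids: list[str] | None = None,
) -> AnomalyResult:
    """Fit the isolation forest and flag point outliers by the z rule.

    Scores are standardized against the sample's own mean and SD.  If
    the raw-score SD is zero (e.g. all rows identical) no outliers are
    flagged and a warning is logged.
    """
    raw = _fit_scores(x, config.n_estimators, config.max_samples,
                      config.contamination, config.random_state)
    mean = float(raw.mean())
    sd = float(raw.std(ddof=0))
    if sd <= 1e-12:  # numerically degenerate: all rows score identically
        sd = 0.0
    if sd > 0:
        z = (raw - mean) / sd
        flags = flags_from_z(z)
    else:
        logger.warning("anomaly-score SD is zero; flagging no outliers")
        z = np.zeros_like(raw)
        flags = np.zeros(len(raw), dtype=bool)
    idx = participant_ids if participant_ids is not None else [str(i) for i in range(len(raw))]
    frame = pd.DataFrame(
        {"anomaly_score": raw, "z_score": z, "is_outlier": flags},
        index=pd.Index(idx, name="participant_id"),
    )
    return AnomalyResult(
        frame=frame,
        score_mean=mean,
        score_sd=sd,
        n_estimators=config.n_estimators,
        max_samples=min(config.max_samples, x.shape[0]),
        random_state=config.random_state,
    )


def detect_point_outliers(
    table: CohortTable,
    config: IsolationConfig | None = None,
    tune: bool = False,
) -> tuple[AnomalyResult, TuningResult | None]:
    """Convenience wrapper: encode, optionally tune, then score a cohort."""
    config = config or IsolationConfig()
    x, _ = encode_features(table)
    tuning = None
    if tune:
        tuning = tune_isolation(x, config)
        config = IsolationConfig(
            n_estimators=tuning.n_estimators,
            max_samples=tuning.max_samples,
            contamination=config.contamination,
            random_state=config.random_state,
            n_estimators_grid=config.n_estimators_grid,
            max_samples_grid=config.max_samples_grid,
            tuning_replicates=config.tuning_replicates,
            tuning_tolerance=config.tuning_tolerance,
        )
    return score_anomalies(x, config, table.participant_ids), tuning
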