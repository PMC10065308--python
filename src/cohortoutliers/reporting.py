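"""Reviewer-facing outputs: characterization tables and case narratives.

The characterization table contrasts an outlier subset with the full
cohort, one row per variable, using the conventional summary for each
variable type: mean (SD) for continuous measurements, median (IQR) for
count-like ordinals, n (%) for binaries.  Any subset count between 1
and 6 participants is suppressed — cell rendered as "Suppressed", with
the percentage suppressed alongside so the count cannot be recovered;
0 and counts of 7 or more are rendered.

Case narratives collect, for one flagged participant, the detector
provenance (stage, score or confidence), the declared risk-factor
values, and the variables most deviant from the cohort medians (top k
by robust z-score).  The novelty assessment field is a human reviewer's
to fill; it is generated as "unreviewed" and never set automatically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import KIND_CATEGORICAL, KIND_CONTINUOUS, CohortTable

logger = logging.getLogger(__name__)

SUPPRESSED = "Suppressed"
SUPPRESS_MAX = 6  # counts 1..6 are suppressed; 0 and >=7 render

ASSESSMENT_UNREVIEWED = "unreviewed"
ASSESSMENT_NOVELTY = "potential_novelty"
ASSESSMENT_NATURAL = "natural_deviation"

STAT_MEAN_SD = "mean_sd"
STAT_MEDIAN_IQR = "median_iqr"
STAT_N_PERCENT = "n_percent"

#: continuous variables with at most this many distinct integer values
#: are summarized as median (IQR), like gravidity-style counts
_COUNT_LIKE_MAX_LEVELS = 12


def _suppress_count(n: int) -> bool:
    return 1 <= n <= SUPPRESS_MAX


def _stat_kind(table: CohortTable, name: str) -> str:
    meta = table.metadata[name]
    col = table.data[name].dropna()
    if meta.kind == KIND_CATEGORICAL:
        return STAT_N_PERCENT
    vals = col.to_numpy(float)
    if len(vals) and np.all(vals == np.round(vals)) and len(np.unique(vals)) <= _COUNT_LIKE_MAX_LEVELS:
        return STAT_MEDIAN_IQR
    return STAT_MEAN_SD


def _positive_level(col: pd.Series) -> str:
    """Reporting level for a 2-level categorical: 'yes'-like if present,
    else the rarer level (risk-factor convention)."""
    levels = sorted(map(str, col.dropna().unique()))
    for cand in ("yes", "Yes", "1", "true", "True"):
        if cand in levels:
            return cand
    counts = col.dropna().astype(str).value_counts()
    return str(counts.index[-1])


def _fmt_mean_sd(vals: np.ndarray) -> str:
    return f"{np.mean(vals):.1f} ({np.std(vals, ddof=1):.1f})" if len(vals) > 1 else (
        f"{np.mean(vals):.1f} (0.0)" if len(vals) else "NA")


def _fmt_median_iqr(vals: np.ndarray) -> str:
    if not len(vals):
        return "NA"
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    g = lambda v: f"{v:g}"
    return f"{g(med)} ({g(q1)} to {g(q3)})"


def _fmt_count(n: int, total: int, suppress: bool) -> str:
    if suppress and _suppress_count(n):
        return SUPPRESSED
    pct = 100.0 * n / total if total else 0.0
    return f"{n} ({pct:.1f})" if n else "0 (0)"


@dataclass
class ComparisonTable:
    """Outlier-subset vs full-cohort characterization, pre-rendered."""

    frame: pd.DataFrame  # variable, statistic, level, outliers, cohort, suppressed

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def render_text(self) -> str:
        width = max(len(str(v)) for v in self.frame["variable"]) + 2
        lines = [f"{'Variable':<{width}}{'Outliers':>22}{'Cohort':>22}"]
        for _, row in self.frame.iterrows():
            label = row["variable"] if not row["level"] else f"{row['variable']}={row['level']}"
            lines.append(f"{label:<{width}}{row['outliers']:>22}{row['cohort']:>22}")
        return "\n".join(lines) + "\n"


def characterize_outliers(
    outlier_ids: list[str],
    table: CohortTable,
    variables: list[str] | None = None,
) -> ComparisonTable:
    """Build the outlier-vs-cohort characterization table.

    Small-cell suppression applies to outlier-subset counts only; full-
    cohort counts are aggregate enough to render.  Multi-level
    categorical variables contribute one row per level.
    """
    if not outlier_ids:
        raise ValueError("outlier set is empty")
    sub = table.data.loc[[str(i) for i in outlier_ids]]
    variables = variables if variables is not None else table.feature_columns()
    rows = []
    for name in variables:
        kind = _stat_kind(table, name)
        col_full = table.data[name]
        col_sub = sub[name]
        if kind == STAT_MEAN_SD:
            rows.append({
                "variable": name, "statistic": kind, "level": "",
                "outliers": _fmt_mean_sd(col_sub.dropna().to_numpy(float)),
                "cohort": _fmt_mean_sd(col_full.dropna().to_numpy(float)),
                "suppressed": False,
            })
        elif kind == STAT_MEDIAN_IQR:
            rows.append({
                "variable": name, "statistic": kind, "level": "",
                "outliers": _fmt_median_iqr(col_sub.dropna().to_numpy(float)),
                "cohort": _fmt_median_iqr(col_full.dropna().to_numpy(float)),
                "suppressed": False,
            })
        else:
            levels = sorted(map(str, col_full.dropna().unique()))
            report_levels = [_positive_level(col_full)] if len(levels) <= 2 else levels
            for lev in report_levels:
                n_sub = int((col_sub.astype(str) == lev).sum())
                n_full = int((col_full.astype(str) == lev).sum())
                # suppression applies to every rendered count cell, cohort
                # side included: a 1..6 count is identifying wherever it sits
                rows.append({
                    "variable": name, "statistic": kind, "level": lev if len(levels) > 2 else "",
                    "outliers": _fmt_count(n_sub, len(sub), suppress=True),
                    "cohort": _fmt_count(n_full, len(col_full), suppress=True),
                    "suppressed": _suppress_count(n_sub) or _suppress_count(n_full),
                })
    return ComparisonTable(frame=pd.DataFrame(rows))


@dataclass
class DetectorProvenance:
    detector: str          # "isolation_forest" | "random_forest"
    score: float           # z-score or vote fraction
    detail: str = ""


@dataclass
class CaseNarrative:
    """Structured case narrative for one flagged participant."""

    participant_id: str
    provenance: list[DetectorProvenance]
    feature_highlights: list[tuple[str, float | str, float]]  # (variable, value, robust z)
    risk_factors: list[tuple[str, float | str]]
    interesting_variables: list[str]
    assessment: str = ASSESSMENT_UNREVIEWED
    reasoning: str = ""

    def render_text(self) -> str:
        lines = [f"Participant {self.participant_id}"]
        for p in self.provenance:
            lines.append(f"  flagged by {p.detector} (score {p.score:.3f}) {p.detail}".rstrip())
        fmt = lambda v: f"{v:.1f}" if isinstance(v, float) else str(v)
        lines.append("  Risk factors: " + (
            ", ".join(f"{k}={fmt(v)}" for k, v in self.risk_factors) or "none declared"))
        lines.append("  Most deviant variables (robust z):")
        for name, value, rz in self.feature_highlights:
            lines.append(f"    {name} = {fmt(value)} (z {rz:+.2f})")
        lines.append("  Interesting variables: " + ", ".join(self.interesting_variables))
        lines.append(f"  Assessment: {self.assessment}")
        lines.append(f"  Reasoning: {self.reasoning or '(pending review)'}")
        return "\n".join(lines) + "\n"


def _robust_z(col: pd.Series, value: float) -> float | None:
    vals = col.dropna().to_numpy(float)
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    if mad == 0:
        return None
    return float((value - med) / (1.4826 * mad))


def build_case_narrative(
    participant_id: str,
    table: CohortTable,
    detector_results: list[DetectorProvenance],
    k: int = 5,
) -> CaseNarrative:
    """Assemble the narrative for one flagged participant.

    ``detector_results`` must be non-empty (an unflagged id is a hard
    error).  Highlights are the top-``k`` continuous variables by
    absolute robust z of the participant's value against the cohort.
    Deterministic given the cohort, flags and ``k``.
    """
    if not detector_results:
        raise ValueError(f"participant {participant_id!r} was not flagged by any detector")
    pid = str(participant_id)
    if pid not in table.data.index:
        raise KeyError(f"participant {pid!r} not in table")
    row = table.data.loc[pid]
    deviations = []
    for name in table.feature_columns():
        if table.metadata[name].kind != KIND_CONTINUOUS or pd.isna(row[name]):
            continue
        rz = _robust_z(table.data[name], float(row[name]))
        if rz is not None:
            deviations.append((name, float(row[name]), rz))
    deviations.sort(key=lambda t: (-abs(t[2]), t[0]))
    highlights = deviations[:k]
    risk = [
        (name, row[name])
        for name in table.feature_columns()
        if table.metadata[name].risk_factor
    ]
    return CaseNarrative(
        participant_id=pid,
        provenance=list(detector_results),
        feature_highlights=highlights,
        risk_factors=risk,
        interesting_variables=[name for name, _, _ in highlights],
    )


def summarize_run(assessments: dict[str, dict[str, str]]) -> pd.DataFrame:
    """Per-detector flag and assessment summary.

    ``assessments`` maps detector name -> {participant_id: assessment},
    where assessment is one of unreviewed / potential_novelty /
    natural_deviation.  Percentages are over flagged-and-reviewed rows;
    with zero reviewed rows the percentage columns are rendered as NA.
    """
    rows = []
    for detector, cases in assessments.items():
        total = len(cases)
        novel = sum(1 for a in cases.values() if a == ASSESSMENT_NOVELTY)
        natural = sum(1 for a in cases.values() if a == ASSESSMENT_NATURAL)
        unreviewed = total - novel - natural
        reviewed = novel + natural

        def npct(n: int) -> str:
            if reviewed == 0:
                return f"{n} (NA)"
            return f"{n} ({100.0 * n / reviewed:.1f})"

        rows.append({
            "detector": detector,
            "total_flagged": total,
            "potential_novelty": npct(novel),
            "natural_deviation": npct(natural),
            "unreviewed": unreviewed,
        })
    return pd.DataFrame(rows).set_index("detector")
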