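"""Cohort table and variable-metadata I/O.

The data model shared by every pipeline stage: a participant-by-variable
table (:class:`CohortTable`) in which each cell is a number, a category
token, or missing, plus per-variable metadata (:class:`VariableMetadata`)
declaring its kind (continuous/categorical), its role relative to the
outcome, and any structured "not applicable" missingness rule.

On disk a cohort is a header-row CSV (one row per participant) and the
metadata a YAML document.  Missing cells are encoded as empty fields;
both ``""`` and ``"NA"`` parse to missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MISSING_TOKENS = ("", "NA")

KIND_CONTINUOUS = "continuous"
KIND_CATEGORICAL = "categorical"

ROLE_FEATURE = "feature"
ROLE_OUTCOME = "outcome"
ROLE_OUTCOME_DERIVED = "outcome_derived"
ROLE_RECATEGORIZATION = "recategorization"
ROLE_IDENTIFIER = "identifier"

_VALID_KINDS = {KIND_CONTINUOUS, KIND_CATEGORICAL}
_VALID_ROLES = {
    ROLE_FEATURE,
    ROLE_OUTCOME,
    ROLE_OUTCOME_DERIVED,
    ROLE_RECATEGORIZATION,
    ROLE_IDENTIFIER,
}


class CohortError(ValueError):
    """Raised on invalid cohort tables or metadata."""


@dataclass(frozen=True)
class NotApplicableRule:
    """Structured-missingness rule: when ``gate_variable == gate_value``
    for a row, a missing cell in the dependent variable means "question
    not asked" and is filled with ``fill`` (a numeric sentinel for a
    continuous target, a new category token for a categorical one)
    rather than imputed."""

    gate_variable: str
    gate_value: str
    fill: float | str


@dataclass(frozen=True)
class VariableMetadata:
    """Declared kind, role and gating of one cohort variable."""

    name: str
    kind: str
    role: str = ROLE_FEATURE
    recategorization_of: str | None = None
    gate: NotApplicableRule | None = None
    risk_factor: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise CohortError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        if self.role not in _VALID_ROLES:
            raise CohortError(f"variable {self.name!r}: unknown role {self.role!r}")
        if self.role == ROLE_RECATEGORIZATION and not self.recategorization_of:
            raise CohortError(
                f"variable {self.name!r}: role {ROLE_RECATEGORIZATION} requires "
                "recategorization_of"
            )


@dataclass(frozen=True)
class OutcomeSpec:
    """The binary study outcome: which column, and which token is positive."""

    column: str
    positive_label: str


@dataclass
class CohortTable:
    """One row per participant, typed columns, explicit missing cells.

    ``data`` is indexed by participant id (opaque strings).  Continuous
    columns are float64 with NaN for missing; categorical columns are
    object dtype holding string tokens with NaN for missing.
    """

    data: pd.DataFrame
    metadata: dict[str, VariableMetadata]
    outcome: OutcomeSpec | None = None
    n_unparseable: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        idx = self.data.index
        if idx.hasnans or (idx.astype(str) == "").any():
            raise CohortError("participant_id values must be non-missing")
        if not idx.is_unique:
            dups = idx[idx.duplicated()].unique().tolist()
            raise CohortError(f"duplicate participant_id values: {dups}")
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            dups = sorted({c for c in cols if cols.count(c) > 1})
            raise CohortError(f"duplicate column names in table: {dups}")
        missing_meta = [c for c in cols if c not in self.metadata]
        extra_meta = [m for m in self.metadata if m not in cols]
        if missing_meta or extra_meta:
            raise CohortError(
                "metadata/column mismatch: "
                f"columns without metadata {missing_meta}, "
                f"metadata without columns {extra_meta}"
            )
        recat_targets = [
            m.recategorization_of
            for m in self.metadata.values()
            if m.role == ROLE_RECATEGORIZATION
        ]
        unknown = [t for t in recat_targets if t not in self.metadata]
        if unknown:
            raise CohortError(f"recategorization_of targets unknown variables: {unknown}")
        n_outcomes = sum(1 for m in self.metadata.values() if m.role == ROLE_OUTCOME)
        if self.outcome is not None and n_outcomes != 1:
            raise CohortError(f"exactly one variable must have role outcome, got {n_outcomes}")

    # -- convenience ------------------------------------------------------
    @property
    def participant_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    def feature_columns(self) -> list[str]:
        """Columns usable as model features (everything but outcome/identifier)."""
        return [
            c
            for c in self.data.columns
            if self.metadata[c].role not in (ROLE_OUTCOME, ROLE_IDENTIFIER)
        ]

    def copy(self) -> "CohortTable":
        return CohortTable(
            data=self.data.copy(),
            metadata=dict(self.metadata),
            outcome=self.outcome,
            n_unparseable=self.n_unparseable,
        )

    def drop_columns(self, names: list[str]) -> "CohortTable":
        dropped = set(names)
        keep_meta = {}
        for k, v in self.metadata.items():
            if k in dropped:
                continue
            if v.recategorization_of in dropped:
                # source gone: the survivor stands on its own
                v = VariableMetadata(name=v.name, kind=v.kind, role=ROLE_FEATURE,
                                     gate=v.gate, risk_factor=v.risk_factor)
            keep_meta[k] = v
        return CohortTable(
            data=self.data.drop(columns=list(names)),
            metadata=keep_meta,
            outcome=self.outcome,
            n_unparseable=self.n_unparseable,
        )


def read_metadata(path: str | Path) -> tuple[dict[str, VariableMetadata], OutcomeSpec | None]:
    """Parse a YAML variable-metadata file.

    Schema::

        variables:
          age: {kind: continuous, role: feature}
          age_group: {kind: categorical, role: recategorization, recategorization_of: age}
          cigs_per_day:
            kind: continuous
            gate: {variable: smoker, value: "no", fill: 0}
        outcome: {column: preeclampsia, positive_label: "yes"}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "variables" not in doc:
        raise CohortError(f"metadata file {path}: expected a mapping with a 'variables' key")
    meta: dict[str, VariableMetadata] = {}
    for name, entry in doc["variables"].items():
        entry = dict(entry or {})
        gate = None
        if "gate" in entry and entry["gate"] is not None:
            g = entry["gate"]
            gate = NotApplicableRule(
                gate_variable=str(g["variable"]),
                gate_value=str(g["value"]),
                fill=g["fill"] if isinstance(g["fill"], (int, float)) else str(g["fill"]),
            )
        meta[str(name)] = VariableMetadata(
            name=str(name),
            kind=entry.get("kind", KIND_CONTINUOUS),
            role=entry.get("role", ROLE_FEATURE),
            recategorization_of=entry.get("recategorization_of"),
            gate=gate,
            risk_factor=bool(entry.get("risk_factor", False)),
        )
    outcome = None
    if doc.get("outcome"):
        outcome = OutcomeSpec(
            column=str(doc["outcome"]["column"]),
            positive_label=str(doc["outcome"]["positive_label"]),
        )
        if outcome.column in meta and meta[outcome.column].role != ROLE_OUTCOME:
            meta[outcome.column] = VariableMetadata(
                name=outcome.column,
                kind=meta[outcome.column].kind,
                role=ROLE_OUTCOME,
            )
    return meta, outcome


def write_metadata(
    metadata: Mapping[str, VariableMetadata],
    outcome: OutcomeSpec | None,
    path: str | Path,
    identifier: str | None = "participant_id",
) -> None:
    doc: dict = {"variables": {}}
    if identifier and identifier not in metadata:
        doc["variables"][identifier] = {"kind": "categorical", "role": "identifier"}
    for name, m in metadata.items():
        entry: dict = {"kind": m.kind, "role": m.role}
        if m.recategorization_of:
            entry["recategorization_of"] = m.recategorization_of
        if m.gate is not None:
            entry["gate"] = {
                "variable": m.gate.gate_variable,
                "value": m.gate.gate_value,
                "fill": m.gate.fill,
            }
        if m.risk_factor:
            entry["risk_factor"] = True
        doc["variables"][name] = entry
    if outcome is not None:
        doc["outcome"] = {"column": outcome.column, "positive_label": outcome.positive_label}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_cohort(table_path: str | Path, metadata_path: str | Path) -> CohortTable:
    """Read a cohort CSV plus its metadata into a typed :class:`CohortTable`.

    Cells equal to ``""`` or ``"NA"`` become missing.  In continuous
    columns any other unparseable token also becomes missing, with the
    total count logged as a warning and recorded on the table.
    Duplicate participant ids or a metadata/column mismatch are hard
    errors.  If no column has role ``identifier``, the row index is
    promoted to participant id with a logged warning.
    """
    metadata, outcome = read_metadata(metadata_path)
    raw = pd.read_csv(
        table_path,
        dtype=str,
        keep_default_na=False,
        na_values=list(MISSING_TOKENS),
        skipinitialspace=False,
    )
    # pandas mangles duplicate headers to "x.1"; detect from the raw header line
    with open(table_path) as fh:
        header = fh.readline().rstrip("\n").rstrip("\r").split(",")
    dup_headers = sorted({h for h in header if header.count(h) > 1})
    if dup_headers:
        raise CohortError(f"duplicate column name(s) in header: {dup_headers}")

    id_cols = [n for n, m in metadata.items() if m.role == ROLE_IDENTIFIER]
    if id_cols and id_cols[0] in raw.columns:
        id_col = id_cols[0]
        raw = raw.set_index(id_col)
        raw.index = raw.index.astype(str)
        metadata = {k: v for k, v in metadata.items() if k != id_col}
    else:
        logger.warning("no identifier column declared/present; promoting row index to id")
        raw.index = pd.Index([str(i) for i in range(len(raw))], name="participant_id")

    n_unparseable = 0
    data = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        meta = metadata.get(col)
        if meta is None:
            continue  # validated below via CohortTable
        if meta.kind == KIND_CONTINUOUS:
            numeric = pd.to_numeric(raw[col], errors="coerce")
            bad = numeric.isna() & raw[col].notna()
            n_unparseable += int(bad.sum())
            data[col] = numeric.astype(float)
        else:
            data[col] = raw[col].astype(object)
    # preserve any columns lacking metadata so validation names them
    for col in raw.columns:
        if col not in data.columns:
            data[col] = raw[col]
    if n_unparseable:
        logger.warning("%d unparseable numeric cells set to missing", n_unparseable)
    return CohortTable(data=data, metadata=metadata, outcome=outcome, n_unparseable=n_unparseable)


def write_table(table: CohortTable, path: str | Path) -> None:
    """Write the cohort as CSV; missing cells become empty fields.

    ``read_cohort(write_table(t), meta)`` reproduces ``t`` cell for cell,
    and repeated writes of the same table are byte-identical.
    """
    out = table.data.copy()
    out.index.name = out.index.name or "participant_id"
    out.to_csv(path, na_rep="")
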