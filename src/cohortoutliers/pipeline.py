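"""End-to-end pipeline: simulate/load -> filter -> gate-fill -> impute ->
detect (isolation forest + extreme misclassification) -> report.

One dataset is analyzed at a time; a configuration listing several
datasets to pool is rejected (the two source studies were analyzed
separately, never combined, and this pipeline preserves that contract).
A master seed deterministically derives every stage seed, and the run
manifest records the configuration snapshot, seeds, per-stage row and
column counts, chosen hyperparameters and SHA-256 digests of every
output file, so a run is reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reporting
from .contextual import (
    ForestSearchSpec,
    SplitSpec,
    classification_report,
    detect_contextual_outliers,
)
from .io import CohortError, CohortTable, read_cohort, write_metadata, write_table
from .point import IsolationConfig, detect_point_outliers
from .preprocess import ImputationConfig, apply_gate_fills, filter_variables, impute_iterative
from .reporting import DetectorProvenance, build_case_narrative, characterize_outliers, summarize_run
from .synthetic import SyntheticSpec, generate_cohort

logger = logging.getLogger(__name__)

ISOLATION_FOREST = "isolation_forest"
RANDOM_FOREST = "random_forest_misclassification"


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml`` for schema)."""

    seed: int = 2022
    source: str = "synthetic"               # synthetic | csv
    table_path: str | None = None
    metadata_path: str | None = None
    synthetic: dict = field(default_factory=dict)
    imputation: dict = field(default_factory=dict)
    isolation: dict = field(default_factory=dict)
    tune_isolation: bool = False
    split: dict = field(default_factory=dict)   # train_n/test_n/validation_n
    threshold: float = 0.90
    fixed_forest_params: dict | None = None
    search: dict = field(default_factory=dict)
    holdout_only: bool = False
    narrative_k: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        if "datasets" in doc:
            raise CohortError(
                "config lists multiple datasets; each dataset must be analyzed "
                "separately — datasets are not combined"
            )
        ds = doc.get("dataset", {})
        source = ds.get("source", "synthetic")
        if source not in ("synthetic", "csv"):
            raise CohortError(f"config field dataset.source: unknown value {source!r}")
        if source == "csv" and not (ds.get("table") and ds.get("metadata")):
            raise CohortError("config fields dataset.table and dataset.metadata are required for csv source")
        known = {"dataset", "seed", "imputation", "isolation", "misclassification", "narrative_k"}
        unknown = sorted(set(doc) - known)
        if unknown:
            raise CohortError(f"unknown config field(s): {unknown}")
        mis = doc.get("misclassification", {})
        return cls(
            seed=int(doc.get("seed", 2022)),
            source=source,
            table_path=ds.get("table"),
            metadata_path=ds.get("metadata"),
            synthetic=ds.get("synthetic", {}),
            imputation=doc.get("imputation", {}),
            isolation=doc.get("isolation", {}),
            tune_isolation=bool(doc.get("isolation", {}).get("tune", False)),
            split=mis.get("split", {}),
            threshold=float(mis.get("threshold", 0.90)),
            fixed_forest_params=mis.get("fixed_params"),
            search=mis.get("search", {}),
            holdout_only=bool(mis.get("holdout_only", False)),
            narrative_k=int(doc.get("narrative_k", 5)),
        )


@dataclass
class RunManifest:
    """Everything needed to regenerate a run's outputs."""

    config: dict
    master_seed: int
    stage_seeds: dict[str, int]
    stage_counts: dict[str, dict]
    hyperparameters: dict
    output_digests: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    table: CohortTable
    anomaly: "object"
    misclassification: "object"
    manifest: RunManifest
    out_dir: Path


def run_pipeline(config: PipelineConfig | str | Path, out_dir: str | Path) -> PipelineResult:
    """Execute the full flow on one dataset and write all artifacts.

    Outputs under ``out_dir``: the post-imputation cohort, exclusion
    log, both per-row flag files, characterization tables, case
    narratives, a run summary and the manifest.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: derive_seed(config.seed, s) for s in
             ("synthetic", "imputation", "split", "search", "forest")}

    # ---- acquire --------------------------------------------------------
    if config.source == "synthetic":
        spec = SyntheticSpec(**{**config.synthetic, "seed": seeds["synthetic"]})
        table, meta, truth = generate_cohort(spec)
        truth.to_json(out / "truth.json")
        write_metadata(meta, table.outcome, out / "metadata.yml")
    else:
        table = read_cohort(config.table_path, config.metadata_path)
    counts = {"input": {"rows": len(table.data), "columns": len(table.columns),
                        "missing_cells": table.n_missing()}}
    logger.info("input: %d rows x %d columns, %d missing cells",
                len(table.data), len(table.columns), table.n_missing())

    # ---- preprocess -----------------------------------------------------
    table, excl = filter_variables(table)
    excl.to_csv(out / "exclusions.csv")
    counts["filtered"] = {"rows": len(table.data), "columns": len(table.columns),
                          "dropped_variables": len(excl.entries)}
    table = apply_gate_fills(table)
    imp = ImputationConfig(**{**config.imputation, "seed": seeds["imputation"]})
    table = impute_iterative(table, imp)
    counts["imputed"] = {"rows": len(table.data), "columns": len(table.columns),
                         "missing_cells": table.n_missing()}
    write_table(table, out / "cohort_imputed.csv")
    logger.info("preprocess: %d variables dropped, 0 missing cells remain",
                len(excl.entries))

    # ---- point outliers -------------------------------------------------
    iso_kwargs = {k: v for k, v in config.isolation.items() if k != "tune"}
    iso = IsolationConfig(**iso_kwargs)
    anomaly, tuning = detect_point_outliers(table, iso, tune=config.tune_isolation)
    anomaly.frame.to_csv(out / "point_outliers.csv")
    if tuning is not None:
        tuning.ledger.to_csv(out / "isolation_tuning.csv", index=False)
    counts["point_outliers"] = {"flagged": int(anomaly.frame["is_outlier"].sum())}
    logger.info("isolation forest: %d point outliers flagged",
                counts["point_outliers"]["flagged"])

    # ---- contextual outliers -------------------------------------------
    n = len(table.data)
    split = SplitSpec(
        train_n=int(config.split.get("train_n", round(n * 0.52))),
        test_n=int(config.split.get("test_n", round(n * 0.35))),
        validation_n=int(config.split.get(
            "validation_n",
            n - int(config.split.get("train_n", round(n * 0.52)))
              - int(config.split.get("test_n", round(n * 0.35))))),
        seed=seeds["split"],
    )
    search = ForestSearchSpec(**{**config.search, "seed": seeds["search"]}) \
        if config.fixed_forest_params is None else None
    mis, search_result, model = detect_contextual_outliers(
        table, split,
        search=search,
        fixed_params=config.fixed_forest_params,
        threshold=config.threshold,
        seed=seeds["forest"],
        holdout_only=config.holdout_only,
    )
    mis.frame.to_csv(out / "contextual_outliers.csv")
    if search_result is not None:
        search_result.ledger.to_csv(out / "forest_search_ledger.csv", index=False)
    report = classification_report(mis)
    report.to_csv(out / "classification_report.csv")
    counts["contextual_outliers"] = {"flagged": int(mis.frame["is_outlier"].sum()),
                                     "split": [split.train_n, split.test_n, split.validation_n]}
    logger.info("random forest: %d contextual outliers flagged",
                counts["contextual_outliers"]["flagged"])

    # ---- reporting ------------------------------------------------------
    narratives = []
    provenance: dict[str, list[DetectorProvenance]] = {}
    for pid in anomaly.outlier_ids:
        z = float(anomaly.frame.loc[pid, "z_score"])
        provenance.setdefault(pid, []).append(
            DetectorProvenance(ISOLATION_FOREST, z, "anomaly-score z"))
    for pid in mis.outlier_ids:
        vf = float(mis.frame.loc[pid, "vote_fraction"])
        provenance.setdefault(pid, []).append(
            DetectorProvenance(RANDOM_FOREST, vf, "vote-fraction confidence"))
    for pid, prov in sorted(provenance.items()):
        narratives.append(build_case_narrative(pid, table, prov, k=config.narrative_k))
    (out / "case_narratives.txt").write_text(
        "\n".join(nar.render_text() for nar in narratives) or "no outliers flagged\n")

    for name, ids in ((ISOLATION_FOREST, anomaly.outlier_ids),
                      (RANDOM_FOREST, mis.outlier_ids)):
        if ids:
            comp = characterize_outliers(ids, table)
            comp.to_csv(out / f"characterization_{name}.csv")
            (out / f"characterization_{name}.txt").write_text(comp.render_text())

    summary = summarize_run({
        ISOLATION_FOREST: {pid: reporting.ASSESSMENT_UNREVIEWED for pid in anomaly.outlier_ids},
        RANDOM_FOREST: {pid: reporting.ASSESSMENT_UNREVIEWED for pid in mis.outlier_ids},
    })
    summary.to_csv(out / "summary.csv")

    hyper = {
        "isolation": {"n_estimators": anomaly.n_estimators,
                      "max_samples": anomaly.max_samples,
                      "contamination": iso.contamination,
                      "random_state": anomaly.random_state},
        "forest": (search_result.best_params if search_result is not None
                   else config.fixed_forest_params),
        "threshold": config.threshold,
    }
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        master_seed=config.seed,
        stage_seeds=seeds,
        stage_counts=counts,
        hyperparameters=hyper,
    )
    manifest_path = out / "manifest.json"
    manifest.to_json(manifest_path)
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest.output_digests[f.name] = _sha256(f)
    manifest.to_json(manifest_path)
    return PipelineResult(table=table, anomaly=anomaly, misclassification=mis,
                          manifest=manifest, out_dir=out)
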