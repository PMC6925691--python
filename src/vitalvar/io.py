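"""Shared I/O, configuration, and the end-to-end pipeline runner.

Series travel as long-format CSV (UTF-8, header, '.' decimal):
``patient_id, group, vital_sign, time_offset_min, value`` with one row per
sample; offsets are integer-valued minutes since ICU admission and each
patient's reference moment t0 sits one sampling step after their last
sample.  Feature tables are CSV with ``patient_id, label`` plus 20 feature
columns.  Configuration is a JSON document validated field-by-field before
any stage runs; every pipeline artifact is traceable through a manifest of
SHA-256 checksums keyed by the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd

from .evaluation import evaluate, group_stats
from .features import SIGNS, featurize_cohort
from .models import FAMILIES, fit, stratified_split, tune
from .selection import select_features
from .synthetic import (
    Cohort,
    CohortSpec,
    GeneratorParams,
    SignParams,
    calibrate,
    default_params,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

SERIES_COLUMNS = ["patient_id", "group", "vital_sign", "time_offset_min", "value"]


class SchemaError(ValueError):
    """A table or configuration file violates the published schema."""


def read_timeseries_csv(path) -> pd.DataFrame:
    """Read and validate a long-format cohort series.

    Rejects missing columns, unknown signs/groups, duplicate
    (patient, sign, time) rows and non-numeric values, naming the offending
    CSV row (1-based, header excluded).  Returns the table sorted by
    patient, sign, time.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file — not a cohort series") from None
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows — empty cohort")
    bad_sign = ~df["vital_sign"].isin(SIGNS)
    if bad_sign.any():
        row = int(df.index[bad_sign][0]) + 1
        raise SchemaError(f"{path}: row {row}: unknown vital_sign {df['vital_sign'][bad_sign].iloc[0]!r}")
    bad_group = ~df["group"].isin(("septic", "control"))
    if bad_group.any():
        row = int(df.index[bad_group][0]) + 1
        raise SchemaError(f"{path}: row {row}: unknown group {df['group'][bad_group].iloc[0]!r}")
    for col in ("time_offset_min", "value"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(df.index[numeric.isna()][0]) + 1
            raise SchemaError(f"{path}: row {row}: non-numeric {col}")
        df[col] = numeric
    dup = df.duplicated(subset=["patient_id", "vital_sign", "time_offset_min"])
    if dup.any():
        row = int(df.index[dup][0]) + 1
        raise SchemaError(f"{path}: row {row}: duplicate (patient, sign, time) sample")
    return df.sort_values(["patient_id", "vital_sign", "time_offset_min"], kind="mergesort").reset_index(drop=True)


def write_timeseries_csv(cohort: Cohort, path) -> None:
    cohort.series.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, JSON-serialisable."""

    n_septic: int = 300
    n_control: int = 300
    T_hours: float = 8.0
    horizon_hours: float = 4.0
    sampling_per_hour: int = 6
    feature_set: str = "variability"
    families: tuple[str, ...] = FAMILIES
    train_frac: float = 0.75
    cv_folds: int = 10
    tune_models: bool = False
    calibrate_generator: bool = False
    selection_k: int = 2
    importance_repeats: int = 5
    seed: int = 0
    septic_params: GeneratorParams | None = None
    control_params: GeneratorParams | None = None

    def validate(self) -> None:
        if self.feature_set not in ("variability", "baseline"):
            raise SchemaError(f"feature_set must be variability|baseline, got {self.feature_set!r}")
        unknown = [f for f in self.families if f not in FAMILIES]
        if unknown:
            raise SchemaError(f"unknown model families {unknown}; valid: {list(FAMILIES)}")
        if not 0.0 < self.train_frac < 1.0:
            raise SchemaError("train_frac must be in (0, 1)")
        if self.cv_folds < 2:
            raise SchemaError("cv_folds must be >= 2")
        if self.selection_k < 1 or self.importance_repeats < 1:
            raise SchemaError("selection_k and importance_repeats must be >= 1")
        # CohortSpec re-validates the cohort geometry
        self.cohort_spec()

    def cohort_spec(self) -> CohortSpec:
        try:
            return CohortSpec(
                n_septic=self.n_septic,
                n_control=self.n_control,
                T_hours=self.T_hours,
                sampling_per_hour=self.sampling_per_hour,
                horizon_hours=self.horizon_hours,
                seed=self.seed,
            )
        except ValueError as err:
            raise SchemaError(str(err)) from None

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["families"] = list(self.families)
        for key in ("septic_params", "control_params"):
            if d[key] is not None:
                d[key]["signs"] = {s: asdict(p) for s, p in getattr(self, key).signs.items()}
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown config keys {sorted(unknown)}")
        for key in ("septic_params", "control_params"):
            if data.get(key) is not None:
                gp = dict(data[key])
                gp["signs"] = {
                    s: SignParams(**{**p, "physiologic_bounds": tuple(p["physiologic_bounds"])})
                    for s, p in gp["signs"].items()
                }
                data[key] = GeneratorParams(**gp)
        if "families" in data:
            data["families"] = tuple(data["families"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        try:
            with open(path, encoding="utf-8") as fh:
                data = json.load(fh)
        except json.JSONDecodeError as err:
            raise SchemaError(f"{path}: invalid JSON: {err}") from None
        return cls.from_dict(data)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Manifest and the pipeline runner


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    files: dict[str, str]  # artifact name -> sha256
    created_utc: str = ""

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute simulate -> extract -> select -> train -> evaluate, writing artifacts.

    Fully deterministic under ``config.seed``: running the same config twice
    produces byte-identical CSV/JSON artifacts (manifest timestamps aside).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.cohort_spec()
    files: dict[str, str] = {}

    logger.info("stage=simulate seed=%d n=%d+%d", config.seed, config.n_septic, config.n_control)
    septic = config.septic_params or default_params("septic")
    control = config.control_params or default_params("control")
    if config.calibrate_generator:
        septic = calibrate(septic, seed=config.seed).params
        control = calibrate(control, seed=config.seed).params
    cohort = simulate_cohort(spec, septic, control)
    cohort_path = out / "cohort.csv"
    write_timeseries_csv(cohort, cohort_path)
    files["cohort.csv"] = _sha256(cohort_path)

    logger.info("stage=extract T=%.1f horizon=%.1f set=%s", config.T_hours, config.horizon_hours, config.feature_set)
    feats = featurize_cohort(cohort.series, config.T_hours, config.horizon_hours, config.feature_set)
    feats_path = out / "features.csv"
    feats.to_csv(feats_path)
    files["features.csv"] = _sha256(feats_path)

    stats_path = out / "group_stats.csv"
    group_stats(feats).to_csv(stats_path)
    files["group_stats.csv"] = _sha256(stats_path)

    split = stratified_split(feats, config.train_frac, config.seed)
    train = feats.iloc[split.train_idx]
    test = feats.iloc[split.test_idx]

    logger.info("stage=select families=%s k=%d", ",".join(config.families), config.selection_k)
    selection = select_features(
        train, config.families, k=config.selection_k, n_repeats=config.importance_repeats, seed=config.seed
    )
    sel_path = out / "selected.json"
    with open(sel_path, "w", encoding="utf-8") as fh:
        json.dump({"features": selection.features, "provenance": selection.provenance}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["selected.json"] = _sha256(sel_path)

    train_sel = train[["label"] + selection.features]
    test_sel = test[["label"] + selection.features]
    reports = {}
    for family in config.families:
        logger.info("stage=train family=%s seed=%d", family, config.seed)
        hyper = None
        if config.tune_models:
            hyper = tune(
                family,
                train_sel.drop(columns="label"),
                train_sel["label"].to_numpy(),
                cv_folds=config.cv_folds,
                seed=config.seed,
            )
        fitted = fit(family, train_sel, train_sel["label"].to_numpy(), hyper, seed=config.seed)
        report = evaluate(fitted, test_sel)
        reports[family] = {"hyperparams": fitted.hyperparams, **report.as_dict()}
    eval_path = out / "evaluation.json"
    with open(eval_path, "w", encoding="utf-8") as fh:
        json.dump(reports, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["evaluation.json"] = _sha256(eval_path)

    manifest = RunManifest(
        config_hash=config_hash(config),
        seed=config.seed,
        files=files,
        created_utc=datetime.now(timezone.utc).isoformat(),
    )
    manifest.to_json(out / "manifest.json")
    return manifest
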