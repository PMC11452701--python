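"""End-to-end orchestration: synth -> calibrate -> simulate -> biomarkers ->
classify, with a single seed, provenance block, and one report artifact."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import FEATURE_COLUMNS, feature_row, feature_table
from .classify import EvalConfig, evaluate_features
from .cohort import CohortSpec, EffectConfig, PatientRecord, default_cohort_spec, \
    generate_cohort
from .io import twins_to_json, write_cohort_csv
from .model.solver import SolverSettings
from .personalize import CalibrationSettings, calibrate, extract_biomarker_inputs, \
    targets_from_record

log = logging.getLogger("uteroflow")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "process_patient"]


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_npe: int = 12
    n_pe: int = 9
    uterine_resistance_multiplier: float = 1.0
    cohort_csv: str | None = None          # load instead of synthesising
    network: str = "reduced"
    calibration_tol: float = 0.02
    calibration_max_iter: int = 30
    solver: SolverSettings = field(default_factory=SolverSettings)
    eval: EvalConfig = field(default_factory=EvalConfig)
    out_dir: str = "uteroflow_out"
    analysis_side: str = "right"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        solver = SolverSettings(**doc.pop("solver", {}))
        ev = EvalConfig(**doc.pop("eval", {}))
        return cls(solver=solver, eval=ev, **doc)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config: PipelineConfig
    patient_status: dict[str, dict]
    features: pd.DataFrame
    classification: dict | None
    errors: dict[str, str]

    def provenance(self) -> dict:
        return {
            "package": "uteroflow",
            "version": __version__,
            "seed": self.config.seed,
            "config_hash": self.config.digest(),
        }

    def to_json(self, path) -> None:
        doc = {
            "provenance": self.provenance(),
            "config": dataclasses.asdict(self.config),
            "patients": self.patient_status,
            "classification": self.classification,
            "errors": self.errors,
        }
        Path(path).write_text(json.dumps(doc, indent=1, default=str))


def process_patient(record: PatientRecord, config: PipelineConfig):
    """Calibrate one patient and compute their feature row.

    Returns (row_or_None, status dict, model)."""
    settings = CalibrationSettings(
        network=config.network,
        max_iter=config.calibration_max_iter,
        solver=config.solver,
    )
    targets = targets_from_record(record, rel_tol=config.calibration_tol)
    model, result = calibrate(targets, settings)
    status = {
        "converged": model.converged,
        "n_iter": model.n_iter,
        "max_residual": model.max_residual,
    }
    for entry in model.residual_log:
        log.info("calibration id=%s iter=%d max_residual=%.4g",
                 record.id, entry["iteration"],
                 max(entry["residuals"].values()))
    if not model.converged:
        return None, status, model
    inputs = extract_biomarker_inputs(model, result, targets)
    row = feature_row(inputs, result, record, side=config.analysis_side)
    return row, status, model


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    errors: dict[str, str] = {}

    # stage 1: cohort
    if config.cohort_csv:
        from .io import read_cohort_csv
        records = read_cohort_csv(config.cohort_csv)
    else:
        spec = default_cohort_spec(
            n_npe=config.n_npe, n_pe=config.n_pe, seed=config.seed,
            effect=EffectConfig(config.uterine_resistance_multiplier))
        records = generate_cohort(spec)
    write_cohort_csv(records, out / "cohort.csv")

    # stage 2+3: calibration and simulation, per patient
    rows, status, twins = [], {}, {}
    for rec in records:
        try:
            row, st, model = process_patient(rec, config)
        except Exception as exc:  # keep going, report the failure
            errors[rec.id] = f"{type(exc).__name__}: {exc}"
            status[rec.id] = {"converged": False, "error": str(exc)}
            rows.append(None)
            continue
        rows.append(row)
        status[rec.id] = st
        twins[rec.id] = {
            "scale_params": dataclasses.asdict(model.scale_params),
            "R_periph": model.R_periph, "C_syst": model.C_syst,
            "R_ut_right": model.R_ut_right, "R_ut_left": model.R_ut_left,
            "A_aortic_m2": model.A_aortic_m2, "PWV_model": model.PWV_model,
            "converged": model.converged, "n_iter": model.n_iter,
            "residuals": model.residual_log[-1]["residuals"]
            if model.residual_log else {},
        }
    twins_to_json(twins, out / "twins.json")

    # stage 4: feature table
    table = feature_table(rows, [r.id for r in records],
                          [r.group for r in records])
    table.to_csv(out / "features.csv", index=False)

    # stage 5: classification
    classification = None
    try:
        ev = replace(config.eval, seed=config.seed)
        classification = evaluate_features(table, FEATURE_COLUMNS, ev)
    except ValueError as exc:
        errors["classification"] = str(exc)

    report = RunReport(config=config, patient_status=status,
                       features=table, classification=classification,
                       errors=errors)
    report.to_json(out / "report.json")
    return report
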