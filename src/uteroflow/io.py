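"""CSV/JSON I/O for cohorts, waveforms, simulation results and twins."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import DopplerWaveform, PatientRecord
from .model.solver import SimulationResult
from .units import M3S_TO_LMIN, MS_TO_CMS, PA_TO_MMHG

__all__ = [
    "COHORT_COLUMNS",
    "CohortIOError",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_waveform_csv",
    "write_result_csv",
    "twins_to_json",
]

COHORT_COLUMNS = [
    "id", "group", "GA_weeks", "parity", "BMI", "SBP_mmHg", "DBP_mmHg",
    "HR_bpm", "CO_L_per_min", "PWV_m_per_s", "age_years", "weight_kg",
    "S_left_cm_per_s", "D_left_cm_per_s", "S_right_cm_per_s",
    "D_right_cm_per_s", "PI", "RI",
]


class CohortIOError(ValueError):
    pass


def write_cohort_csv(records: list[PatientRecord], path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        rows.append({c: d[c] for c in COHORT_COLUMNS})
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortIOError(f"cohort file missing column(s): {missing}")
    records = []
    for i, row in df.iterrows():
        kwargs = {}
        for c in COHORT_COLUMNS:
            v = row[c]
            if c in ("id", "group"):
                kwargs[c] = str(v)
                continue
            try:
                kwargs[c] = float(v)
            except (TypeError, ValueError):
                raise CohortIOError(f"row {i}: non-numeric value in {c!r}: {v!r}")
        rec = PatientRecord(**kwargs)
        try:
            rec.validate()
        except ValueError as exc:
            raise CohortIOError(f"row {i}: {exc}")
        records.append(rec)
    return records


def write_waveform_csv(wave: DopplerWaveform, path) -> None:
    pd.DataFrame({
        "time_s": wave.time_s,
        "velocity_cm_per_s": wave.velocity_cm_per_s,
    }).to_csv(path, index=False)


def write_result_csv(result: SimulationResult, site: str, path) -> None:
    s = result.sites[site]
    pd.DataFrame({
        "time_s": result.time_s,
        "P_mmHg": s.P * PA_TO_MMHG,
        "Q_mL_per_s": s.Q * 1e6,
        "U_cm_per_s": s.U * MS_TO_CMS,
    }).to_csv(path, index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def twins_to_json(twins: dict[str, dict], path) -> None:
    Path(path).write_text(json.dumps(_jsonable(twins), indent=1))
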