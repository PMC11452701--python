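"""Candidate classifier computation.

Six Buckingham-Pi dimensionless terms built from the personalised model
parameters, the pressure pulsatility index PPI = (P_max - P_min)/P_mean,
the generic resistance index RI = (V_max - V_min)/V_max, and the standard
Doppler pulsatility index PI = (V_max - V_min)/V_mean, assembled into the
per-patient feature table used by the classification stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BiomarkerInputs",
    "WaveformStats",
    "pi_terms",
    "ppi",
    "ri",
    "pi_index",
    "stats_from_arrays",
    "feature_row",
    "feature_table",
    "FEATURE_COLUMNS",
]

# canonical classifier column order of the feature table
FEATURE_COLUMNS = [
    "pi1", "pi2", "pi3", "pi4", "pi5", "pi6",
    "PPI_arc", "RI_arc", "PPI_rad", "RI_rad",
    "PI", "RI", "SBP", "DBP",
]


@dataclass(frozen=True)
class BiomarkerInputs:
    """Model/measurement quantities in coherent SI units."""

    R_ut: float       # Pa s / m^3
    R_periph: float   # Pa s / m^3
    SV: float         # m^3
    CO: float         # m^3 / s
    C_syst: float     # m^3 / Pa
    PWV: float        # m / s
    P_syst: float     # Pa
    dP_pulse: float   # Pa
    A: float          # m^2

    def validate(self) -> None:
        for f in ("R_ut", "R_periph", "SV", "CO", "C_syst", "PWV",
                  "P_syst", "dP_pulse", "A"):
            v = getattr(self, f)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"BiomarkerInputs.{f} must be finite and > 0")
        if not self.dP_pulse < self.P_syst:
            raise ValueError("requires dP_pulse < P_syst")


@dataclass(frozen=True)
class WaveformStats:
    P_max: float
    P_min: float
    P_mean: float
    V_max: float
    V_min: float
    V_mean: float

    def validate(self) -> None:
        if not self.P_max >= self.P_mean >= self.P_min:
            raise ValueError("requires P_max >= P_mean >= P_min")
        if not self.V_max >= self.V_mean >= self.V_min:
            raise ValueError("requires V_max >= V_mean >= V_min")


def stats_from_arrays(P: np.ndarray, U: np.ndarray,
                      t: np.ndarray) -> WaveformStats:
    """Extrema and trapezoidal time-averages over one period."""
    T = float(t[-1] - t[0]) if t[0] != 0 else float(t[-1])
    return WaveformStats(
        P_max=float(np.max(P)), P_min=float(np.min(P)),
        P_mean=float(np.trapezoid(P, t) / T),
        V_max=float(np.max(U)), V_min=float(np.min(U)),
        V_mean=float(np.trapezoid(U, t) / T),
    )


def pi_terms(inputs: BiomarkerInputs) -> dict[str, float]:
    """The six dimensionless terms (computed in SI, hence unit-free)."""
    inputs.validate()
    return {
        "pi1": inputs.R_ut / inputs.R_periph,
        "pi2": inputs.SV ** 2 / inputs.A ** 3,
        "pi3": inputs.CO * inputs.R_periph / inputs.P_syst,
        "pi4": inputs.C_syst * inputs.P_syst / inputs.A ** 1.5,
        "pi5": inputs.R_periph * inputs.A * inputs.PWV / inputs.P_syst,
        "pi6": inputs.dP_pulse / inputs.P_syst,
    }


def ppi(stats: WaveformStats) -> float:
    """Pressure pulsatility index (P_max - P_min)/P_mean."""
    if stats.P_mean <= 0:
        raise ValueError(f"PPI requires P_mean > 0, got {stats.P_mean}")
    return (stats.P_max - stats.P_min) / stats.P_mean


def ri(stats: WaveformStats) -> float:
    """Resistance index (V_max - V_min)/V_max."""
    if stats.V_max <= 0:
        raise ValueError(f"RI requires V_max > 0, got {stats.V_max}")
    return (stats.V_max - stats.V_min) / stats.V_max


def pi_index(stats: WaveformStats) -> float:
    """Pulsatility index (V_max - V_min)/V_mean."""
    if stats.V_mean <= 0:
        raise ValueError(f"PI requires V_mean > 0, got {stats.V_mean}")
    return (stats.V_max - stats.V_min) / stats.V_mean


def feature_row(inputs: BiomarkerInputs, result, record,
                side: str = "right") -> dict[str, float]:
    """One patient's classifier values (downstream waveforms from ``side``)."""
    terms = pi_terms(inputs)
    row: dict[str, float] = dict(terms)
    for level, tag in (("arcuate", "arc"), ("radial", "rad")):
        s = result.sites[f"{level}_{side}"]
        st = stats_from_arrays(s.P, s.U, result.time_s)
        row[f"PPI_{tag}"] = ppi(st)
        row[f"RI_{tag}"] = ri(st)
    row["PI"] = record.PI
    row["RI"] = record.RI
    row["SBP"] = record.SBP_mmHg
    row["DBP"] = record.DBP_mmHg
    return row


def feature_table(rows: list[dict], ids: list[str],
                  groups: list[str]) -> pd.DataFrame:
    """Assemble the feature matrix: id, group, then the 14 classifiers.

    ``rows`` may contain ``None`` for excluded (non-converged) patients;
    those ids are dropped and reported in the frame's ``attrs``."""
    kept, excluded = [], []
    for row, pid, grp in zip(rows, ids, groups):
        if row is None:
            excluded.append(pid)
            continue
        kept.append({"id": pid, "group": grp, **{c: row[c] for c in FEATURE_COLUMNS}})
    df = pd.DataFrame(kept, columns=["id", "group", *FEATURE_COLUMNS])
    df.attrs["excluded"] = excluded
    return df
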