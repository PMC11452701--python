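"""Synthetic patient cohorts and parametric uterine Doppler waveforms.

A cohort is a list of :class:`PatientRecord` drawn from per-group truncated
normal distributions (independent per parameter, optional left/right and
RI/PI coupling).  The uterine velocity waveform is a piecewise template —
half-sine systolic rise to the peak velocity S followed by a shifted
exponential diastolic decay back to the end-diastolic velocity D — whose
decay time constant can be fitted so the waveform's pulsatility index
matches a prescribed value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .units import bpm_to_period_s

__all__ = [
    "ParamSpec",
    "CohortSpec",
    "PatientRecord",
    "DopplerWaveform",
    "WaveformShape",
    "CohortSpecError",
    "generate_cohort",
    "generate_uterine_waveform",
    "fit_shape_to_pi",
    "derive_fields",
    "default_cohort_spec",
]


class CohortSpecError(ValueError):
    """Invalid cohort specification (names the offending field)."""


@dataclass(frozen=True)
class ParamSpec:
    """Truncated-normal marginal for one clinical parameter."""

    mean: float
    sd: float
    lo: float
    hi: float

    def validate(self, name: str) -> None:
        if self.sd < 0:
            raise CohortSpecError(f"{name}: SD must be >= 0, got {self.sd}")
        if not self.lo < self.hi:
            raise CohortSpecError(
                f"{name}: truncation bounds must satisfy lo < hi, got "
                f"[{self.lo}, {self.hi}]"
            )

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(size, float(np.clip(self.mean, self.lo, self.hi)))
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                             size=size, random_state=rng)


# Parameter names sampled per group, in canonical order.
PARAM_NAMES = (
    "GA_weeks", "parity", "BMI", "SBP_mmHg", "DBP_mmHg", "HR_bpm",
    "CO_L_per_min", "PWV_m_per_s", "age_years", "weight_kg", "PI", "RI",
    "S_cm_per_s",
)


@dataclass(frozen=True)
class EffectConfig:
    """Optional group-level haemodynamic effect for the PE group."""

    uterine_resistance_multiplier: float = 1.0


@dataclass(frozen=True)
class CohortSpec:
    n_npe: int
    n_pe: int
    npe: dict[str, ParamSpec]
    pe: dict[str, ParamSpec]
    seed: int = 0
    lr_correlation: float = 0.9  # left/right Doppler velocity correlation
    min_pulse_pressure: float = 20.0  # resample SBP/DBP into this window, mmHg
    max_pulse_pressure: float = 70.0
    effect: EffectConfig = field(default_factory=EffectConfig)

    def validate(self) -> None:
        if self.n_npe < 0:
            raise CohortSpecError(f"n_npe must be >= 0, got {self.n_npe}")
        if self.n_pe < 0:
            raise CohortSpecError(f"n_pe must be >= 0, got {self.n_pe}")
        if not -1.0 <= self.lr_correlation <= 1.0:
            raise CohortSpecError(
                f"lr_correlation must be in [-1, 1], got {self.lr_correlation}")
        for label, dists in (("npe", self.npe), ("pe", self.pe)):
            for name in PARAM_NAMES:
                if name not in dists:
                    raise CohortSpecError(f"{label}: missing parameter {name!r}")
                dists[name].validate(f"{label}.{name}")


# Reference per-group statistics for the default synthetic cohort
# (high-risk mid-gestation pregnancy cohort; NPE = no early-onset disease,
# PE = early-onset disease).  S has no published statistic and uses a
# literature-typical mid-gestation uterine peak-systolic velocity.
_NPE_STATS = {
    "GA_weeks": ParamSpec(23.3, 0.7, 18.0, 30.0),
    "parity": ParamSpec(1.7, 1.4, 0.0, 8.0),
    "BMI": ParamSpec(29.6, 7.3, 16.0, 55.0),
    "SBP_mmHg": ParamSpec(133.9, 13.0, 90.0, 190.0),
    "DBP_mmHg": ParamSpec(89.6, 8.2, 55.0, 125.0),
    "HR_bpm": ParamSpec(91.6, 11.9, 50.0, 140.0),
    "CO_L_per_min": ParamSpec(4.6, 1.4, 2.0, 10.0),
    "PWV_m_per_s": ParamSpec(7.3, 1.7, 3.5, 14.0),
    "age_years": ParamSpec(32.2, 3.7, 16.0, 50.0),
    "weight_kg": ParamSpec(79.0, 22.6, 40.0, 160.0),
    "PI": ParamSpec(0.9, 0.2, 0.3, 3.5),
    "RI": ParamSpec(0.5, 0.1, 0.35, 0.93),
    "S_cm_per_s": ParamSpec(80.0, 15.0, 30.0, 160.0),
}

_PE_STATS = {
    "GA_weeks": ParamSpec(25.2, 2.0, 18.0, 32.0),
    "parity": ParamSpec(0.7, 0.9, 0.0, 8.0),
    "BMI": ParamSpec(28.3, 3.2, 16.0, 55.0),
    "SBP_mmHg": ParamSpec(140.9, 17.6, 90.0, 200.0),
    "DBP_mmHg": ParamSpec(90.7, 12.2, 55.0, 130.0),
    "HR_bpm": ParamSpec(81.9, 11.3, 50.0, 140.0),
    "CO_L_per_min": ParamSpec(6.1, 1.1, 2.0, 11.0),
    "PWV_m_per_s": ParamSpec(8.9, 1.5, 3.5, 15.0),
    "age_years": ParamSpec(34.1, 4.6, 16.0, 50.0),
    "weight_kg": ParamSpec(75.8, 8.5, 40.0, 160.0),
    "PI": ParamSpec(1.7, 0.7, 0.3, 4.5),
    "RI": ParamSpec(0.7, 0.1, 0.45, 0.93),
    "S_cm_per_s": ParamSpec(75.0, 15.0, 30.0, 160.0),
}


def default_cohort_spec(n_npe: int = 12, n_pe: int = 9, seed: int = 0,
                        effect: EffectConfig | None = None) -> CohortSpec:
    """Cohort spec reproducing the reference group statistics."""
    return CohortSpec(
        n_npe=n_npe, n_pe=n_pe,
        npe=dict(_NPE_STATS), pe=dict(_PE_STATS),
        seed=seed, effect=effect or EffectConfig(),
    )


@dataclass(frozen=True)
class PatientRecord:
    id: str
    group: str  # "NPE" or "PE"
    GA_weeks: float
    parity: float
    BMI: float
    SBP_mmHg: float
    DBP_mmHg: float
    HR_bpm: float
    CO_L_per_min: float
    PWV_m_per_s: float
    age_years: float
    weight_kg: float
    S_left_cm_per_s: float
    D_left_cm_per_s: float
    S_right_cm_per_s: float
    D_right_cm_per_s: float
    PI: float
    RI: float
    uterine_resistance_multiplier: float = 1.0

    def validate(self) -> None:
        if self.group not in ("NPE", "PE"):
            raise ValueError(f"{self.id}: group must be NPE or PE, got {self.group}")
        if not self.SBP_mmHg > self.DBP_mmHg > 0:
            raise ValueError(
                f"{self.id}: requires SBP > DBP > 0, got "
                f"{self.SBP_mmHg}/{self.DBP_mmHg}")
        for name in ("HR_bpm", "CO_L_per_min", "PWV_m_per_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.id}: {name} must be positive")
        for side in ("left", "right"):
            s = getattr(self, f"S_{side}_cm_per_s")
            d = getattr(self, f"D_{side}_cm_per_s")
            if not s >= d >= 0:
                raise ValueError(f"{self.id}: requires S >= D >= 0 on {side} side")
        s, d = self.S_right_cm_per_s, self.D_right_cm_per_s
        if s > 0 and abs(self.RI - (s - d) / s) > 1e-9:
            raise ValueError(
                f"{self.id}: RI inconsistent with right-side S/D: "
                f"RI={self.RI}, (S-D)/S={(s - d) / s}")

    def doppler(self, side: str = "right") -> tuple[float, float]:
        """(S, D) in cm/s for one side."""
        return (getattr(self, f"S_{side}_cm_per_s"),
                getattr(self, f"D_{side}_cm_per_s"))


@dataclass(frozen=True)
class WaveformShape:
    """Template parameters: systolic rise fraction and decay constant.

    ``decay_tau_frac`` is the exponential time constant of the diastolic
    decay as a fraction of the cardiac period.
    """

    rise_frac: float = 0.15
    decay_tau_frac: float = 0.25
    n_samples: int = 400


@dataclass(frozen=True)
class DopplerWaveform:
    time_s: np.ndarray
    velocity_cm_per_s: np.ndarray
    S: float
    D: float

    @property
    def period_s(self) -> float:
        return float(self.time_s[-1])

    @property
    def v_mean(self) -> float:
        return float(np.trapezoid(self.velocity_cm_per_s, self.time_s)
                     / self.period_s)

    @property
    def ri(self) -> float:
        if self.S <= 0:
            return 0.0
        return (self.S - self.D) / self.S

    @property
    def pi(self) -> float:
        vm = self.v_mean
        if vm <= 0:
            raise ValueError("PI undefined for non-positive mean velocity")
        return (self.S - self.D) / vm


def _template_profile(n: int, rise_frac: float, tau_frac: float) -> np.ndarray:
    """Normalised profile g on n+1 uniform samples of [0, 1]: g(0)=g(1)=0,
    max g = 1 attained at the (snapped) end of the systolic rise."""
    k = max(1, min(n - 1, round(rise_frac * n)))
    s = np.arange(n + 1) / n
    g = np.empty(n + 1)
    t1 = k / n
    g[: k + 1] = np.sin(0.5 * math.pi * s[: k + 1] / t1)
    # shifted exponential reaching exactly 0 at s = 1
    tail = s[k:] - t1
    e_end = math.exp(-(1.0 - t1) / tau_frac)
    g[k:] = (np.exp(-tail / tau_frac) - e_end) / (1.0 - e_end)
    g[k] = 1.0
    g[-1] = 0.0
    return g


def _profile_mean(rise_frac: float, tau_frac: float, n: int = 2000) -> float:
    g = _template_profile(n, rise_frac, tau_frac)
    return float(np.trapezoid(g, np.arange(n + 1) / n))


def generate_uterine_waveform(S: float, D: float, HR: float,
                              shape: WaveformShape | None = None) -> DopplerWaveform:
    """Parametric one-period uterine velocity waveform with exact S and D."""
    if S < D:
        raise ValueError(f"requires S >= D, got S={S}, D={D}")
    if D < 0:
        raise ValueError(f"requires D >= 0, got D={D}")
    shape = shape or WaveformShape()
    T = bpm_to_period_s(HR)
    n = shape.n_samples
    t = np.linspace(0.0, T, n + 1)
    g = _template_profile(n, shape.rise_frac, shape.decay_tau_frac)
    v = D + (S - D) * g
    return DopplerWaveform(time_s=t, velocity_cm_per_s=v, S=float(S), D=float(D))


def pi_feasible_range(RI: float, rise_frac: float = 0.15,
                      tau_lo: float = 0.02, tau_hi: float = 20.0) -> tuple[float, float]:
    """PI values attainable by the template at a given RI (V_mean in (D, S))."""
    g_lo = _profile_mean(rise_frac, tau_lo)
    g_hi = _profile_mean(rise_frac, tau_hi)
    ratio = (1.0 - RI) / RI if RI > 0 else math.inf
    return 1.0 / (g_hi + ratio), 1.0 / (g_lo + ratio)


def fit_shape_to_pi(S: float, D: float, HR: float, PI: float,
                    rise_frac: float = 0.15) -> WaveformShape:
    """Solve the decay constant so the template waveform has the given PI.

    Requires S > D (a pulsatile waveform) and a PI inside the feasible
    range of :func:`pi_feasible_range`.
    """
    if S <= D:
        raise ValueError("PI fitting requires S > D")
    tau_lo, tau_hi = 0.02, 20.0
    # target normalised mean: V_mean = D + (S-D) g_mean and PI = (S-D)/V_mean
    g_target = 1.0 / PI - D / (S - D)
    g_min = _profile_mean(rise_frac, tau_lo)
    g_max = _profile_mean(rise_frac, tau_hi)
    if not g_min < g_target < g_max:
        raise ValueError(
            f"PI={PI} outside template-feasible range for RI={(S - D) / S:.3f}")
    tau = brentq(lambda x: _profile_mean(rise_frac, x) - g_target,
                 tau_lo, tau_hi, xtol=1e-10)
    return WaveformShape(rise_frac=rise_frac, decay_tau_frac=float(tau))


def derive_fields(record: PatientRecord) -> dict[str, float]:
    """Stroke volume (mL), pulse pressure and MAP (mmHg) from a record."""
    record.validate()
    sv_ml = record.CO_L_per_min * 1000.0 / record.HR_bpm
    pp = record.SBP_mmHg - record.DBP_mmHg
    return {
        "SV_mL": sv_ml,
        "pulse_pressure_mmHg": pp,
        "MAP_mmHg": record.DBP_mmHg + pp / 3.0,
    }


def _correlated_pair(rng: np.random.Generator, spec: ParamSpec,
                     corr: float, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Two truncated-normal samples with Gaussian-copula correlation."""
    z1 = rng.standard_normal(size)
    z2 = corr * z1 + math.sqrt(max(0.0, 1.0 - corr * corr)) * rng.standard_normal(size)
    a = (spec.lo - spec.mean) / spec.sd if spec.sd > 0 else 0.0
    b = (spec.hi - spec.mean) / spec.sd if spec.sd > 0 else 0.0
    if spec.sd == 0:
        v = np.full(size, float(np.clip(spec.mean, spec.lo, spec.hi)))
        return v, v.copy()
    from scipy.stats import norm
    u1 = norm.cdf(z1)
    u2 = norm.cdf(z2)
    x1 = truncnorm.ppf(np.clip(u1, 1e-12, 1 - 1e-12), a, b,
                       loc=spec.mean, scale=spec.sd)
    x2 = truncnorm.ppf(np.clip(u2, 1e-12, 1 - 1e-12), a, b,
                       loc=spec.mean, scale=spec.sd)
    return x1, x2


def _sample_group(rng: np.random.Generator, dists: dict[str, ParamSpec],
                  n: int, group: str, id_offset: int,
                  lr_corr: float, rut_mult: float,
                  min_pp: float, max_pp: float) -> list[PatientRecord]:
    records: list[PatientRecord] = []
    for i in range(n):
        draws: dict[str, float] = {}
        for name in ("GA_weeks", "parity", "BMI", "HR_bpm", "CO_L_per_min",
                     "PWV_m_per_s", "age_years", "weight_kg"):
            draws[name] = float(dists[name].sample(rng, 1)[0])
        # resample until SBP exceeds DBP by a plausible pulse pressure
        for _ in range(1000):
            sbp = float(dists["SBP_mmHg"].sample(rng, 1)[0])
            dbp = float(dists["DBP_mmHg"].sample(rng, 1)[0])
            if min_pp <= sbp - dbp <= max_pp and dbp > 0:
                break
        else:  # pragma: no cover - bounds would have to be pathological
            raise CohortSpecError("could not draw SBP > DBP within 1000 tries")

        ri_r, ri_l = _correlated_pair(rng, dists["RI"], lr_corr, 1)
        ri_r, ri_l = float(ri_r[0]), float(ri_l[0])
        s_r, s_l = _correlated_pair(rng, dists["S_cm_per_s"], lr_corr, 1)
        s_r, s_l = float(s_r[0]), float(s_l[0])
        # PI must be template-compatible with the drawn (right-side) RI
        pi_lo, pi_hi = pi_feasible_range(ri_r)
        pspec = dists["PI"]
        margin = 0.02 * (pi_hi - pi_lo)
        lo = max(pspec.lo, pi_lo + margin)
        hi = min(pspec.hi, pi_hi - margin)
        if lo >= hi:
            pi = 0.5 * (pi_lo + pi_hi)
        else:
            pi = float(ParamSpec(pspec.mean, pspec.sd, lo, hi).sample(rng, 1)[0])

        d_r = s_r * (1.0 - ri_r)
        d_l = s_l * (1.0 - ri_l)
        rec = PatientRecord(
            id=f"{group}{i + 1}",
            group=group,
            SBP_mmHg=sbp, DBP_mmHg=dbp,
            S_left_cm_per_s=s_l, D_left_cm_per_s=d_l,
            S_right_cm_per_s=s_r, D_right_cm_per_s=d_r,
            PI=pi, RI=ri_r,
            uterine_resistance_multiplier=rut_mult,
            **draws,
        )
        rec.validate()
        records.append(rec)
    return records


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a reproducible synthetic cohort; NPE records first, then PE."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records = _sample_group(rng, spec.npe, spec.n_npe, "NPE", 0,
                            spec.lr_correlation, 1.0,
                            spec.min_pulse_pressure, spec.max_pulse_pressure)
    records += _sample_group(rng, spec.pe, spec.n_pe, "PE", spec.n_npe,
                             spec.lr_correlation,
                             spec.effect.uterine_resistance_multiplier,
                             spec.min_pulse_pressure, spec.max_pulse_pressure)
    return records
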