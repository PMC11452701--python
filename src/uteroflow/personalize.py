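"""Per-patient calibration of the network model ("digital twin").

A damped multiplicative fixed-point loop drives the simulated observables
to the patient's measurements: Windkessel resistance scale -> MAP,
Windkessel compliance scale -> pulse pressure, global stiffness scale ->
PWV (analytic, path-averaged), and per-side uterine-path resistance total /
proximal split -> cycle-mean uterine velocity and resistance index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .cohort import PatientRecord, WaveformShape, _profile_mean, fit_shape_to_pi
from .model.network import ArterialNetwork, ScaleParams, build_default_network, \
    build_reduced_network
from .model.solver import InflowWaveform, SimulationResult, SolverSettings, solve
from .units import CMS_TO_MS, LMIN_TO_M3S, MMHG_TO_PA

__all__ = [
    "MeasurementTargets",
    "CalibrationSettings",
    "PersonalizedModel",
    "CalibrationError",
    "targets_from_record",
    "initial_guess",
    "calibrate",
    "extract_biomarker_inputs",
    "NETWORK_PRESETS",
]

NETWORK_PRESETS: dict[str, Callable[[ScaleParams], ArterialNetwork]] = {
    "reduced": build_reduced_network,
    "full": build_default_network,
}


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MeasurementTargets:
    """Non-invasive targets, clinical units at the boundary."""

    SBP_mmHg: float
    DBP_mmHg: float
    HR_bpm: float
    CO_L_per_min: float
    PWV_m_per_s: float
    S_left_cm_per_s: float
    D_left_cm_per_s: float
    S_right_cm_per_s: float
    D_right_cm_per_s: float
    V_mean_left_cm_per_s: float | None = None
    V_mean_right_cm_per_s: float | None = None
    rel_tol: float = 0.02

    def validate(self) -> None:
        if not self.SBP_mmHg > self.DBP_mmHg > 0:
            raise CalibrationError(
                f"targets require SBP > DBP > 0, got "
                f"{self.SBP_mmHg}/{self.DBP_mmHg}")
        for f in ("HR_bpm", "CO_L_per_min", "PWV_m_per_s"):
            if getattr(self, f) <= 0:
                raise CalibrationError(f"target {f} must be positive")
        for side in ("left", "right"):
            s = getattr(self, f"S_{side}_cm_per_s")
            d = getattr(self, f"D_{side}_cm_per_s")
            if not s >= d >= 0:
                raise CalibrationError(f"targets require S >= D >= 0 ({side})")
            if s <= 0:
                raise CalibrationError(f"target S must be positive ({side})")

    # -- derived, SI -------------------------------------------------------
    @property
    def MAP_pa(self) -> float:
        return (self.DBP_mmHg + (self.SBP_mmHg - self.DBP_mmHg) / 3.0) * MMHG_TO_PA

    @property
    def PP_pa(self) -> float:
        return (self.SBP_mmHg - self.DBP_mmHg) * MMHG_TO_PA

    @property
    def CO_si(self) -> float:
        return self.CO_L_per_min * LMIN_TO_M3S

    @property
    def SV_si(self) -> float:
        return self.CO_si * 60.0 / self.HR_bpm

    def ri(self, side: str) -> float:
        s = getattr(self, f"S_{side}_cm_per_s")
        d = getattr(self, f"D_{side}_cm_per_s")
        return (s - d) / s

    def v_mean_si(self, side: str) -> float:
        v = getattr(self, f"V_mean_{side}_cm_per_s")
        if v is None:
            s = getattr(self, f"S_{side}_cm_per_s")
            d = getattr(self, f"D_{side}_cm_per_s")
            shape = WaveformShape()
            g = _profile_mean(shape.rise_frac, shape.decay_tau_frac)
            v = d + (s - d) * g
        return v * CMS_TO_MS


def targets_from_record(record: PatientRecord,
                        rel_tol: float = 0.02) -> MeasurementTargets:
    """Measurement targets for one patient; the measured PI fixes the
    template mean velocity when it is waveform-compatible."""
    record.validate()
    v_means: dict[str, float | None] = {}
    for side in ("left", "right"):
        s, d = record.doppler(side)
        try:
            shape = fit_shape_to_pi(s, d, record.HR_bpm, record.PI)
            g = _profile_mean(shape.rise_frac, shape.decay_tau_frac)
            v_means[side] = d + (s - d) * g
        except ValueError:
            v_means[side] = None
    return MeasurementTargets(
        SBP_mmHg=record.SBP_mmHg, DBP_mmHg=record.DBP_mmHg,
        HR_bpm=record.HR_bpm, CO_L_per_min=record.CO_L_per_min,
        PWV_m_per_s=record.PWV_m_per_s,
        S_left_cm_per_s=record.S_left_cm_per_s,
        D_left_cm_per_s=record.D_left_cm_per_s,
        S_right_cm_per_s=record.S_right_cm_per_s,
        D_right_cm_per_s=record.D_right_cm_per_s,
        V_mean_left_cm_per_s=v_means["left"],
        V_mean_right_cm_per_s=v_means["right"],
        rel_tol=rel_tol,
    )


@dataclass(frozen=True)
class CalibrationSettings:
    network: str = "reduced"
    max_iter: int = 40
    damping: float = 0.7
    uterine_flow_fraction: float = 0.03   # of CO, per side, for the seed
    solver: SolverSettings = field(default_factory=SolverSettings)
    phi_bounds: tuple[float, float] = (0.005, 0.99)

    def builder(self) -> Callable[[ScaleParams], ArterialNetwork]:
        try:
            return NETWORK_PRESETS[self.network]
        except KeyError:
            raise CalibrationError(f"unknown network preset {self.network!r}")


@dataclass
class PersonalizedModel:
    """Calibrated parameter set and convergence log for one patient."""

    scale_params: ScaleParams
    network_preset: str
    R_periph: float          # Pa s / m^3, MAP_model / CO
    C_syst: float            # m^3 / Pa, summed model compliance
    R_ut_right: float        # Pa s / m^3, (mean P2 - P_ven) / mean Q_ut
    R_ut_left: float
    A_aortic_m2: float       # time-averaged ascending-aortic area
    PWV_model: float
    converged: bool
    n_iter: int
    residual_log: list[dict] = field(default_factory=list)

    @property
    def R_ut(self) -> float:
        """Analysis-side (right) uterine vascular resistance."""
        return self.R_ut_right

    @property
    def max_residual(self) -> float:
        if not self.residual_log:
            return math.nan
        return max(self.residual_log[-1]["residuals"].values())


def initial_guess(record_or_targets,
                  settings: CalibrationSettings | None = None) -> ScaleParams:
    """Physiology-based parameter seed.

    R_periph0 = MAP/CO split between Windkessel and uterine paths (the
    uterine share from an assumed per-side flow fraction of CO), systemic
    compliance seed SV/PP, stiffness scale from inverting the analytic
    path PWV at the measured value.
    """
    settings = settings or CalibrationSettings()
    targets = (record_or_targets if isinstance(record_or_targets, MeasurementTargets)
               else targets_from_record(record_or_targets))
    targets.validate()

    r_periph0 = targets.MAP_pa / targets.CO_si
    q_side = settings.uterine_flow_fraction * targets.CO_si
    base = settings.builder()(ScaleParams())
    r_ut0 = (targets.MAP_pa - ScaleParams().P_ven) / q_side
    g_wk = 1.0 / r_periph0 - 2.0 / r_ut0
    if g_wk <= 0:
        g_wk = 0.5 / r_periph0
    pwv_base = base.analytic_pwv()
    k_beta0 = (targets.PWV_m_per_s / pwv_base) ** 2
    c_syst0 = targets.SV_si / targets.PP_pa
    trial = settings.builder()(replace(ScaleParams(), k_beta=k_beta0))
    c_1d = trial.total_compliance() - sum(
        t.C for t in trial.terminals.values()) - sum(
        c.C_arc + c.C_rad for c in trial.cascades.values())
    c_wk0 = max(0.2 * c_syst0, c_syst0 - c_1d)
    return replace(
        ScaleParams(),
        R_wk_total=1.0 / g_wk,
        C_wk_total=c_wk0,
        k_beta=k_beta0,
        R_ut_total_left=r_ut0,
        R_ut_total_right=r_ut0,
    )


def _observe(net: ArterialNetwork, result: SimulationResult) -> dict[str, float]:
    root = result.stats("aortic_root")
    obs = {
        "MAP": root["P_mean"],
        "PP": root["P_max"] - root["P_min"],
        "PWV": net.analytic_pwv(),
    }
    for side in ("left", "right"):
        s = result.stats(f"uterine_mid_{side}")
        obs[f"Umean_{side}"] = s["V_mean"]
        obs[f"RI_{side}"] = (s["V_max"] - s["V_min"]) / s["V_max"] \
            if s["V_max"] > 0 else math.nan
    return obs


def calibrate(targets: MeasurementTargets,
              settings: CalibrationSettings | None = None,
              seed_params: ScaleParams | None = None) -> tuple[
                  PersonalizedModel, SimulationResult]:
    """Fixed-point calibration; returns the personalised model and the
    final converged simulation."""
    settings = settings or CalibrationSettings()
    targets.validate()
    params = seed_params or initial_guess(targets, settings)
    builder = settings.builder()
    lam = settings.damping
    tol = targets.rel_tol

    inflow = InflowWaveform(CO_m3_per_s=targets.CO_si, HR_bpm=targets.HR_bpm)
    goal = {
        "MAP": targets.MAP_pa, "PP": targets.PP_pa,
        "PWV": targets.PWV_m_per_s,
        "Umean_left": targets.v_mean_si("left"),
        "Umean_right": targets.v_mean_si("right"),
        "RI_left": targets.ri("left"), "RI_right": targets.ri("right"),
    }
    # a degenerate Doppler (S == D) removes the RI handle
    active = {k for k, v in goal.items() if v > 0}

    log: list[dict] = []
    state = None
    prev_a0 = None
    result = None
    net = None
    converged = False
    for it in range(1, settings.max_iter + 1):
        net = builder(params)
        flat = net.compile(settings.solver.dx_target_m)
        if state is not None:
            # geometry may have changed (a_scale update): keep the relative
            # distension, not the absolute areas
            state.A = state.A * (flat.a0 / prev_a0)
        prev_a0 = flat.a0
        result = solve(net, inflow, settings.solver, warm_state=state, flat=flat)
        state = result._state
        obs = _observe(net, result)
        residuals = {k: abs(obs[k] / goal[k] - 1.0) for k in active}
        log.append({"iteration": it, "params": params, "residuals": residuals,
                    "observables": obs})
        if max(residuals.values()) <= tol:
            converged = True
            break
        # stall: infeasible target combination pinned at a parameter bound
        if it >= 8:
            recent = [max(e["residuals"].values()) for e in log[-4:]]
            if max(recent) - min(recent) < 1e-4:
                break

        def ratio(key):
            return obs[key] / goal[key]

        updates = {}
        if "MAP" in active:
            updates["R_wk_total"] = params.R_wk_total * ratio("MAP") ** -lam
        if "PP" in active:
            # compliance follows the pulse-pressure mismatch, but authority
            # over PP rests with the aortic size (Z_c ~ 1/A at fixed c0)
            updates["C_wk_total"] = float(np.clip(
                params.C_wk_total * ratio("PP") ** lam, 1e-9, 1e-7))
            step = float(np.clip(ratio("PP") ** (0.5 * lam), 0.8, 1.25))
            updates["a_scale"] = float(np.clip(params.a_scale * step, 0.45, 2.5))
        if "PWV" in active:
            updates["k_beta"] = params.k_beta * (goal["PWV"] / obs["PWV"]) ** 2
        for side in ("left", "right"):
            if f"Umean_{side}" in active:
                updates[f"R_ut_total_{side}"] = np.clip(
                    getattr(params, f"R_ut_total_{side}")
                    * ratio(f"Umean_{side}") ** lam, 1e8, 1e12)
            if f"RI_{side}" in active and np.isfinite(obs[f"RI_{side}"]):
                updates[f"phi_{side}"] = float(np.clip(
                    getattr(params, f"phi_{side}") * ratio(f"RI_{side}") ** lam,
                    *settings.phi_bounds))
        params = replace(params, **updates)

    model = _build_model(net, result, params, settings, targets, log, converged)
    return model, result


def _build_model(net, result, params, settings, targets, log, converged):
    a_stats = result.stats("aorta_asc")
    r_ut = {}
    for side in ("left", "right"):
        s = result.stats(f"uterine_outlet_{side}")
        q = s["Q_mean"]
        r_ut[side] = (s["P_mean"] - params.P_ven) / q if q > 0 else math.inf
    return PersonalizedModel(
        scale_params=params,
        network_preset=settings.network,
        R_periph=result.stats("aortic_root")["P_mean"] / targets.CO_si,
        C_syst=net.total_compliance(),
        R_ut_right=r_ut["right"], R_ut_left=r_ut["left"],
        A_aortic_m2=a_stats["A_mean"],
        PWV_model=net.analytic_pwv(),
        converged=converged,
        n_iter=len(log),
        residual_log=log,
    )


def extract_biomarker_inputs(model: PersonalizedModel,
                             result: SimulationResult,
                             record_or_targets,
                             allow_nonconverged: bool = False):
    """Coherent-SI inputs for the dimensionless biomarker terms."""
    from .biomarkers import BiomarkerInputs

    if not model.converged and not allow_nonconverged:
        raise CalibrationError(
            "model did not converge; pass allow_nonconverged=True to override")
    t = (record_or_targets if isinstance(record_or_targets, MeasurementTargets)
         else targets_from_record(record_or_targets))
    return BiomarkerInputs(
        R_ut=model.R_ut,
        R_periph=model.R_periph,
        SV=t.SV_si,
        CO=t.CO_si,
        C_syst=model.C_syst,
        PWV=t.PWV_m_per_s,
        P_syst=t.SBP_mmHg * MMHG_TO_PA,
        dP_pulse=(t.SBP_mmHg - t.DBP_mmHg) * MMHG_TO_PA,
        A=model.A_aortic_m2,
    )
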