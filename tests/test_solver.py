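import math

import numpy as np
import pytest

from uteroflow.model.network import ScaleParams, build_reduced_network
from uteroflow.model.solver import (InflowWaveform, SolverError, SolverSettings,
                                    periodicity_error, solve)
from uteroflow.units import LMIN_TO_M3S, MMHG_TO_PA

from conftest import single_vessel_network


class TestInflow:
    def test_volume_integral_is_sv(self):
        inflow = InflowWaveform(CO_m3_per_s=8e-5, HR_bpm=75.0)
        t = np.linspace(0, inflow.period_s, 20001)
        vol = np.trapezoid(inflow.sample(t), t)
        assert vol == pytest.approx(inflow.SV_m3, rel=1e-3)

    def test_nonnegative(self):
        inflow = InflowWaveform(CO_m3_per_s=8e-5, HR_bpm=75.0)
        t = np.linspace(0, 3 * inflow.period_s, 5000)
        assert np.all(inflow.sample(t) >= 0)

    def test_validation(self):
        with pytest.raises(ValueError):
            InflowWaveform(CO_m3_per_s=-1e-5, HR_bpm=70).validate()
        with pytest.raises(ValueError):
            InflowWaveform(CO_m3_per_s=1e-5, HR_bpm=70, mode="square").validate()


class TestPeriodicityError:
    def test_identical_cycles(self):
        x = np.random.default_rng(0).normal(size=(4, 100))
        assert periodicity_error(x, x) == 0.0

    def test_transient_decay(self):
        net = build_reduced_network(ScaleParams())
        inflow = InflowWaveform(CO_m3_per_s=4.6 * LMIN_TO_M3S, HR_bpm=90.0)
        r3 = solve(net, inflow, SolverSettings(max_cycles=3, periodicity_tol=0.0))
        r12 = solve(net, inflow, SolverSettings(max_cycles=12, periodicity_tol=0.0))
        assert r12.periodicity_error < r3.periodicity_error


class TestOhmicOracle:
    def test_mean_pressure_drop(self):
        # constant inflow through one vessel into a resistive terminal:
        # steady pressure at the outlet = P_out + Q*(R1+R2)
        r1, r2, c = 2.0e7, 1.6e8, 2.0e-10   # small C -> fast settling
        net = single_vessel_network(r1, r2, c, c0=8.0)
        q = 6.0e-5
        inflow = InflowWaveform(CO_m3_per_s=q, HR_bpm=60.0, mode="constant")
        res = solve(net, inflow, SolverSettings(max_cycles=20,
                                                periodicity_tol=1e-6))
        p_out_drop = res.stats("outlet")["P_mean"] - 666.6
        assert p_out_drop == pytest.approx(q * (r1 + r2), rel=0.01)

    def test_doubling_resistance_doubles_drop(self):
        q = 5.0e-5
        drops = []
        for scale in (1.0, 2.0):
            net = single_vessel_network(2e7 * scale, 1.6e8 * scale, 2e-10, c0=8.0)
            res = solve(net, InflowWaveform(CO_m3_per_s=q, HR_bpm=60.0,
                                            mode="constant"),
                        SolverSettings(max_cycles=20, periodicity_tol=1e-6))
            drops.append(res.stats("outlet")["P_mean"] - 666.6)
        assert drops[1] == pytest.approx(2.0 * drops[0], rel=0.02)


class TestWindkesselDecayOracle:
    def test_diastolic_time_constant(self):
        # stiff, short vessel so the terminal capacitor dominates; inflow is
        # gated to zero in diastole -> P decays towards P_out with tau = R2*C
        r2, c = 2.4e8, 1.2e-9
        net = single_vessel_network(1.5e7, r2, c, length=0.05, c0=28.0)
        inflow = InflowWaveform(CO_m3_per_s=5e-5, HR_bpm=60.0,
                                systolic_fraction=0.3)
        res = solve(net, inflow, SolverSettings(max_cycles=30,
                                                periodicity_tol=1e-5))
        t = res.time_s
        p = res.sites["outlet"].P
        T = res.period_s
        mask = (t > 0.45 * T) & (t < 0.95 * T)   # clear of the ejection phase
        y = np.log(p[mask] - 666.6)
        slope = np.polyfit(t[mask], y, 1)[0]
        tau_fit = -1.0 / slope
        assert tau_fit == pytest.approx(r2 * c, rel=0.05)


class TestConservationAndSymmetry:
    def test_junction_flow_conservation(self):
        net = build_reduced_network(ScaleParams())
        # probe cells adjacent to the aortic junction
        net.sites["parent_end"] = ("aorta", 0.999)
        net.sites["child_a"] = ("upper_body", 0.0)
        net.sites["child_b"] = ("abdominal", 0.0)
        inflow = InflowWaveform(CO_m3_per_s=4.6 * LMIN_TO_M3S, HR_bpm=91.6)
        res = solve(net, inflow,
                    SolverSettings(max_cycles=60, periodicity_tol=1e-5,
                                   dx_target_m=0.02))
        qp = res.stats("parent_end")["Q_mean"]
        qc = res.stats("child_a")["Q_mean"] + res.stats("child_b")["Q_mean"]
        assert abs(qp - qc) / abs(qp) < 0.005

    def test_inflow_mass_balance(self, reduced_result):
        net, res = reduced_result
        q_in = res.stats("aortic_root")["Q_mean"]
        assert q_in == pytest.approx(4.6 * LMIN_TO_M3S, rel=0.01)

    def test_left_right_symmetry(self, reduced_result):
        net, res = reduced_result
        for a, b in (("uterine_mid_left", "uterine_mid_right"),
                     ("arcuate_left", "arcuate_right")):
            pa, pb = res.sites[a].P, res.sites[b].P
            assert np.max(np.abs(pa - pb)) < 1e-6 * np.max(np.abs(pa))

    def test_area_positivity(self, reduced_result):
        net, res = reduced_result
        for s in res.sites.values():
            assert np.all(s.A > 0)
            assert np.all(np.isfinite(s.P))


class TestTransitTimeOracle:
    def test_pulse_foot_speed_matches_formula(self):
        # uniform, essentially frictionless vessel; time the pulse foot
        # between two stations and compare with c = sqrt(beta*sqrt(A)/2rho)
        from uteroflow.model.network import wave_speed
        net = single_vessel_network(3.0e7, 2.0e8, 1.0e-9, length=1.0,
                                    radius=0.008, c0=6.0, mu=1e-6)
        net.sites["x1"] = ("vessel", 0.2)
        net.sites["x2"] = ("vessel", 0.8)
        inflow = InflowWaveform(CO_m3_per_s=1e-5, HR_bpm=60.0,
                                systolic_fraction=0.15)
        res = solve(net, inflow, SolverSettings(max_cycles=1,
                                                periodicity_tol=0.0,
                                                dx_target_m=0.02,
                                                dt_max_s=2e-4,
                                                p_init_pa=1000.0))
        flat = net.compile(0.02)
        n = flat.seg_ncell[0]
        # distance between the two probed cell centres
        c1 = min(n - 1, int(0.2 * n)); c2 = min(n - 1, int(0.8 * n))
        dist = (c2 - c1) * flat.dx[0]

        def foot_time(p):
            base = p[0]
            thresh = base + 0.05 * (p.max() - base)
            return res.time_s[np.argmax(p > thresh)]

        dt_foot = foot_time(res.sites["x2"].P) - foot_time(res.sites["x1"].P)
        seg = net.segments["vessel"]
        c_formula = wave_speed(seg.beta_mid(), seg.a0_prox_m2)
        assert dist / dt_foot == pytest.approx(c_formula, rel=0.05)


class TestStability:
    def test_blowup_reports_segment(self):
        # absurd inflow drives the scheme unstable
        net = single_vessel_network(1e7, 1e8, 1e-10, c0=3.0)
        inflow = InflowWaveform(CO_m3_per_s=5e-2, HR_bpm=60.0)
        with pytest.raises(SolverError, match="vessel"):
            solve(net, inflow, SolverSettings(max_cycles=3))

    def test_nonconvergence_flagged(self):
        net = build_reduced_network(ScaleParams())
        inflow = InflowWaveform(CO_m3_per_s=4.6 * LMIN_TO_M3S, HR_bpm=90.0)
        res = solve(net, inflow, SolverSettings(max_cycles=2,
                                                periodicity_tol=1e-12))
        assert not res.converged
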