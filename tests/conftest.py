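import numpy as np
import pytest

from uteroflow.cohort import default_cohort_spec, generate_cohort
from uteroflow.model.network import (ArterialNetwork, ScaleParams,
                                     UteroOvarianCascade, VesselSegment1D,
                                     WindkesselTerminal, build_reduced_network)
from uteroflow.model.solver import InflowWaveform, SolverSettings, solve
from uteroflow.personalize import MeasurementTargets, calibrate
from uteroflow.units import LMIN_TO_M3S


@pytest.fixture(scope="session")
def cohort21():
    return generate_cohort(default_cohort_spec(seed=7))


@pytest.fixture(scope="session")
def npe_targets():
    return MeasurementTargets(
        SBP_mmHg=133.9, DBP_mmHg=89.6, HR_bpm=91.6, CO_L_per_min=4.6,
        PWV_m_per_s=7.3, S_left_cm_per_s=80.0, D_left_cm_per_s=40.0,
        S_right_cm_per_s=80.0, D_right_cm_per_s=40.0,
        V_mean_left_cm_per_s=44.4, V_mean_right_cm_per_s=44.4)


@pytest.fixture(scope="session")
def calibrated_npe(npe_targets):
    """One converged digital twin, shared across tests."""
    model, result = calibrate(npe_targets)
    assert model.converged
    return model, result


@pytest.fixture(scope="session")
def reduced_result():
    """Default reduced-network periodic solution."""
    net = build_reduced_network(ScaleParams())
    inflow = InflowWaveform(CO_m3_per_s=4.6 * LMIN_TO_M3S, HR_bpm=91.6)
    return net, solve(net, inflow,
                      SolverSettings(max_cycles=40, periodicity_tol=2e-4))


def single_vessel_network(r1, r2, c, length=0.2, radius=0.008, c0=6.0,
                          p_out=666.6, mu=4.0e-3, c0_taper=None):
    """One segment with a Windkessel terminal (analytic-oracle rig)."""
    seg = VesselSegment1D("vessel", length, radius,
                          radius if c0_taper is None else c0_taper, c0, None)
    net = ArterialNetwork(
        segments={"vessel": seg},
        terminals={"vessel": WindkesselTerminal(R1=r1, R2=r2, C=c, P_out=p_out)},
        cascades={},
        sites={"inlet": ("vessel", 0.0), "mid": ("vessel", 0.5),
               "outlet": ("vessel", 0.999)},
        cascade_sites={},
        pwv_path=["vessel"],
        mu=mu,
    )
    net.validate()
    return net
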