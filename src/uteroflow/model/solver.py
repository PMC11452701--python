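"""Explicit 1D pulse-wave solver.

Mass/momentum in (A, Q) conservative form with the square-root tube law,
integrated with a two-step Lax-Wendroff (Richtmyer) finite-volume scheme.
Boundaries are coupled through Riemann invariants ``u +/- 4c``: prescribed
periodic inflow at the root, Newton-solved junction continuity (static
pressure + mass), and 0D terminals (three-element Windkessel or the
utero-ovarian RC cascade) advanced semi-implicitly.

The per-cycle inner loop is JIT-compiled with numba; the Python driver
iterates cycles until the periodic state converges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from ..units import MMHG_TO_PA
from .network import ArterialNetwork, FlatNetwork, wave_speed

__all__ = [
    "InflowWaveform",
    "SolverSettings",
    "SiteSeries",
    "SimulationResult",
    "SolverError",
    "solve",
    "periodicity_error",
    "wave_speed",
]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class InflowWaveform:
    """Periodic aortic-root volumetric inflow.

    Pulsatile mode: half-sine systolic ejection over ``systolic_fraction``
    of the period, zero in diastole; one-period integral equals SV = CO/HR.
    Constant mode: steady flow at CO (used by the analytic oracles).
    """

    CO_m3_per_s: float
    HR_bpm: float
    systolic_fraction: float = 0.35
    mode: str = "pulsatile"        # or "constant"

    def validate(self) -> None:
        if self.CO_m3_per_s <= 0 or self.HR_bpm <= 0:
            raise ValueError("inflow requires CO > 0 and HR > 0")
        if not 0.05 < self.systolic_fraction < 0.9:
            raise ValueError("systolic_fraction must be in (0.05, 0.9)")
        if self.mode not in ("pulsatile", "constant"):
            raise ValueError(f"unknown inflow mode {self.mode!r}")

    @property
    def period_s(self) -> float:
        return 60.0 / self.HR_bpm

    @property
    def SV_m3(self) -> float:
        return self.CO_m3_per_s * self.period_s

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Q(t) on arbitrary times (reference implementation)."""
        t = np.asarray(t, dtype=float)
        if self.mode == "constant":
            return np.full_like(t, self.CO_m3_per_s)
        T = self.period_s
        ts = self.systolic_fraction * T
        tc = np.mod(t, T)
        q = np.where(tc < ts,
                     (math.pi * self.SV_m3 / (2.0 * ts)) * np.sin(math.pi * tc / ts),
                     0.0)
        return q


@dataclass(frozen=True)
class SolverSettings:
    dx_target_m: float = 0.04
    cfl: float = 0.5
    max_cycles: int = 20
    periodicity_tol: float = 1e-3
    p_init_pa: float = 85.0 * MMHG_TO_PA
    dt_max_s: float = 2e-3

    def validate(self) -> None:
        if not 0 < self.cfl <= 1:
            raise ValueError("cfl must be in (0, 1]")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")


@dataclass
class SiteSeries:
    P: np.ndarray    # Pa
    Q: np.ndarray    # m^3/s
    A: np.ndarray    # m^2 (nominal, for cascade sites)

    @property
    def U(self) -> np.ndarray:
        return self.Q / self.A


@dataclass
class SimulationResult:
    time_s: np.ndarray
    period_s: float
    sites: dict[str, SiteSeries]
    periodicity_error: float
    converged: bool
    n_cycles: int
    total_compliance: float = float("nan")

    def stats(self, site: str) -> dict[str, float]:
        s = self.sites[site]
        T = self.period_s
        return {
            "P_max": float(np.max(s.P)), "P_min": float(np.min(s.P)),
            "P_mean": float(np.trapezoid(s.P, self.time_s) / T),
            "V_max": float(np.max(s.U)), "V_min": float(np.min(s.U)),
            "V_mean": float(np.trapezoid(s.U, self.time_s) / T),
            "Q_mean": float(np.trapezoid(s.Q, self.time_s) / T),
            "A_mean": float(np.trapezoid(s.A, self.time_s) / T),
        }


def periodicity_error(prev: np.ndarray, cur: np.ndarray) -> float:
    """Relative L2 distance between consecutive-cycle pressure records."""
    denom = float(np.linalg.norm(cur))
    if denom == 0.0:
        return 0.0
    return float(np.linalg.norm(cur - prev) / denom)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _cwave(a, beta, rho):
    return math.sqrt(beta * math.sqrt(a) / (2.0 * rho))


@njit(cache=True, inline="always")
def _ptube(a, a0, beta):
    return beta * (math.sqrt(a) - math.sqrt(a0))


@njit(cache=True)
def _junction_newton(x, w1p, bp, a0p, nch, w2c, bc, a0c, rho):
    """Solve areas at a 1-parent/nch-children junction.

    Unknowns x[0]=A_parent, x[1..nch]=A_child.  Equations: mass balance of
    A*u (u from the invariants) and static-pressure continuity."""
    m = 1 + nch
    J = np.zeros((3, 3))
    r = np.zeros(3)
    for _ in range(30):
        cp = _cwave(x[0], bp, rho)
        up = w1p - 4.0 * cp
        pp = _ptube(x[0], a0p, bp)
        r[0] = -x[0] * up
        J[0, 0] = -(up - cp)
        J[0, 1] = 0.0
        J[0, 2] = 0.0
        for j in range(nch):
            aj = x[1 + j]
            cj = _cwave(aj, bc[j], rho)
            uj = w2c[j] + 4.0 * cj
            r[0] += aj * uj
            J[0, 1 + j] = uj + cj
            r[1 + j] = pp - _ptube(aj, a0c[j], bc[j])
            J[1 + j, 0] = bp / (2.0 * math.sqrt(x[0]))
            J[1 + j, 1 + j] = -bc[j] / (2.0 * math.sqrt(aj))
            J[1 + j, 2 - j] = 0.0  # zero the off slot (nch <= 2)
        # Gaussian elimination with partial pivoting on the m x m block
        for k in range(m):
            piv = k
            big = abs(J[k, k])
            for i2 in range(k + 1, m):
                if abs(J[i2, k]) > big:
                    big = abs(J[i2, k]); piv = i2
            if piv != k:
                for jj in range(m):
                    tmp = J[k, jj]; J[k, jj] = J[piv, jj]; J[piv, jj] = tmp
                tmp = r[k]; r[k] = r[piv]; r[piv] = tmp
            for i2 in range(k + 1, m):
                f = J[i2, k] / J[k, k]
                for jj in range(k, m):
                    J[i2, jj] -= f * J[k, jj]
                r[i2] -= f * r[k]
        dx_ = np.zeros(3)
        for k in range(m - 1, -1, -1):
            s = r[k]
            for jj in range(k + 1, m):
                s -= J[k, jj] * dx_[jj]
            dx_[k] = s / J[k, k]
        conv = True
        for k in range(m):
            step = -dx_[k]
            newx = x[k] + step
            if newx <= 0.1 * x[k]:
                newx = 0.1 * x[k]
            if abs(newx - x[k]) > 1e-12 * x[k]:
                conv = False
            x[k] = newx
        if conv:
            break
    return x


@njit(cache=True, inline="always")
def _terminal_newton(a_guess, w1, beta, a0, r1, pc, rho):
    """Boundary area where the outgoing invariant meets Q = (P - Pc)/R1."""
    a = a_guess
    for _ in range(40):
        c = _cwave(a, beta, rho)
        u = w1 - 4.0 * c
        p = _ptube(a, a0, beta)
        g = a * u - (p - pc) / r1
        dg = (u - c) - beta / (2.0 * math.sqrt(a) * r1)
        da = -g / dg
        newa = a + da
        if newa <= 0.1 * a:
            newa = 0.1 * a
        if abs(newa - a) < 1e-13 * a:
            a = newa
            break
        a = newa
    c = _cwave(a, beta, rho)
    return a, a * (w1 - 4.0 * c)


@njit(cache=True)
def _advance_cycle(A, Q,
                   a0, beta, dxc,
                   seg_first, seg_ncell,
                   jn_parent, jn_nchild, jn_child,
                   term_type, term_ptr,
                   wk_R1, wk_R2, wk_C, wk_Pout, wk_Pc,
                   cs_Rut, cs_Rarc, cs_Rrad, cs_Carc, cs_Crad, cs_Pven,
                   cs_Parc, cs_Prad,
                   rho, cf,
                   inflow_mode, sv, T, ts, dt, nsteps, t0,
                   site_cell, recP, recQ, recA,
                   cs_recParc, cs_recQarc, cs_recPrad, cs_recQrad):
    # Mass is conservative (interface fluxes); momentum uses the advective
    # flux plus a non-conservative -(A/rho) dP/dx term built from interface
    # pressures, which is exactly well-balanced on a tapered vessel at rest.
    N = a0.size
    nseg = seg_first.size
    Pc_ = np.empty(N); Fa = np.empty(N)
    iF1 = np.empty(N + nseg); iFa = np.empty(N + nseg); iP = np.empty(N + nseg)
    xj = np.empty(3); w2c = np.empty(2); bcj = np.empty(2); a0cj = np.empty(2)

    for s in range(nsteps):
        tmid = t0 + (s + 0.5) * dt
        for i in range(N):
            ai = A[i]; qi = Q[i]
            Pc_[i] = beta[i] * (math.sqrt(ai) - math.sqrt(a0[i]))
            Fa[i] = qi * qi / ai

        # interior interfaces (Richtmyer half step)
        for g in range(nseg):
            f0 = seg_first[g]; n = seg_ncell[g]; ofs = f0 + g
            dx = dxc[f0]
            for k in range(1, n):
                i = f0 + k - 1; i1 = i + 1
                abar = 0.5 * (A[i] + A[i1])
                qbar = 0.5 * (Q[i] + Q[i1])
                ah = abar - dt / (2.0 * dx) * (Q[i1] - Q[i])
                qh = (qbar - dt / (2.0 * dx) * (Fa[i1] - Fa[i])
                      - dt / (2.0 * dx) * abar / rho * (Pc_[i1] - Pc_[i])
                      - 0.5 * dt * cf * qbar / abar)
                bh = 0.5 * (beta[i] + beta[i1])
                a0h = 0.5 * (a0[i] + a0[i1])
                iF1[ofs + k] = qh
                iFa[ofs + k] = qh * qh / ah
                iP[ofs + k] = bh * (math.sqrt(ah) - math.sqrt(a0h))

        # root inflow
        if inflow_mode == 0:
            tc = tmid % T
            if tc < ts:
                qin = (math.pi * sv / (2.0 * ts)) * math.sin(math.pi * tc / ts)
            else:
                qin = 0.0
        else:
            qin = sv / T
        i0 = seg_first[0]
        c1 = _cwave(A[i0], beta[i0], rho)
        w2 = Q[i0] / A[i0] - 4.0 * c1
        ab = A[i0]
        for _ in range(40):
            cb = _cwave(ab, beta[i0], rho)
            f = qin / ab - 4.0 * cb - w2
            df = -qin / (ab * ab) - cb / ab
            da = -f / df
            newa = ab + da
            if newa <= 0.1 * A[i0]:
                newa = 0.1 * A[i0]
            if abs(newa - ab) < 1e-13 * ab:
                ab = newa
                break
            ab = newa
        iF1[0] = qin
        iFa[0] = qin * qin / ab
        iP[0] = _ptube(ab, a0[i0], beta[i0])

        # junctions
        for j in range(jn_parent.size):
            p = jn_parent[j]
            ip = seg_first[p] + seg_ncell[p] - 1
            w1p = Q[ip] / A[ip] + 4.0 * _cwave(A[ip], beta[ip], rho)
            nch = jn_nchild[j]
            xj[0] = A[ip]
            for k in range(nch):
                ch = jn_child[j, k]
                ic = seg_first[ch]
                w2c[k] = Q[ic] / A[ic] - 4.0 * _cwave(A[ic], beta[ic], rho)
                bcj[k] = beta[ic]; a0cj[k] = a0[ic]
                xj[1 + k] = A[ic]
            xj = _junction_newton(xj, w1p, beta[ip], a0[ip], nch,
                                  w2c, bcj, a0cj, rho)
            cp = _cwave(xj[0], beta[ip], rho)
            up = w1p - 4.0 * cp
            qp = xj[0] * up
            ofs_p = seg_first[p] + p + seg_ncell[p]
            iF1[ofs_p] = qp
            iFa[ofs_p] = qp * qp / xj[0]
            iP[ofs_p] = _ptube(xj[0], a0[ip], beta[ip])
            for k in range(nch):
                ch = jn_child[j, k]
                ic = seg_first[ch]
                ac = xj[1 + k]
                cc = _cwave(ac, beta[ic], rho)
                uc = w2c[k] + 4.0 * cc
                qc = ac * uc
                ofs_c = seg_first[ch] + ch
                iF1[ofs_c] = qc
                iFa[ofs_c] = qc * qc / ac
                iP[ofs_c] = _ptube(ac, a0[ic], beta[ic])

        # terminals
        for g in range(nseg):
            tt = term_type[g]
            if tt == 0:
                continue
            il = seg_first[g] + seg_ncell[g] - 1
            w1 = Q[il] / A[il] + 4.0 * _cwave(A[il], beta[il], rho)
            ptr = term_ptr[g]
            if tt == 1:
                r1 = wk_R1[ptr]; pc = wk_Pc[ptr]
            else:
                r1 = cs_Rut[ptr]; pc = cs_Parc[ptr]
            ab, qb = _terminal_newton(A[il], w1, beta[il], a0[il], r1, pc, rho)
            ofs = seg_first[g] + g + seg_ncell[g]
            iF1[ofs] = qb
            iFa[ofs] = qb * qb / ab
            iP[ofs] = _ptube(ab, a0[il], beta[il])
            if tt == 1:
                # semi-implicit capacitor update
                r2 = wk_R2[ptr]; ccap = wk_C[ptr]; pout = wk_Pout[ptr]
                wk_Pc[ptr] = ((pc + dt / ccap * (qb + pout / r2))
                              / (1.0 + dt / (ccap * r2)))
            else:
                # backward-Euler 2x2 for the cascade nodes
                g12 = 1.0 / cs_Rarc[ptr]; g2v = 1.0 / cs_Rrad[ptr]
                aC = cs_Carc[ptr] / dt; bC = cs_Crad[ptr] / dt
                a11 = aC + g12; a12 = -g12
                a21 = -g12; a22 = bC + g12 + g2v
                b1 = aC * cs_Parc[ptr] + qb
                b2 = bC * cs_Prad[ptr] + g2v * cs_Pven[ptr]
                det = a11 * a22 - a12 * a21
                p1 = (b1 * a22 - a12 * b2) / det
                p2 = (a11 * b2 - a21 * b1) / det
                cs_Parc[ptr] = p1
                cs_Prad[ptr] = p2

        # update: conservative mass, advective + pressure-gradient momentum
        for g in range(nseg):
            f0 = seg_first[g]; n = seg_ncell[g]; ofs = f0 + g
            dx = dxc[f0]
            for k in range(n):
                i = f0 + k
                anew = A[i] - dt / dx * (iF1[ofs + k + 1] - iF1[ofs + k])
                Q[i] += (-dt / dx * (iFa[ofs + k + 1] - iFa[ofs + k])
                         - dt / dx * A[i] / rho * (iP[ofs + k + 1] - iP[ofs + k])
                         - dt * cf * Q[i] / A[i])
                A[i] = anew

        # records
        for m in range(site_cell.size):
            i = site_cell[m]
            recP[m, s] = _ptube(A[i], a0[i], beta[i])
            recQ[m, s] = Q[i]
            recA[m, s] = A[i]
        for m in range(cs_Parc.size):
            qa = (cs_Parc[m] - cs_Prad[m]) / cs_Rarc[m]
            qr = (cs_Prad[m] - cs_Pven[m]) / cs_Rrad[m]
            cs_recParc[m, s] = cs_Parc[m]
            cs_recQarc[m, s] = qa
            cs_recPrad[m, s] = cs_Prad[m]
            cs_recQrad[m, s] = qr
    return 0


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

@dataclass
class SolverState:
    """Warm-startable solver state (areas, flows, 0D pressures)."""

    A: np.ndarray
    Q: np.ndarray
    wk_Pc: np.ndarray
    cs_Parc: np.ndarray
    cs_Prad: np.ndarray


def _initial_state(flat: FlatNetwork, p_init: float) -> SolverState:
    A = (np.sqrt(flat.a0) + p_init / flat.beta) ** 2
    Q = np.zeros_like(A)
    return SolverState(
        A=A, Q=Q,
        wk_Pc=np.full(flat.wk_R1.size, p_init),
        cs_Parc=np.full(flat.cs_Rut.size, 0.7 * p_init),
        cs_Prad=np.full(flat.cs_Rut.size, 0.4 * p_init),
    )


def solve(network: ArterialNetwork, inflow: InflowWaveform,
          settings: SolverSettings | None = None,
          warm_state: SolverState | None = None,
          flat: FlatNetwork | None = None) -> SimulationResult:
    """Run cycles until the periodic state converges; return the final
    cycle's waveforms at the network's named sites."""
    settings = settings or SolverSettings()
    settings.validate()
    inflow.validate()
    if flat is None:
        flat = network.compile(settings.dx_target_m)

    T = inflow.period_s
    dt_stab = min(flat.stable_dt(settings.cfl), settings.dt_max_s)
    nsteps = max(16, int(math.ceil(T / dt_stab)))
    dt = T / nsteps

    st = warm_state or _initial_state(flat, settings.p_init_pa)
    nsite = len(flat.site_names)
    ncas = len(flat.cs_names)
    recP = np.empty((nsite, nsteps)); recQ = np.empty_like(recP)
    recA = np.empty_like(recP)
    csP1 = np.empty((ncas, nsteps)); csQ1 = np.empty_like(csP1)
    csP2 = np.empty_like(csP1); csQ2 = np.empty_like(csP1)

    inflow_mode = 0 if inflow.mode == "pulsatile" else 1
    ts = inflow.systolic_fraction * T
    sv = inflow.SV_m3

    prevP = None
    err = math.inf
    converged = False
    cyc = 0
    for cyc in range(1, settings.max_cycles + 1):
        _advance_cycle(
            st.A, st.Q,
            flat.a0, flat.beta, flat.dx,
            flat.seg_first, flat.seg_ncell,
            flat.jn_parent, flat.jn_nchild, flat.jn_child,
            flat.term_type, flat.term_ptr,
            flat.wk_R1, flat.wk_R2, flat.wk_C, flat.wk_Pout, st.wk_Pc,
            flat.cs_Rut, flat.cs_Rarc, flat.cs_Rrad, flat.cs_Carc,
            flat.cs_Crad, flat.cs_Pven, st.cs_Parc, st.cs_Prad,
            flat.rho, flat.cf,
            inflow_mode, sv, T, ts, dt, nsteps, (cyc - 1) * T,
            flat.site_cell, recP, recQ, recA,
            csP1, csQ1, csP2, csQ2)
        if not np.all(np.isfinite(st.A)) or np.any(st.A <= 0) \
                or not np.all(np.isfinite(st.Q)):
            bad = int(np.argmin(np.where(np.isfinite(st.A), st.A, -np.inf)))
            seg = _segment_of(flat, bad)
            raise SolverError(
                f"solver blow-up in segment {seg!r} during cycle {cyc}")
        if prevP is not None:
            err = periodicity_error(prevP, recP)
            if err < settings.periodicity_tol:
                converged = True
                break
        prevP = recP.copy()

    time = (np.arange(nsteps) + 1) * dt
    sites: dict[str, SiteSeries] = {}
    for m, name in enumerate(flat.site_names):
        sites[name] = SiteSeries(P=recP[m].copy(), Q=recQ[m].copy(),
                                 A=recA[m].copy())
    for name, (seg, level) in flat.cascade_sites.items():
        ptr = flat.cs_names.index(seg)
        if level == "arcuate":
            sites[name] = SiteSeries(P=csP1[ptr].copy(), Q=csQ1[ptr].copy(),
                                     A=np.full(nsteps, flat.cs_Aarc[ptr]))
        else:
            sites[name] = SiteSeries(P=csP2[ptr].copy(), Q=csQ2[ptr].copy(),
                                     A=np.full(nsteps, flat.cs_Arad[ptr]))

    res = SimulationResult(
        time_s=time, period_s=T, sites=sites,
        periodicity_error=float(err), converged=converged, n_cycles=cyc,
        total_compliance=network.total_compliance(),
    )
    res._state = st  # warm-start handle for calibration loops
    return res


def _segment_of(flat: FlatNetwork, cell: int) -> str:
    for k, name in enumerate(flat.seg_names):
        if flat.seg_first[k] <= cell < flat.seg_first[k] + flat.seg_ncell[k]:
            return name
    return "?"
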