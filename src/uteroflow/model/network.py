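"""Arterial network description: 1D segments, Windkessel terminals and the
utero-ovarian cascade, plus the flat (solver-ready) compilation.

Segments follow the tube law ``P = P_ext + beta*(sqrt(A) - sqrt(A0))`` with
``beta(x) = 2*rho*c0^2/sqrt(A0(x))`` so each segment has a constant
reference wave speed ``c0`` at its unstressed area.  A global stiffness
scale ``k_beta`` multiplies every beta (the personalisation handle for
pulse wave velocity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from ..units import MMHG_TO_PA

__all__ = [
    "VesselSegment1D",
    "WindkesselTerminal",
    "UteroOvarianCascade",
    "ArterialNetwork",
    "ScaleParams",
    "FlatNetwork",
    "NetworkError",
    "build_default_network",
    "build_reduced_network",
    "network_to_yaml",
    "network_from_yaml",
    "wave_speed",
]

BLOOD_RHO = 1060.0   # kg/m^3
BLOOD_MU = 4.0e-3    # Pa s
# Poiseuille-type momentum sink -Cf*Q/A with a polynomial velocity profile
FRICTION_CF = 22.0 * math.pi * BLOOD_MU / BLOOD_RHO


class NetworkError(ValueError):
    pass


def wave_speed(beta: float, A: float, rho: float = BLOOD_RHO) -> float:
    """Tube-law characteristic speed c = sqrt(beta*sqrt(A)/(2*rho))."""
    if beta <= 0 or A <= 0 or rho <= 0:
        raise ValueError("wave_speed requires beta, A, rho > 0")
    return math.sqrt(beta * math.sqrt(A) / (2.0 * rho))


@dataclass(frozen=True)
class VesselSegment1D:
    name: str
    length_m: float
    r_prox_m: float
    r_dist_m: float
    c0_m_per_s: float          # reference wave speed at A0 (before k_beta)
    parent: str | None = None

    def validate(self) -> None:
        if self.length_m <= 0:
            raise NetworkError(f"{self.name}: length must be > 0")
        if self.r_prox_m <= 0 or self.r_dist_m <= 0:
            raise NetworkError(f"{self.name}: radii must be > 0")
        if self.c0_m_per_s <= 0:
            raise NetworkError(f"{self.name}: reference wave speed must be > 0")

    @property
    def a0_prox_m2(self) -> float:
        return math.pi * self.r_prox_m ** 2

    @property
    def a0_dist_m2(self) -> float:
        return math.pi * self.r_dist_m ** 2

    def beta_mid(self, rho: float = BLOOD_RHO) -> float:
        a_mid = math.pi * (0.5 * (self.r_prox_m + self.r_dist_m)) ** 2
        return 2.0 * rho * self.c0_m_per_s ** 2 / math.sqrt(a_mid)


@dataclass(frozen=True)
class WindkesselTerminal:
    R1: float      # Pa s / m^3
    R2: float
    C: float       # m^3 / Pa
    P_out: float   # Pa

    def validate(self, name: str = "terminal") -> None:
        if self.R1 < 0 or self.R2 < 0:
            raise NetworkError(f"{name}: resistances must be >= 0")
        if self.C <= 0:
            raise NetworkError(f"{name}: compliance must be > 0")


@dataclass(frozen=True)
class UteroOvarianCascade:
    """Lumped utero-ovarian bed downstream of one uterine artery.

    Chain: uterine outlet -> R_ut -> [arcuate node: C_arc] -> R_arc ->
    [radial/spiral node: C_rad] -> R_rad -> venous pressure.  "radial"
    stands for the combined radial+spiral compartment.
    """

    R_ut: float
    R_arc: float
    R_rad: float
    C_arc: float
    C_rad: float
    A_arc: float   # nominal area for velocity conversion, m^2
    A_rad: float
    P_ven: float

    def validate(self, name: str = "cascade") -> None:
        for f in ("R_ut", "R_arc", "R_rad", "C_arc", "C_rad", "A_arc", "A_rad"):
            if getattr(self, f) <= 0:
                raise NetworkError(f"{name}: {f} must be > 0")

    @property
    def R_total(self) -> float:
        return self.R_ut + self.R_arc + self.R_rad


@dataclass(frozen=True)
class ScaleParams:
    """Global scale handles applied when building a network.

    ``R_wk_total`` is the net (parallel) resistance of all Windkessel
    terminals; ``C_wk_total`` their summed compliance.  Per-side uterine
    path totals and the proximal split fraction ``phi`` (R_ut / R_total)
    parameterise the cascade.
    """

    R_wk_total: float = 1.9e8
    C_wk_total: float = 8.0e-9
    k_beta: float = 1.0
    a_scale: float = 1.0                # radius scale; Z_c ~ 1/a_scale^2 at fixed c0
    R_ut_total_left: float = 6.0e9
    R_ut_total_right: float = 6.0e9
    phi_left: float = 0.3
    phi_right: float = 0.3
    arc_rad_split: float = 0.6          # distal R share in the arcuate level
    cascade_tau_s: float = 0.18         # RC time constant of each cascade level
    P_out: float = 5.0 * MMHG_TO_PA
    P_ven: float = 3.0 * MMHG_TO_PA

    def validate(self) -> None:
        for f in ("R_wk_total", "C_wk_total", "k_beta", "a_scale",
                  "R_ut_total_left", "R_ut_total_right", "cascade_tau_s"):
            if getattr(self, f) <= 0:
                raise NetworkError(f"scale_params.{f} must be > 0")
        for f in ("phi_left", "phi_right", "arc_rad_split"):
            if not 0.0 < getattr(self, f) < 1.0:
                raise NetworkError(f"scale_params.{f} must be in (0, 1)")


@dataclass
class ArterialNetwork:
    segments: dict[str, VesselSegment1D]
    terminals: dict[str, WindkesselTerminal]
    cascades: dict[str, UteroOvarianCascade]     # keyed by uterine segment
    sites: dict[str, tuple[str, float]]          # name -> (segment, fraction)
    cascade_sites: dict[str, tuple[str, str]]    # name -> (uterine seg, level)
    pwv_path: list[str] = field(default_factory=list)
    rho: float = BLOOD_RHO
    mu: float = BLOOD_MU
    k_beta: float = 1.0

    # -- structure ---------------------------------------------------------
    def root(self) -> str:
        roots = [s.name for s in self.segments.values() if s.parent is None]
        if len(roots) != 1:
            raise NetworkError(f"expected exactly one root segment, got {roots}")
        return roots[0]

    def children(self, name: str) -> list[str]:
        return [s.name for s in self.segments.values() if s.parent == name]

    def validate(self) -> None:
        for seg in self.segments.values():
            seg.validate()
            if seg.parent is not None and seg.parent not in self.segments:
                raise NetworkError(f"{seg.name}: unknown parent {seg.parent!r}")
        root = self.root()
        # reachability (tree rooted at the inflow)
        seen = set()
        stack = [root]
        while stack:
            s = stack.pop()
            if s in seen:
                raise NetworkError(f"cycle detected at segment {s!r}")
            seen.add(s)
            stack.extend(self.children(s))
        if seen != set(self.segments):
            raise NetworkError(f"unreachable segments: {set(self.segments) - seen}")
        for name, term in self.terminals.items():
            term.validate(name)
        for name, cas in self.cascades.items():
            cas.validate(name)
        for name in self.segments:
            kids = self.children(name)
            has_term = name in self.terminals
            has_cas = name in self.cascades
            if kids and (has_term or has_cas):
                raise NetworkError(f"{name}: has both children and a terminal")
            if not kids and not (has_term or has_cas):
                raise NetworkError(f"{name}: leaf segment without terminal")
            if len(kids) > 2:
                raise NetworkError(f"{name}: more than two children unsupported")
        if self.k_beta <= 0:
            raise NetworkError("k_beta must be > 0")

    # -- derived quantities ------------------------------------------------
    def total_compliance(self) -> float:
        """Sum of 1D segment, Windkessel and cascade compliances (m^3/Pa)."""
        c = 0.0
        for seg in self.segments.values():
            # per length dA/dP = 2*sqrt(A0)/beta; integrate over the taper
            n = 32
            x = (np.arange(n) + 0.5) / n
            r = seg.r_prox_m + (seg.r_dist_m - seg.r_prox_m) * x
            a0 = math.pi * r ** 2
            beta = 2.0 * self.rho * seg.c0_m_per_s ** 2 / np.sqrt(a0) * self.k_beta
            c += float(np.sum(2.0 * np.sqrt(a0) / beta) * seg.length_m / n)
        for term in self.terminals.values():
            c += term.C
        for cas in self.cascades.values():
            c += cas.C_arc + cas.C_rad
        return c

    def analytic_pwv(self) -> float:
        """Path length over summed transit time along ``pwv_path`` at A0."""
        if not self.pwv_path:
            raise NetworkError("network has no pwv_path")
        total_l = 0.0
        total_t = 0.0
        for name in self.pwv_path:
            seg = self.segments[name]
            c = wave_speed(seg.beta_mid(self.rho) * self.k_beta,
                           math.pi * (0.5 * (seg.r_prox_m + seg.r_dist_m)) ** 2,
                           self.rho)
            total_l += seg.length_m
            total_t += seg.length_m / c
        return total_l / total_t

    def compile(self, dx_target: float = 0.04) -> "FlatNetwork":
        return _compile(self, dx_target)


@dataclass
class FlatNetwork:
    """Solver-ready flat-array view of an :class:`ArterialNetwork`."""

    seg_names: list[str]
    seg_first: np.ndarray
    seg_ncell: np.ndarray
    a0: np.ndarray
    beta: np.ndarray
    dx: np.ndarray
    jn_parent: np.ndarray
    jn_nchild: np.ndarray
    jn_child: np.ndarray
    term_type: np.ndarray      # per segment: 0 none, 1 windkessel, 2 cascade
    term_ptr: np.ndarray
    wk_R1: np.ndarray
    wk_R2: np.ndarray
    wk_C: np.ndarray
    wk_Pout: np.ndarray
    cs_Rut: np.ndarray
    cs_Rarc: np.ndarray
    cs_Rrad: np.ndarray
    cs_Carc: np.ndarray
    cs_Crad: np.ndarray
    cs_Pven: np.ndarray
    cs_Aarc: np.ndarray
    cs_Arad: np.ndarray
    cs_names: list[str]        # uterine segment per cascade slot
    site_names: list[str]
    site_cell: np.ndarray
    cascade_sites: dict[str, tuple[str, str]]
    rho: float
    cf: float

    @property
    def ncell(self) -> int:
        return int(self.a0.size)

    def stable_dt(self, cfl: float = 0.5, p_max: float = 200 * MMHG_TO_PA,
                  u_margin: float = 2.0) -> float:
        """CFL bound using areas pressurised to ``p_max``."""
        a_p = (np.sqrt(self.a0) + p_max / self.beta) ** 2
        c = np.sqrt(self.beta * np.sqrt(a_p) / (2.0 * self.rho))
        return float(cfl * np.min(self.dx / (c + u_margin)))


def _compile(net: ArterialNetwork, dx_target: float) -> FlatNetwork:
    net.validate()
    # deterministic breadth-first ordering, root first
    order: list[str] = [net.root()]
    i = 0
    while i < len(order):
        order.extend(sorted(net.children(order[i])))
        i += 1
    index = {name: k for k, name in enumerate(order)}

    seg_first, seg_ncell = [], []
    a0_l, beta_l, dx_l = [], [], []
    first = 0
    for name in order:
        seg = net.segments[name]
        n = max(3, int(round(seg.length_m / dx_target)))
        dx = seg.length_m / n
        x = (np.arange(n) + 0.5) * dx
        r = seg.r_prox_m + (seg.r_dist_m - seg.r_prox_m) * x / seg.length_m
        a0 = math.pi * r ** 2
        beta = 2.0 * net.rho * seg.c0_m_per_s ** 2 / np.sqrt(a0) * net.k_beta
        seg_first.append(first)
        seg_ncell.append(n)
        a0_l.append(a0); beta_l.append(beta)
        dx_l.append(np.full(n, dx))
        first += n

    jn_parent, jn_nchild, jn_child = [], [], []
    term_type = np.zeros(len(order), dtype=np.int64)
    term_ptr = np.full(len(order), -1, dtype=np.int64)
    wk = {k: [] for k in ("R1", "R2", "C", "Pout")}
    cs = {k: [] for k in ("Rut", "Rarc", "Rrad", "Carc", "Crad", "Pven",
                          "Aarc", "Arad")}
    cs_names: list[str] = []
    for name in order:
        kids = net.children(name)
        if kids:
            jn_parent.append(index[name])
            jn_nchild.append(len(kids))
            row = [index[k] for k in sorted(kids)]
            jn_child.append(row + [-1] * (2 - len(row)))
        elif name in net.terminals:
            t = net.terminals[name]
            term_type[index[name]] = 1
            term_ptr[index[name]] = len(wk["R1"])
            wk["R1"].append(t.R1); wk["R2"].append(t.R2)
            wk["C"].append(t.C); wk["Pout"].append(t.P_out)
        else:
            c = net.cascades[name]
            term_type[index[name]] = 2
            term_ptr[index[name]] = len(cs["Rut"])
            cs["Rut"].append(c.R_ut); cs["Rarc"].append(c.R_arc)
            cs["Rrad"].append(c.R_rad); cs["Carc"].append(c.C_arc)
            cs["Crad"].append(c.C_rad); cs["Pven"].append(c.P_ven)
            cs["Aarc"].append(c.A_arc); cs["Arad"].append(c.A_rad)
            cs_names.append(name)

    site_names = list(net.sites)
    site_cell = []
    for sname in site_names:
        seg_name, frac = net.sites[sname]
        k = index[seg_name]
        n = seg_ncell[k]
        cell = min(n - 1, int(frac * n))
        site_cell.append(seg_first[k] + cell)

    def arr(x, dtype=np.float64):
        return np.asarray(x, dtype=dtype)

    return FlatNetwork(
        seg_names=order,
        seg_first=arr(seg_first, np.int64),
        seg_ncell=arr(seg_ncell, np.int64),
        a0=np.concatenate(a0_l), beta=np.concatenate(beta_l),
        dx=np.concatenate(dx_l),
        jn_parent=arr(jn_parent or [], np.int64),
        jn_nchild=arr(jn_nchild or [], np.int64),
        jn_child=arr(jn_child, np.int64).reshape(-1, 2) if jn_child
        else np.empty((0, 2), dtype=np.int64),
        term_type=term_type, term_ptr=term_ptr,
        wk_R1=arr(wk["R1"]), wk_R2=arr(wk["R2"]), wk_C=arr(wk["C"]),
        wk_Pout=arr(wk["Pout"]),
        cs_Rut=arr(cs["Rut"]), cs_Rarc=arr(cs["Rarc"]), cs_Rrad=arr(cs["Rrad"]),
        cs_Carc=arr(cs["Carc"]), cs_Crad=arr(cs["Crad"]),
        cs_Pven=arr(cs["Pven"]), cs_Aarc=arr(cs["Aarc"]), cs_Arad=arr(cs["Arad"]),
        cs_names=cs_names,
        site_names=site_names, site_cell=arr(site_cell, np.int64),
        cascade_sites=dict(net.cascade_sites),
        rho=net.rho, cf=22.0 * math.pi * net.mu / net.rho,
    )


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _make_cascade(r_total: float, phi: float, split: float, tau: float,
                  p_ven: float) -> UteroOvarianCascade:
    r_ut = phi * r_total
    r_dist = (1.0 - phi) * r_total
    r_arc = split * r_dist
    r_rad = (1.0 - split) * r_dist
    return UteroOvarianCascade(
        R_ut=r_ut, R_arc=r_arc, R_rad=r_rad,
        C_arc=tau / r_dist, C_rad=0.5 * tau / r_rad,
        A_arc=2.4e-5, A_rad=6.0e-5, P_ven=p_ven,
    )


def _attach_terminals(segments: dict[str, VesselSegment1D],
                      wk_fracs: dict[str, float],
                      uterine_names: tuple[str, str],
                      p: ScaleParams,
                      rho: float) -> tuple[dict, dict]:
    total_f = sum(wk_fracs.values())
    g_wk = 1.0 / p.R_wk_total
    terminals = {}
    for name, f in wk_fracs.items():
        f_n = f / total_f
        r_i = 1.0 / (f_n * g_wk)
        seg = segments[name]
        a_d = seg.a0_dist_m2
        z_c = rho * seg.c0_m_per_s * math.sqrt(p.k_beta) / a_d
        r1 = min(z_c, 0.2 * r_i)
        terminals[name] = WindkesselTerminal(
            R1=r1, R2=r_i - r1, C=p.C_wk_total * f_n, P_out=p.P_out)
    cascades = {
        uterine_names[0]: _make_cascade(p.R_ut_total_left, p.phi_left,
                                        p.arc_rad_split, p.cascade_tau_s,
                                        p.P_ven),
        uterine_names[1]: _make_cascade(p.R_ut_total_right, p.phi_right,
                                        p.arc_rad_split, p.cascade_tau_s,
                                        p.P_ven),
    }
    return terminals, cascades


def _standard_sites(uterine: tuple[str, str], aorta_root_seg: str,
                    aorta_asc_seg: str) -> tuple[dict, dict]:
    sites = {
        "aortic_root": (aorta_root_seg, 0.0),
        "aorta_asc": (aorta_asc_seg, 0.25),
    }
    cas_sites = {}
    for seg, side in zip(uterine, ("left", "right")):
        sites[f"uterine_inlet_{side}"] = (seg, 0.0)
        sites[f"uterine_mid_{side}"] = (seg, 0.5)
        sites[f"uterine_outlet_{side}"] = (seg, 0.999)
        cas_sites[f"arcuate_{side}"] = (seg, "arcuate")
        cas_sites[f"radial_{side}"] = (seg, "radial")
    return sites, cas_sites


def build_reduced_network(scale_params: ScaleParams | None = None) -> ArterialNetwork:
    """Nine-segment desk-scale network: aorta, lumped upper body, abdominal
    aorta, common/internal iliac trunks, uterine arteries, pelvic branches."""
    p = scale_params or ScaleParams()
    p.validate()
    S = VesselSegment1D
    segs = [
        S("aorta", 0.32, 0.0140, 0.0105, 5.2, None),
        S("upper_body", 0.10, 0.0090, 0.0085, 5.5, "aorta"),
        S("abdominal", 0.24, 0.0100, 0.0082, 5.8, "aorta"),
        S("common_iliac_left", 0.12, 0.0048, 0.0040, 6.5, "abdominal"),
        S("common_iliac_right", 0.12, 0.0048, 0.0040, 6.5, "abdominal"),
        S("uterine_left", 0.10, 0.0017, 0.0017, 7.0, "common_iliac_left"),
        S("uterine_right", 0.10, 0.0017, 0.0017, 7.0, "common_iliac_right"),
        S("pelvic_left", 0.09, 0.0040, 0.0036, 7.0, "common_iliac_left"),
        S("pelvic_right", 0.09, 0.0040, 0.0036, 7.0, "common_iliac_right"),
    ]
    segments = {s.name: replace(s, r_prox_m=s.r_prox_m * p.a_scale,
                                r_dist_m=s.r_dist_m * p.a_scale) for s in segs}
    wk_fracs = {"upper_body": 0.48, "pelvic_left": 0.26, "pelvic_right": 0.26}
    terminals, cascades = _attach_terminals(
        segments, wk_fracs, ("uterine_left", "uterine_right"), p, BLOOD_RHO)
    sites, cas_sites = _standard_sites(("uterine_left", "uterine_right"),
                                       "aorta", "aorta")
    net = ArterialNetwork(
        segments=segments, terminals=terminals, cascades=cascades,
        sites=sites, cascade_sites=cas_sites,
        pwv_path=["aorta", "abdominal", "common_iliac_right"],
        k_beta=p.k_beta,
    )
    net.validate()
    return net


def build_default_network(scale_params: ScaleParams | None = None) -> ArterialNetwork:
    """24-segment maternal arterial tree (aorta and major branches down to
    the uterine arteries; other beds truncated to Windkessel terminals)."""
    p = scale_params or ScaleParams()
    p.validate()
    S = VesselSegment1D
    segs = [
        S("asc_aorta", 0.05, 0.0145, 0.0140, 4.8, None),
        S("aortic_arch_a", 0.03, 0.0136, 0.0130, 4.9, "asc_aorta"),
        S("brachiocephalic", 0.035, 0.0063, 0.0060, 5.5, "aortic_arch_a"),
        S("aortic_arch_b", 0.04, 0.0127, 0.0122, 5.0, "aortic_arch_a"),
        S("l_carotid", 0.14, 0.0037, 0.0037, 6.0, "aortic_arch_b"),
        S("aortic_arch_c", 0.04, 0.0120, 0.0115, 5.0, "aortic_arch_b"),
        S("l_subclavian", 0.04, 0.0042, 0.0042, 6.0, "aortic_arch_c"),
        S("thoracic_aorta", 0.16, 0.0112, 0.0100, 5.4, "aortic_arch_c"),
        S("celiac", 0.03, 0.0039, 0.0039, 6.0, "thoracic_aorta"),
        S("abdominal_a", 0.06, 0.0097, 0.0095, 5.8, "thoracic_aorta"),
        S("renal_left", 0.03, 0.0026, 0.0026, 6.5, "abdominal_a"),
        S("abdominal_b", 0.03, 0.0094, 0.0093, 5.8, "abdominal_a"),
        S("renal_right", 0.03, 0.0026, 0.0026, 6.5, "abdominal_b"),
        S("abdominal_c", 0.11, 0.0092, 0.0084, 6.0, "abdominal_b"),
        S("common_iliac_left", 0.06, 0.0046, 0.0044, 6.5, "abdominal_c"),
        S("common_iliac_right", 0.06, 0.0046, 0.0044, 6.5, "abdominal_c"),
        S("external_iliac_left", 0.14, 0.0040, 0.0037, 7.0, "common_iliac_left"),
        S("external_iliac_right", 0.14, 0.0040, 0.0037, 7.0, "common_iliac_right"),
        S("internal_iliac_left", 0.05, 0.0035, 0.0030, 7.0, "common_iliac_left"),
        S("internal_iliac_right", 0.05, 0.0035, 0.0030, 7.0, "common_iliac_right"),
        S("uterine_left", 0.10, 0.0017, 0.0017, 7.0, "internal_iliac_left"),
        S("uterine_right", 0.10, 0.0017, 0.0017, 7.0, "internal_iliac_right"),
        S("pelvic_left", 0.05, 0.0030, 0.0028, 7.0, "internal_iliac_left"),
        S("pelvic_right", 0.05, 0.0030, 0.0028, 7.0, "internal_iliac_right"),
    ]
    segments = {s.name: replace(s, r_prox_m=s.r_prox_m * p.a_scale,
                                r_dist_m=s.r_dist_m * p.a_scale) for s in segs}
    wk_fracs = {
        "brachiocephalic": 0.18, "l_carotid": 0.09, "l_subclavian": 0.09,
        "celiac": 0.20, "renal_left": 0.10, "renal_right": 0.10,
        "external_iliac_left": 0.08, "external_iliac_right": 0.08,
        "pelvic_left": 0.04, "pelvic_right": 0.04,
    }
    terminals, cascades = _attach_terminals(
        segments, wk_fracs, ("uterine_left", "uterine_right"), p, BLOOD_RHO)
    sites, cas_sites = _standard_sites(("uterine_left", "uterine_right"),
                                       "asc_aorta", "asc_aorta")
    net = ArterialNetwork(
        segments=segments, terminals=terminals, cascades=cascades,
        sites=sites, cascade_sites=cas_sites,
        pwv_path=["asc_aorta", "aortic_arch_a", "aortic_arch_b",
                  "aortic_arch_c", "thoracic_aorta", "abdominal_a",
                  "abdominal_b", "abdominal_c", "common_iliac_right",
                  "external_iliac_right"],
        k_beta=p.k_beta,
    )
    net.validate()
    return net


# ---------------------------------------------------------------------------
# YAML round trip
# ---------------------------------------------------------------------------

def network_to_yaml(net: ArterialNetwork, path: str) -> None:
    doc = {
        "version": 1,
        "blood": {"rho": net.rho, "mu": net.mu},
        "k_beta": net.k_beta,
        "segments": [
            {"name": s.name, "parent": s.parent, "length": s.length_m,
             "r_prox": s.r_prox_m, "r_dist": s.r_dist_m, "c0": s.c0_m_per_s}
            for s in net.segments.values()
        ],
        "terminals": {
            n: {"R1": t.R1, "R2": t.R2, "C": t.C, "P_out": t.P_out}
            for n, t in net.terminals.items()
        },
        "cascades": {
            n: {"R_ut": c.R_ut, "R_arc": c.R_arc, "R_rad": c.R_rad,
                "C_arc": c.C_arc, "C_rad": c.C_rad, "A_arc": c.A_arc,
                "A_rad": c.A_rad, "P_ven": c.P_ven}
            for n, c in net.cascades.items()
        },
        "sites": {n: [seg, frac] for n, (seg, frac) in net.sites.items()},
        "cascade_sites": {n: list(v) for n, v in net.cascade_sites.items()},
        "pwv_path": net.pwv_path,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def network_from_yaml(path: str) -> ArterialNetwork:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    segments = {
        d["name"]: VesselSegment1D(
            name=d["name"], length_m=d["length"], r_prox_m=d["r_prox"],
            r_dist_m=d["r_dist"], c0_m_per_s=d["c0"], parent=d["parent"])
        for d in doc["segments"]
    }
    terminals = {n: WindkesselTerminal(**t) for n, t in doc["terminals"].items()}
    cascades = {n: UteroOvarianCascade(**c) for n, c in doc["cascades"].items()}
    net = ArterialNetwork(
        segments=segments, terminals=terminals, cascades=cascades,
        sites={n: (v[0], float(v[1])) for n, v in doc["sites"].items()},
        cascade_sites={n: (v[0], v[1]) for n, v in doc["cascade_sites"].items()},
        pwv_path=list(doc.get("pwv_path", [])),
        rho=doc["blood"]["rho"], mu=doc["blood"]["mu"],
        k_beta=float(doc.get("k_beta", 1.0)),
    )
    net.validate()
    return net
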