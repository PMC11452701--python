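"""Periodic solution of the utero-ovarian RC cascade driven by the
uterine-artery outlet.

The cascade is linear, so the exact periodic response is assembled
harmonic-by-harmonic in the frequency domain.  This also covers the
zero-compliance (purely resistive divider) limit.
"""

from __future__ import annotations

import numpy as np

from .network import UteroOvarianCascade

__all__ = ["cascade_waveforms"]


def cascade_waveforms(P2_t: np.ndarray, Q_ut_t: np.ndarray,
                      cascade: UteroOvarianCascade,
                      period_s: float) -> dict[str, dict[str, np.ndarray]]:
    """Exact periodic arcuate/radial pressures and velocities.

    ``Q_ut_t`` (m^3/s, uniform samples of one period, endpoint excluded)
    drives the chain; ``P2_t`` is accepted for interface symmetry with the
    1D solver and used only to report the proximal drop consistency.
    Returns ``{"arcuate": {...}, "radial": {...}}`` with P (Pa), Q (m^3/s)
    and U (m/s) arrays on the same grid.
    """
    q = np.asarray(Q_ut_t, dtype=float)
    n = q.size
    if n < 2:
        raise ValueError("need at least 2 samples of the driving flow")
    if period_s <= 0:
        raise ValueError("period must be positive")
    cascade.validate()

    g12 = 1.0 / cascade.R_arc
    g2v = 1.0 / cascade.R_rad
    qk = np.fft.rfft(q)
    omega = 2.0 * np.pi * np.fft.rfftfreq(n, d=period_s / n)

    p1k = np.zeros_like(qk, dtype=complex)
    p2k = np.zeros_like(qk, dtype=complex)
    # DC component includes the venous offset
    a11 = g12
    a12 = -g12
    a21 = -g12
    a22 = g12 + g2v
    b1 = qk[0]
    b2 = g2v * cascade.P_ven * n
    det = a11 * a22 - a12 * a21
    p1k[0] = (b1 * a22 - a12 * b2) / det
    p2k[0] = (a11 * b2 - a21 * b1) / det
    # harmonics
    w = omega[1:]
    a11 = 1j * w * cascade.C_arc + g12
    a22 = 1j * w * cascade.C_rad + g12 + g2v
    det = a11 * a22 - g12 * g12
    p1k[1:] = (qk[1:] * a22) / det
    p2k[1:] = (qk[1:] * g12) / det

    p1 = np.fft.irfft(p1k, n=n)
    p2 = np.fft.irfft(p2k, n=n)
    q_arc = g12 * (p1 - p2)
    q_rad = g2v * (p2 - cascade.P_ven)
    return {
        "arcuate": {"P": p1, "Q": q_arc, "U": q_arc / cascade.A_arc},
        "radial": {"P": p2, "Q": q_rad, "U": q_rad / cascade.A_rad},
    }
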