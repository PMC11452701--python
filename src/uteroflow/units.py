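"""Unit conversion constants.

Clinical I/O uses mmHg, cm/s, L/min, bpm; all internal computation is SI
(Pa, m, s, m3/s).
"""

MMHG_TO_PA = 133.322387415
PA_TO_MMHG = 1.0 / MMHG_TO_PA

LMIN_TO_M3S = 1e-3 / 60.0
M3S_TO_LMIN = 1.0 / LMIN_TO_M3S

CMS_TO_MS = 1e-2
MS_TO_CMS = 100.0

ML_TO_M3 = 1e-6
M3_TO_ML = 1e6


def bpm_to_period_s(hr_bpm: float) -> float:
    """Cardiac period T = 60/HR in seconds."""
    if hr_bpm <= 0:
        raise ValueError(f"HR must be positive, got {hr_bpm}")
    return 60.0 / hr_bpm
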