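"""Unit conversion constants.

The library works in strict SI internally (Pa, m, s, kg, m^3).  Clinical
units (mmHg, mL, L/min, mmHg/mL elastances) appear only at I/O boundaries.
"""

MMHG = 133.322  # Pa per mmHg
ML = 1e-6  # m^3 per mL
LMIN = 1e-3 / 60.0  # m^3/s per L/min

#: Pa/m^3 per mmHg/mL (elastance)
MMHG_PER_ML = MMHG / ML
#: Pa.s/m^3 per mmHg.s/mL (resistance)
MMHG_S_PER_ML = MMHG / ML


def pa_to_mmhg(p):
    return p / MMHG


def mmhg_to_pa(p):
    return p * MMHG


def m3s_to_lmin(q):
    return q / LMIN


def lmin_to_m3s(q):
    return q * LMIN
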