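"""Unit conversions.

SI units are used internally everywhere (Pa, m, s, m^3/s).  User-facing I/O
(network files, waveform CSVs, reports) uses the clinical conventions:
pressures in mmHg, lengths in cm, flows in ml/s, areas in cm^2.
"""

MMHG_PA = 133.322

CM_M = 1e-2
CM2_M2 = 1e-4
ML_M3 = 1e-6


def mmhg_to_pa(p):
    return p * MMHG_PA


def pa_to_mmhg(p):
    return p / MMHG_PA


def mls_to_m3s(q):
    return q * ML_M3


def m3s_to_mls(q):
    return q / ML_M3
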