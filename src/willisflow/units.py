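"""Unit conversion between clinical and SI units.

All public interfaces use clinical units (mmHg, mL·min⁻¹); internal solver
arithmetic is coherent SI (Pa, m³·s⁻¹). Pressures are gauge (relative to
atmosphere) throughout.
"""

MMHG_TO_PA = 133.322
MLMIN_TO_M3S = 1e-6 / 60.0


def mmhg_to_pa(p):
    return p * MMHG_TO_PA


def pa_to_mmhg(p):
    return p / MMHG_TO_PA


def mlmin_to_m3s(q):
    return q * MLMIN_TO_M3S


def m3s_to_mlmin(q):
    return q / MLMIN_TO_M3S
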