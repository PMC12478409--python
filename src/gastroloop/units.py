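"""Unit conversions.

The model mixes unit systems (L vs cm^3, cpm vs Hz, kPa vs MPa, nM vs uM)
because each sub-model keeps the units its parameters were reported in.
Every cross-unit conversion in the package goes through this module so the
conversion factors exist in exactly one place.
"""

CM3_PER_L = 1000.0
S_PER_MIN = 60.0
KPA_PER_MPA = 1000.0
NM_PER_UM = 1000.0


def litres_to_cm3(v_l: float) -> float:
    return v_l * CM3_PER_L


def cm3_to_litres(v_cm3: float) -> float:
    return v_cm3 / CM3_PER_L


def cpm_to_hz(f_cpm: float) -> float:
    return f_cpm / S_PER_MIN


def cpm_to_period_s(f_cpm: float) -> float:
    """Slow-wave cycle length t_end = 60/cpm (s)."""
    return S_PER_MIN / f_cpm


def mpa_to_kpa(p_mpa: float) -> float:
    return p_mpa * KPA_PER_MPA


def um_to_nm(c_um: float) -> float:
    return c_um * NM_PER_UM


def nm_to_um(c_nm: float) -> float:
    return c_nm / NM_PER_UM
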