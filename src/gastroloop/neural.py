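"""Vagal afferents, brainstem interneuron maps and autonomic drive.

The sensory side is deliberately simple: mechanoreceptor firing is linear in
the fundic sarcomere stretch, and chemoreceptor firing is linear in the
nutrient volumetric flow rate Q_cal = gamma_max*Omega/g_cal (a fixed caloric
delivery rate divided by caloric density), hard-clamped at 30 Hz.  The
brainstem closes the loop with fitted maps: a logistic curve from
mechanoreceptor firing to the antral cholinergic drive, a ninth-order
polynomial from chemoreceptor firing to the PS tonic NANC drive, and a
piecewise polynomial from total gastric volume to the intramural fundic
NANC drive.  A binary sympathetic flag overrides the parasympathetic
efferents with fixed "fight or flight" frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .params import ParameterRegistry

__all__ = [
    "AfferentSignals",
    "EfferentDrive",
    "mech_firing",
    "nutrient_flow",
    "chem_firing",
    "interneuron_mech",
    "interneuron_chem",
    "intramural_fundus",
    "autonomic_drive",
]


@dataclass(frozen=True)
class AfferentSignals:
    f_mech: float   # Hz
    f_chem: float   # Hz, in [0, 30]
    Q_cal: float    # cm3/s nutrient volumetric flow
    O_sym: int      # {0, 1} sympathetic flag

    def __post_init__(self):
        if self.O_sym not in (0, 1):
            raise ValueError(f"O_sym must be 0 or 1, got {self.O_sym}")


@dataclass(frozen=True)
class EfferentDrive:
    """The eight motor-neuron firing frequencies (Hz)."""

    f_e_to_1: float
    f_i_to_1: float
    f_e_p_2: float
    f_i_p_2: float
    f_e_to_3: float
    f_i_to_3: float
    f_e_p_3: float
    f_i_p_3: float

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


def mech_firing(lam_f_1: float, registry: ParameterRegistry) -> float:
    """Mechanoreceptor afferent rate: linear in stretch, floored at 0 Hz."""
    if lam_f_1 <= 0:
        raise ValueError(f"stretch must be positive, got {lam_f_1}")
    f = (registry.get("afferent.X_mech_a") * lam_f_1
         + registry.get("afferent.X_mech_b"))
    return max(f, 0.0)


def nutrient_flow(g_cal: float, registry: ParameterRegistry) -> float:
    """Nutrient volumetric flow Q_cal = gamma_max*Omega/g_cal (cm3/s).

    For caloric densities below the floor that saturates the chemoreceptor
    at 30 Hz, Q_cal is capped at the saturating value (covers g_cal -> 0).
    """
    if g_cal < 0:
        raise ValueError(f"caloric density must be >= 0, got {g_cal}")
    g = registry.get
    q_cap = ((g("afferent.f_chem_max") - g("afferent.X_chem_b"))
             / g("afferent.X_chem_a"))
    if g_cal == 0.0:
        return q_cap
    return min(g("afferent.gamma_max") * g("afferent.Omega") / g_cal, q_cap)


def chem_firing(q_cal: float, registry: ParameterRegistry) -> float:
    """Chemoreceptor afferent rate: linear in Q_cal, clamped to [0, 30] Hz."""
    if q_cal < 0:
        raise ValueError(f"Q_cal must be >= 0, got {q_cal}")
    g = registry.get
    f = g("afferent.X_chem_a") * q_cal + g("afferent.X_chem_b")
    return min(max(f, 0.0), g("afferent.f_chem_max"))


def interneuron_mech(f_mech: float, registry: ParameterRegistry) -> float:
    """Mechanosensitive afferent->efferent logistic map -> f_e_p_2 (Hz)."""
    if f_mech < 0:
        raise ValueError(f"f_mech must be >= 0, got {f_mech}")
    g = registry.get
    return (g("interneuron.f_min_mech")
            + g("interneuron.f_max_mech")
            * float(expit((f_mech - g("interneuron.f_mid_mech"))
                          / g("interneuron.k_inter_mech"))))


def interneuron_chem(f_chem: float, registry: ParameterRegistry) -> float:
    """Chemosensitive afferent->efferent ninth-order polynomial -> f_i_to_3.

    The polynomial has no constant term (f_i_to_3(0) = 0) and is only valid
    on the fitted domain [0, 30] Hz; extrapolation raises ``ValueError``.
    """
    fmax = registry.get("afferent.f_chem_max")
    if not (0.0 <= f_chem <= fmax):
        raise ValueError(
            f"f_chem={f_chem} outside the fitted domain [0, {fmax}] Hz"
        )
    coeffs = registry.get("interneuron.k_inter_chem")
    out = 0.0
    p = 1.0
    for k in coeffs:
        p *= f_chem
        out += k * p
    return max(out, 0.0)


def intramural_fundus(v_tot: float, registry: ParameterRegistry) -> float:
    """Intramural fundic NANC drive f_i_to_1 (Hz): piecewise polynomial in
    total gastric volume (degree 8 below V_tot_o, degree 9 above)."""
    g = registry.get
    vmin, vmax = g("auxiliary.V_min"), g("auxiliary.V_max")
    if not (vmin <= v_tot <= vmax):
        raise ValueError(
            f"V_tot={v_tot} L outside the physiological bounds "
            f"[{vmin}, {vmax}] L"
        )
    coeffs = (g("interneuron.k_vol_h") if v_tot <= g("interneuron.V_tot_o")
              else g("interneuron.k_vol_l"))
    out = 0.0
    p = 1.0
    for k in coeffs:
        p *= v_tot
        out += k * p
    return max(out, 0.0)


def autonomic_drive(afferents: AfferentSignals,
                    registry: ParameterRegistry,
                    v_tot: float) -> EfferentDrive:
    """Close the loop: afferent signals -> the eight efferent frequencies.

    Sympathetic override (O_sym = 1) pins the antral and PS-tonic efferents
    to the fight-or-flight values irrespective of afferent input; the
    intramural fundic NANC drive remains volume-driven in both states so
    intragastric pressure is maintained.  Phasic PS drives stay at their
    (baseline) configured values in both states.
    """
    g = registry.get
    f_i_to_1 = intramural_fundus(v_tot, registry)
    common = dict(
        f_e_to_1=g("auxiliary.f_e_to_1_base"),
        f_i_to_1=f_i_to_1,
        f_e_p_3=g("auxiliary.f_e_p_3_base"),
        f_i_p_3=g("auxiliary.f_i_p_3_base"),
    )
    if afferents.O_sym == 1:
        return EfferentDrive(
            f_e_p_2=g("auxiliary.sym_f_e_p_2"),
            f_i_p_2=g("auxiliary.sym_f_i_p_2"),
            f_e_to_3=g("auxiliary.sym_f_e_to_3"),
            f_i_to_3=g("auxiliary.sym_f_i_to_3"),
            **common,
        )
    return EfferentDrive(
        f_e_p_2=interneuron_mech(afferents.f_mech, registry),
        f_i_p_2=g("auxiliary.f_i_p_2_base"),
        f_e_to_3=g("auxiliary.f_e_to_3_base"),
        f_i_to_3=interneuron_chem(afferents.f_chem, registry),
        **common,
    )
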