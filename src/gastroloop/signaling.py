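"""Efferent neurotransmitter-release and receptor-response cascades.

Every stage is a Michaelis-Menten/Hill (MMEHC) input-output map evaluated at
quasi-steady state: motor-neuron firing frequency -> junctional transmitter
concentration -> receptor-level fractional response.  Three chains exist:

* fundus (tonic): cholinergic ACh -> Ca2+ rise; NANC VIP -> MLCK inhibition
  and NO -> (downstream) MLCP rise;
* antrum (phasic): cholinergic ACh -> ICC slow-wave amplitude/frequency
  gains; NANC NO -> amplitude/frequency reductions and purinergic ATP ->
  SMC coupling reduction psi;
* pyloric sphincter: a tonic chain reusing the fundic equations with
  index-3 parameters plus a direct inhibitory MMEHC, and a phasic chain
  identical in form to the antrum.

All functions are pure; negative driving frequencies raise ``ValueError`` at
this (public) boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from . import units
from .params import MMEHCParams, ParameterRegistry

logger = logging.getLogger(__name__)

__all__ = [
    "mmehc",
    "FundusSignal",
    "AntrumSignal",
    "PylorusSignal",
    "fundus_cholinergic",
    "fundus_nanc",
    "fundus_signals",
    "antrum_excitatory",
    "antrum_inhibitory",
    "antrum_signals",
    "ps_tonic_inhibition",
    "ps_signals",
]


def mmehc(x: float, params: MMEHCParams) -> float:
    """Saturating Hill response A*x^N/(B^N + x^N).

    Strictly increasing in ``x`` and bounded in ``[0, A)``.
    """
    if x < 0:
        raise ValueError(
            f"MMEHC input for {params.modality!r} must be >= 0, got {x}"
        )
    if x == 0.0:
        return 0.0
    # (B/x)^N form avoids overflow for large x^N; for x << B the response
    # underflows to 0 before the power itself can overflow
    log_ratio = params.N * (math.log(params.B) - math.log(x))
    if log_ratio > 700.0:
        return 0.0
    return params.A / (1.0 + math.exp(log_ratio))


def _check_freq(f: float, name: str) -> float:
    if f < 0:
        raise ValueError(f"firing frequency {name} must be >= 0, got {f}")
    return f


@dataclass(frozen=True)
class FundusSignal:
    Ach_1: float        # uM
    dCa_to_1: float     # uM  cholinergically driven Ca2+ increase
    VIP_1: float        # nM
    NO_1: float         # uM
    phi_ipsi_1: float   # -   MLCK inhibitory fraction


@dataclass(frozen=True)
class AntrumSignal:
    Ach_2: float        # nM
    NO_2: float         # uM
    Pur_2: float        # uM
    phi_ea_2: float     # -  fractional ICC amplitude increase
    phi_ec_2: float     # -  fractional ICC frequency increase
    phi_ia_2: float     # -  fractional ICC amplitude reduction
    phi_ic_2: float     # -  fractional ICC frequency reduction
    phi_ipsi_2: float   # -  fractional SMC amplitude reduction
    psi_2: float        # -  net SMC coupling factor, clamped to [0, 1]


@dataclass(frozen=True)
class PylorusSignal:
    Ach_3: float        # uM   tonic cholinergic
    dCa_to_3: float     # uM
    phi_ih_to_3: float  # -    tonic inhibitory fraction
    phasic: AntrumSignal


def fundus_cholinergic(f_e_to_1: float, registry: ParameterRegistry):
    """Cholinergic chain: firing -> [ACh]_1 -> Ca2+ increase in the SMC."""
    f = _check_freq(f_e_to_1, "f_e_to_1")
    ach = mmehc(f, registry.curve("Ach_to_1"))
    dca = mmehc(ach, registry.curve("Ca_to_1"))
    return ach, dca


def fundus_nanc(f_i_to_1: float, registry: ParameterRegistry):
    """NANC chain: firing -> [VIP] -> MLCK-inhibition fraction, and -> [NO]."""
    f = _check_freq(f_i_to_1, "f_i_to_1")
    vip = mmehc(f, registry.curve("VIP_to_1"))
    phi_ipsi = mmehc(vip, registry.curve("ipsi_to_1"))
    no = mmehc(f, registry.curve("NO_to_1"))
    return vip, no, phi_ipsi


def fundus_signals(f_e_to_1: float, f_i_to_1: float,
                   registry: ParameterRegistry) -> FundusSignal:
    ach, dca = fundus_cholinergic(f_e_to_1, registry)
    vip, no, phi_ipsi = fundus_nanc(f_i_to_1, registry)
    return FundusSignal(Ach_1=ach, dCa_to_1=dca, VIP_1=vip, NO_1=no,
                        phi_ipsi_1=phi_ipsi)


def _antrum_excitatory(f: float, registry: ParameterRegistry, w: int):
    ach = mmehc(f, registry.curve(f"Ach_p_{w}"))
    phi_ea = mmehc(ach, registry.curve(f"ea_p_{w}"))
    phi_ec = mmehc(ach, registry.curve(f"ec_p_{w}"))
    return ach, phi_ea, phi_ec


def _antrum_inhibitory(f: float, registry: ParameterRegistry, w: int):
    no = mmehc(f, registry.curve(f"NO_p_{w}"))           # uM
    no_nM = units.um_to_nm(no)                           # ia/ic curves take nM
    phi_ia = mmehc(no_nM, registry.curve(f"ia_p_{w}"))
    phi_ic = mmehc(no_nM, registry.curve(f"ic_p_{w}"))
    pur = mmehc(f, registry.curve(f"Pur_p_{w}"))         # uM
    phi_ipsi = mmehc(pur, registry.curve(f"ipsi_p_{w}"))
    psi = 1.0 - phi_ipsi
    if psi < 0.0:
        logger.warning(
            "psi_%d clamped to 0 (phi_ipsi=%.3f > 1 at [Pur]=%.3g uM)",
            w, phi_ipsi, pur,
        )
        psi = 0.0
    return no, pur, phi_ia, phi_ic, phi_ipsi, min(psi, 1.0)


def antrum_excitatory(f_e_p_2: float, registry: ParameterRegistry):
    """Cholinergic chain: firing -> [ACh]_2 -> ICC amplitude/frequency gains."""
    f = _check_freq(f_e_p_2, "f_e_p_2")
    return _antrum_excitatory(f, registry, 2)


def antrum_inhibitory(f_i_p_2: float, registry: ParameterRegistry):
    """NANC chain: firing -> [NO], [Pur] -> ICC/SMC inhibitory fractions."""
    f = _check_freq(f_i_p_2, "f_i_p_2")
    return _antrum_inhibitory(f, registry, 2)


def antrum_signals(f_e_p_2: float, f_i_p_2: float,
                   registry: ParameterRegistry) -> AntrumSignal:
    ach, phi_ea, phi_ec = antrum_excitatory(f_e_p_2, registry)
    no, pur, phi_ia, phi_ic, phi_ipsi, psi = antrum_inhibitory(
        f_i_p_2, registry)
    return AntrumSignal(Ach_2=ach, NO_2=no, Pur_2=pur, phi_ea_2=phi_ea,
                        phi_ec_2=phi_ec, phi_ia_2=phi_ia, phi_ic_2=phi_ic,
                        phi_ipsi_2=phi_ipsi, psi_2=psi)


def ps_tonic_inhibition(f_i_to_3: float, registry: ParameterRegistry) -> float:
    """Direct MMEHC inhibitory fraction for PS basal tone (A = 1)."""
    f = _check_freq(f_i_to_3, "f_i_to_3")
    return mmehc(f, registry.curve("ih_to_3"))


def ps_signals(f_e_to_3: float, f_i_to_3: float, f_e_p_3: float,
               f_i_p_3: float, registry: ParameterRegistry) -> PylorusSignal:
    """Pyloric sphincter signal set: tonic (fundus-form, index 3) + phasic
    (antrum-form, index 3) chains."""
    fe = _check_freq(f_e_to_3, "f_e_to_3")
    ach = mmehc(fe, registry.curve("Ach_to_3"))
    dca = mmehc(ach, registry.curve("Ca_to_3"))
    phi_ih = ps_tonic_inhibition(f_i_to_3, registry)
    fep = _check_freq(f_e_p_3, "f_e_p_3")
    fip = _check_freq(f_i_p_3, "f_i_p_3")
    ach_p, phi_ea, phi_ec = _antrum_excitatory(fep, registry, 3)
    no, pur, phi_ia, phi_ic, phi_ipsi, psi = _antrum_inhibitory(
        fip, registry, 3)
    phasic = AntrumSignal(Ach_2=ach_p, NO_2=no, Pur_2=pur, phi_ea_2=phi_ea,
                          phi_ec_2=phi_ec, phi_ia_2=phi_ia, phi_ic_2=phi_ic,
                          phi_ipsi_2=phi_ipsi, psi_2=psi)
    return PylorusSignal(Ach_3=ach, dCa_to_3=dca, phi_ih_to_3=phi_ih,
                         phasic=phasic)
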