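"""Biochemistry-to-force chain shared by all compartments.

Covers the enzyme limb (Ca2+ -> active MLCK; NO -> cGMP -> MLCP), the
four-state Hai-Murphy cross-bridge/latch-bridge kinetics, the
filament-overlap active stress, the polynomial hyperelastic passive stress,
and the nonlinear viscoelastic (dashpot) stretch dynamics.

Conventions
-----------
Myosin fractions are normalised (M + Mp + AMp + AM = 1); published absolute
concentrations are absorbed into the rate constants.  Contractile force is
carried by the attached states: ``bridges = AMp + AM`` (cross-bridges plus
latch bridges).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, fsolve

from . import units
from .params import ParameterRegistry

__all__ = [
    "CrossBridgeState",
    "EnzymePool",
    "StressState",
    "cgmp_from_no",
    "mlcp_from_cgmp",
    "mlck_activation",
    "combine_enzymes",
    "hai_murphy_rhs",
    "hai_murphy_steady_state",
    "total_bridges",
    "active_stress",
    "hyperelastic_stress",
    "viscoelastic_rhs",
    "equilibrium_stretch",
]


@dataclass(frozen=True)
class CrossBridgeState:
    """Hai-Murphy myosin fractions for one contractile system."""

    M: float     # free unphosphorylated
    Mp: float    # free phosphorylated
    AMp: float   # attached phosphorylated (cross-bridge)
    AM: float    # attached dephosphorylated (latch bridge)

    def as_array(self) -> np.ndarray:
        return np.array([self.M, self.Mp, self.AMp, self.AM])

    @property
    def total(self) -> float:
        return self.M + self.Mp + self.AMp + self.AM


@dataclass(frozen=True)
class EnzymePool:
    """MLCK/MLCP concentrations governing one cross-bridge system (uM)."""

    mlck_act: float    # activated MLCK before inhibitory factors
    mlck_total: float  # after inhibitory factor(s)
    mlcp_f: float      # signalling-driven MLCP increase
    mlcp_total: float  # resting + increase
    cgmp: float = 0.0


@dataclass(frozen=True)
class StressState:
    o_mech: float   # sliding-filament passive component (lambda_f1 - 1)
    o_chem: float   # -o_A / o_B (dimensionless)
    o_bar: float    # sum
    L_bar: float    # normalised actin-myosin overlap
    sigma: float    # active tissue stress (kPa)


# ---------------------------------------------------------------------------
# enzyme limb
# ---------------------------------------------------------------------------
def cgmp_from_no(no_uM: float, registry: ParameterRegistry) -> float:
    """NO -> cGMP Michaelis-Menten map (uM)."""
    if no_uM < 0:
        raise ValueError(f"[NO] must be >= 0, got {no_uM}")
    k_no_uM = units.nm_to_um(registry.get("gastric.K_NO"))
    return registry.get("gastric.cGMP_max") * no_uM / (k_no_uM + no_uM)


def mlcp_from_cgmp(cgmp_uM: float, w: int, registry: ParameterRegistry) -> float:
    """cGMP -> MLCP increase (uM) with Hill coefficient N_cGMP for
    compartment ``w`` in {1, 2, 3}."""
    if cgmp_uM < 0:
        raise ValueError(f"[cGMP] must be >= 0, got {cgmp_uM}")
    if cgmp_uM == 0:
        return 0.0
    n = registry.get("gastric.N_cGMP")
    k = registry.get("gastric.K_cGMP")
    a = registry.get(f"gastric.MLCP_max_{w}")
    return a / (1.0 + (k / cgmp_uM) ** n)


def mlck_activation(ca_uM: float, registry: ParameterRegistry) -> float:
    """Ca2+ -> active MLCK (uM): cooperative Ca-calmodulin saturation."""
    if ca_uM < 0:
        raise ValueError(f"[Ca2+] must be >= 0, got {ca_uM}")
    if ca_uM == 0:
        return 0.0
    n = registry.get("auxiliary.n_CaM")
    k = registry.get("auxiliary.K_CaM")
    return registry.get("auxiliary.MLCK_cell") / (1.0 + (k / ca_uM) ** n)


def combine_enzymes(mlck_act: float, mlcp_f: float, factor: float,
                    mode: str, registry: ParameterRegistry,
                    cgmp: float = 0.0) -> EnzymePool:
    """Compose the enzyme pool for one contractile system.

    mode "fundus":   inhibitory VIP factor scales MLCK down and the
                     NO-driven MLCP increase adds in full:
                     MLCK = (1 - phi_ipsi_1) * MLCK_act,  MLCP = rest + MLCP_f
    mode "ps_tonic": the direct inhibitory fraction gates both limbs:
                     MLCK = (1 - phi_ih) * MLCK_act, MLCP = rest + phi_ih*MLCP_f
    mode "phasic":   no tonic inhibitory factor (psi acts on the membrane
                     coupling instead): MLCK = MLCK_act, MLCP = rest + MLCP_f
    """
    if not (-1e-12 <= factor <= 1.0 + 1e-12):
        raise ValueError(f"inhibitory factor must lie in [0, 1], got {factor}")
    factor = min(max(factor, 0.0), 1.0)
    rest = registry.get("gastric.MLCP_rest")
    if mode == "fundus":
        mlck_total = (1.0 - factor) * mlck_act
        mlcp_total = rest + mlcp_f
    elif mode == "ps_tonic":
        mlck_total = (1.0 - factor) * mlck_act
        mlcp_total = rest + factor * mlcp_f
    elif mode == "phasic":
        mlck_total = mlck_act
        mlcp_total = rest + mlcp_f
    else:
        raise ValueError(f"unknown enzyme mode {mode!r}")
    return EnzymePool(mlck_act=mlck_act, mlck_total=mlck_total,
                      mlcp_f=mlcp_f, mlcp_total=mlcp_total, cgmp=cgmp)


# ---------------------------------------------------------------------------
# Hai-Murphy four-state kinetics
# ---------------------------------------------------------------------------
def _hm_rates(registry: ParameterRegistry) -> Tuple[float, ...]:
    g = registry.get
    return (g("auxiliary.kcat_MLCK"), g("auxiliary.km_MLCK"),
            g("auxiliary.kcat_MLCP"), g("auxiliary.km_MLCP"),
            g("auxiliary.k_a"), g("auxiliary.k_b"), g("auxiliary.k_c"))


def hai_murphy_rhs(state, pool: EnzymePool,
                   registry: ParameterRegistry) -> np.ndarray:
    """Time derivatives (d[M], d[Mp], d[AMp], d[AM]) / dt.

    Phosphorylation (MLCK) and dephosphorylation (MLCP) are
    Michaelis-Menten fluxes in the substrate fraction; attachment/detachment
    use first-order rates k_b (Mp->AMp), k_c (AMp->Mp) and k_a (AM->M).
    The four derivatives sum to zero (myosin conservation).
    """
    kcat_k, km_k, kcat_p, km_p, k_a, k_b, k_c = _hm_rates(registry)
    if isinstance(state, CrossBridgeState):
        m, mp, amp, am = state.M, state.Mp, state.AMp, state.AM
    else:
        m, mp, amp, am = state
    kk = kcat_k * pool.mlck_total
    kp = kcat_p * pool.mlcp_total
    phos_m = kk * m / (km_k + m)
    phos_am = kk * am / (km_k + am)
    deph_mp = kp * mp / (km_p + mp)
    deph_amp = kp * amp / (km_p + amp)
    d_m = -phos_m + deph_mp + k_a * am
    d_mp = phos_m - deph_mp - k_b * mp + k_c * amp
    d_amp = k_b * mp - k_c * amp + phos_am - deph_amp
    d_am = -phos_am + deph_amp - k_a * am
    return np.array([d_m, d_mp, d_amp, d_am])


def hai_murphy_steady_state(pool: EnzymePool,
                            registry: ParameterRegistry) -> CrossBridgeState:
    """Steady state of the four-state system on the unit simplex."""
    def rhs3(x):
        mp, amp, am = x
        m = 1.0 - mp - amp - am
        d = hai_murphy_rhs((m, mp, amp, am), pool, registry)
        return d[1:]

    # integrate briefly for a robust initial guess, then polish
    y0 = np.array([1.0, 0.0, 0.0, 0.0])
    sol = solve_ivp(lambda t, y: hai_murphy_rhs(y, pool, registry),
                    (0.0, 80.0), y0, method="LSODA", rtol=1e-8, atol=1e-10)
    guess = sol.y[1:, -1]
    x = fsolve(rhs3, guess, full_output=False, xtol=1e-12)
    mp, amp, am = (max(float(v), 0.0) for v in x)
    m = max(1.0 - mp - amp - am, 0.0)
    return CrossBridgeState(M=m, Mp=mp, AMp=amp, AM=am)


def total_bridges(state, mode: str = "tonic") -> float:
    """Total attached myosin AMp + AM (latch bridges for tonic systems,
    cross-bridges for phasic; the sum is identical in both modes)."""
    if mode not in ("tonic", "phasic"):
        raise ValueError(f"unknown bridge mode {mode!r}")
    if isinstance(state, CrossBridgeState):
        return state.AMp + state.AM
    return float(state[2] + state[3])


# ---------------------------------------------------------------------------
# stress / stretch
# ---------------------------------------------------------------------------
def active_stress(bridges: float, lam_f_1: float,
                  registry: ParameterRegistry) -> StressState:
    """Active antral/PS tissue stress from the sliding-filament model.

    o_mech = lam_f1 - 1 is the passive sliding component, o_chem = -o_A/o_B
    the active cross-bridging component, and L_bar the normalised
    actin-myosin overlap (a parabola with optimum o_opt, offset X_bar).
    The stress is proportional to the attached-bridge total.
    """
    o_a = registry.get("gastric.o_A")                        # kPa
    o_b = units.mpa_to_kpa(registry.get("gastric.o_B"))      # kPa
    o_mech = lam_f_1 - 1.0
    o_chem = -o_a / o_b
    o_bar = o_mech + o_chem
    l_bar = o_bar - o_bar ** 2 / (2.0 * registry.get("gastric.o_opt")) \
        + registry.get("gastric.X_bar")
    sigma = o_b * l_bar * bridges * (lam_f_1 - o_bar - 1.0)
    return StressState(o_mech=o_mech, o_chem=o_chem, o_bar=o_bar,
                       L_bar=l_bar, sigma=sigma)


def hyperelastic_stress(lam: float, registry: ParameterRegistry) -> float:
    """Principal passive stress E(lambda) = sum_{s=1..5} A_{s-1} lambda^s (kPa)."""
    if lam <= 0:
        raise ValueError(f"stretch must be positive, got {lam}")
    coeffs = registry.get("auxiliary.A_poly")
    e = 0.0
    p = 1.0
    for a in coeffs:
        p *= lam
        e += a * p
    return e


def viscoelastic_rhs(lam: float, sigma: float,
                     registry: ParameterRegistry) -> float:
    """Stretch rate d(lambda)/dt = (sigma - E(lambda)) / eta_2.

    eta_1 = S3*exp(S4 + S5*(E - sigma)); eta_2 = eta_1*tanh(S6*(lambda-0.982)),
    floored at eta_floor to keep the dashpot dissipative and the ODE
    well-posed.
    """
    e = hyperelastic_stress(lam, registry)
    g = registry.get
    expo = g("gastric.S4") + g("gastric.S5") * (e - sigma)
    expo = min(max(expo, -8.0), 8.0)
    eta1 = g("gastric.S3") * np.exp(expo)
    eta2 = eta1 * np.tanh(g("gastric.S6") * (lam - 0.982))
    eta2 = max(eta2, g("auxiliary.eta_floor"))
    return (sigma - e) / eta2


def equilibrium_stretch(sigma: float, registry: ParameterRegistry,
                        bracket: Tuple[float, float] = (0.985, 3.0)) -> float:
    """Root of E(lambda) = sigma: the stretch the dashpot relaxes to under a
    constant stress."""
    f = lambda lam: hyperelastic_stress(lam, registry) - sigma
    lo, hi = bracket
    return brentq(f, lo, hi, xtol=1e-12)
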