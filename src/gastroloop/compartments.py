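"""The three stomach compartments.

* Fundus (w=1): tonic.  NANC drive removes latch bridges, the relative
  distension area RA_1 maps the bridge total onto the open-cylinder radius,
  and the sarcomere stretch lambda_f_1 feeds both the mechanoreceptors and
  the antral stress model.
* Antrum (w=2): phasic.  ICC/SMC slow waves (modified leaky-integrate-and-
  fire) gate Ca2+ and hence cross-bridge formation; active stress drives the
  viscoelastic stretch, which deflects the wall inward (Eq.-43 chord
  geometry) to produce the peristaltic radius trace.
* Pyloric sphincter (w=3): tonic chain (fundus-form, index 3) sets the
  open-state radius; an antrum-form phasic chain closes the sphincter once
  per slow-wave cycle; gastric outflow is quadratic in the opening radius.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks
from scipy.special import expit

from . import mechanics, units
from .mechanics import CrossBridgeState, EnzymePool
from .params import ParameterRegistry
from .signaling import AntrumSignal, FundusSignal, PylorusSignal

logger = logging.getLogger(__name__)

__all__ = [
    "FundusState",
    "AntrumState",
    "PylorusState",
    "fundus_enzyme_pool",
    "fundus_geometry",
    "fundus_step",
    "icc_drive",
    "drive_window",
    "icc_smc_rhs",
    "ca_from_vm",
    "smoothstep",
    "contraction_factor",
    "antrum_radius",
    "ps_tonic_pool",
    "ps_tonic_radius",
    "ps_closure",
    "ps_step",
    "q_flow",
    "occlusion",
]


@dataclass(frozen=True)
class FundusState:
    Ca_total_1: float           # uM
    crossbridge_to_1: CrossBridgeState
    RA_1: float                 # relative distension (radius ratio)
    r_fin_1: float              # cm
    lambda_f_1: float           # sarcomere stretch


@dataclass(frozen=True)
class AntrumState:
    Vm_ICC_2: float             # mV
    Vm_SMC_2: float             # mV
    kappa_2: float              # mA
    cpm_2: float                # cpm
    t_end_2: float              # s
    crossbridge_p_2: CrossBridgeState
    lambda_2: float
    r_d_2: float                # cm
    r_fin_2: float              # cm


@dataclass(frozen=True)
class PylorusState:
    crossbridge_to_3: CrossBridgeState
    RA_3: float
    lambda_f_3: float
    r_tonic_3: float            # cm open-state radius set by basal tone
    r_fin_3: float              # cm instantaneous radius
    Q_flow: float               # cm3/s


# ---------------------------------------------------------------------------
# fundus
# ---------------------------------------------------------------------------
def fundus_enzyme_pool(signal: FundusSignal,
                       registry: ParameterRegistry) -> Tuple[float, EnzymePool]:
    """Total SMC calcium and the MLCK/MLCP pool for the fundic tonic system."""
    ca_total = registry.get("gastric.Ca_rest_1") + signal.dCa_to_1
    mlck_act = mechanics.mlck_activation(ca_total, registry)
    cgmp = mechanics.cgmp_from_no(signal.NO_1, registry)
    mlcp_f = mechanics.mlcp_from_cgmp(cgmp, 1, registry)
    pool = mechanics.combine_enzymes(mlck_act, mlcp_f, signal.phi_ipsi_1,
                                     "fundus", registry, cgmp=cgmp)
    return ca_total, pool


def fundus_geometry(bridges: float, registry: ParameterRegistry
                    ) -> Tuple[float, float, float]:
    """(RA_1, r_fin_1, lambda_f_1) from the fundic latch-bridge total.

    RA_1 = [(1 - beta_1*b) / (1 - beta_1*b_max)]^2 with b_max the reference
    (zero-NANC) bridge total: RA_1 = 1 at the full bridge complement (empty
    stomach) and RA_1 = (1 - beta_1*b_max)^-2 at zero bridges, which equals
    the open-cylinder radius ratio sqrt(V_max/V_min) by calibration of
    b_max.  r_fin_1 = RA_1*r_ini_1 and lambda_f_1 = alpha_1*(RA_1 - 1) + 1.
    """
    beta = registry.get("gastric.beta_1")
    b_max = registry.get("auxiliary.b_max_1")
    num = max(1.0 - beta * bridges, 0.0)
    ra = (num / (1.0 - beta * b_max)) ** 2
    r_ini = registry.get("auxiliary.r_ini_1")
    lam = registry.get("gastric.alpha_1") * (ra - 1.0) + 1.0
    return ra, ra * r_ini, lam


def fundus_step(signal: FundusSignal, crossbridge: CrossBridgeState,
                registry: ParameterRegistry) -> FundusState:
    """Algebraic fundus update for a given signal and cross-bridge state."""
    ca_total, _pool = fundus_enzyme_pool(signal, registry)
    bridges = mechanics.total_bridges(crossbridge, "tonic")
    ra, r_fin, lam = fundus_geometry(bridges, registry)
    return FundusState(Ca_total_1=ca_total, crossbridge_to_1=crossbridge,
                       RA_1=ra, r_fin_1=r_fin, lambda_f_1=lam)


# ---------------------------------------------------------------------------
# antrum electrophysiology
# ---------------------------------------------------------------------------
def icc_drive(signal: AntrumSignal, registry: ParameterRegistry
              ) -> Tuple[float, float, float]:
    """(kappa, cpm, t_end): ICC stimulating-current amplitude and slow-wave
    frequency modulated by the fractional neural responses."""
    kappa = registry.get("gastric.kappa_ini") * (
        signal.phi_ea_2 - signal.phi_ia_2 + 1.0)
    cpm = registry.get("gastric.cpm_ini") * (
        signal.phi_ec_2 - signal.phi_ic_2 + 1.0)
    kappa = max(kappa, 0.0)
    cpm = max(cpm, 0.2)
    return kappa, cpm, units.cpm_to_period_s(cpm)


def drive_window(phase: float, duty: float, eps: float) -> float:
    """Smooth periodic stimulus window in the cycle phase (cycles).

    ~1 for frac(phase) in (0, duty), ~0 otherwise; built from a cosine so it
    is smooth across the phase wrap (no event for the stiff solver).
    """
    return float(expit((math.cos(2.0 * math.pi * (phase - 0.5 * duty))
                        - math.cos(math.pi * duty)) / eps))


def icc_smc_rhs(vm_icc: float, vm_smc: float, i_stim: float, psi: float,
                registry: ParameterRegistry) -> Tuple[float, float]:
    """MLIF membrane dynamics for the ICC/SMC pair.

    The gap junction couples the SMC to the ICC with conductance G_coup;
    psi (purinergic inhibition) scales the coupling current.
    """
    g = registry.get
    d_icc = (i_stim * g("auxiliary.R_ICC")
             - (vm_icc - g("auxiliary.Vm_rest_ICC"))) / g("auxiliary.tau_m_ICC")
    i_couple = g("gastric.G_coup") * (vm_icc - vm_smc)
    d_smc = (psi * i_couple * g("auxiliary.R_SMC")
             - (vm_smc - g("auxiliary.Vm_rest_SMC"))) / g("auxiliary.tau_m_SMC")
    return d_icc, d_smc


def ca_from_vm(vm_smc: float, registry: ParameterRegistry) -> float:
    """Phasic SMC Ca2+ as a sigmoidal function of membrane potential (uM)."""
    g = registry.get
    return g("auxiliary.Ca_base") + g("auxiliary.Ca_amp") * float(
        expit((vm_smc - g("auxiliary.V_half_Ca")) / g("auxiliary.k_Ca")))


# ---------------------------------------------------------------------------
# antrum geometry
# ---------------------------------------------------------------------------
def smoothstep(x: float) -> float:
    """C1 ramp: 0 below 0, 1 above 1, 3x^2-2x^3 in between."""
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    return x * x * (3.0 - 2.0 * x)


def contraction_factor(lam: float, lam_on: float, lam_sat: float) -> float:
    """Fraction of the maximal inward wall deflection recruited at stretch
    ``lam``: 0 at rest, saturating once lam exceeds lam_sat."""
    return smoothstep((lam - lam_on) / (lam_sat - lam_on))


def antrum_radius(lam_2: float, r_ini_2: float, l_t_2: float,
                  registry: ParameterRegistry) -> Tuple[float, float]:
    """(r_d_2, r_fin_2): inward wall deflection and final antral radius.

    The contracting tissue segment of undeformed length L_t,2 deflects the
    wall inward by a depth d = f_occ*r_ini_2*contraction_factor(lambda_2);
    the deformed tissue half-length is the hypotenuse
    omega_3,2 = sqrt((L_t/2)^2 + d^2), so the printed chord relation
    r_d = sqrt(omega^2 - L_t^2/4) recovers d.  r_fin_2 = r_ini_2 - r_d,
    clamped to (0, r_ini_2].
    """
    g = registry.get
    s = contraction_factor(lam_2, g("auxiliary.lam_on_2"),
                           g("auxiliary.lam_sat_2"))
    d = g("auxiliary.f_occ_2") * r_ini_2 * s
    omega = math.hypot(0.5 * l_t_2, d)
    radicand = omega * omega - 0.25 * l_t_2 * l_t_2
    if radicand < 0.0:  # cannot occur with the hypotenuse construction
        logger.warning("antral radicand clamped at zero (omega=%.4f)", omega)
        radicand = 0.0
    r_d = math.sqrt(radicand)
    r_fin = min(max(r_ini_2 - r_d, 1e-9), r_ini_2)
    return r_d, r_fin


# ---------------------------------------------------------------------------
# pyloric sphincter
# ---------------------------------------------------------------------------
def ps_tonic_pool(signal: PylorusSignal,
                  registry: ParameterRegistry) -> Tuple[float, EnzymePool]:
    """Calcium and enzyme pool for the PS tonic (basal tone) system.

    The inhibitory fraction phi_ih gates MLCK down and the (full-scale)
    MLCP increase up, reproducing the combined NANC effect with an
    unidentified transmitter.
    """
    ca_total = registry.get("gastric.Ca_rest_3") + signal.dCa_to_3
    mlck_act = mechanics.mlck_activation(ca_total, registry)
    mlcp_f = registry.get("gastric.MLCP_max_3")
    pool = mechanics.combine_enzymes(mlck_act, mlcp_f, signal.phi_ih_to_3,
                                     "ps_tonic", registry)
    return ca_total, pool


def ps_tonic_radius(bridges_to_3: float, registry: ParameterRegistry
                    ) -> Tuple[float, float, float]:
    """(RA_3, lambda_f_3, r_tonic_3) from the PS tonic latch-bridge total.

    Same squared-ratio distension form as the fundus; with beta_3 = 236.32
    the numerator hits zero at b = 1/beta_3, i.e. a moderate latch-bridge
    complement closes the sphincter completely (sympathetic state).
    """
    beta = registry.get("gastric.beta_3")
    b_max = registry.get("auxiliary.b_max_3")
    num = max(1.0 - beta * bridges_to_3, 0.0)
    ra = (num / (1.0 - beta * b_max)) ** 2
    lam = registry.get("gastric.alpha_3") * (ra - 1.0) + 1.0
    r = min(ra * registry.get("auxiliary.r_ini_3"),
            registry.get("gastric.r_max_3"))
    return ra, lam, r


def ps_closure(lam_3p: float, registry: ParameterRegistry) -> float:
    """Phasic closure factor in [0, 1]: 0 fully open, 1 fully closed."""
    return contraction_factor(lam_3p, registry.get("auxiliary.lam_on_3"),
                              registry.get("auxiliary.lam_sat_3"))


def ps_step(signal: PylorusSignal, crossbridge_to_3: CrossBridgeState,
            lam_3p: float, registry: ParameterRegistry) -> PylorusState:
    """Algebraic sphincter update: tonic opening x phasic modulation.

    The tonic chain sets the open-state radius; the phasic stretch closes
    it multiplicatively; the result is clamped to [0, r_max,3] and mapped
    to outflow.
    """
    bridges = mechanics.total_bridges(crossbridge_to_3, "tonic")
    ra3, lam_f3, r_tonic = ps_tonic_radius(bridges, registry)
    r_fin = min(max(r_tonic * (1.0 - ps_closure(lam_3p, registry)), 0.0),
                registry.get("gastric.r_max_3"))
    return PylorusState(crossbridge_to_3=crossbridge_to_3, RA_3=ra3,
                        lambda_f_3=lam_f3, r_tonic_3=r_tonic, r_fin_3=r_fin,
                        Q_flow=q_flow(r_fin, registry))


def q_flow(r_fin_3: float, registry: ParameterRegistry) -> float:
    """Gastric outflow Q = Q_max*(r/r_max)^2 (cm3/s)."""
    r_max = registry.get("gastric.r_max_3")
    r = min(max(r_fin_3, 0.0), r_max)
    return registry.get("gastric.Q_max_flow") * (r / r_max) ** 2


# ---------------------------------------------------------------------------
# occlusion metric
# ---------------------------------------------------------------------------
def occlusion(radius: Sequence[float],
              cycle_bounds: Optional[Sequence[int]] = None,
              rel_tol: float = 1e-6) -> float:
    """Radius-based occlusion percentage of a contraction trace.

    occlusion% = 100*(r_relaxed - r_min)/r_relaxed per cycle, averaged, with
    r_relaxed the pre-contraction plateau (cycle maximum) and r_min the cycle
    minimum.  ``cycle_bounds`` are sample indices delimiting cycles; when
    omitted, cycles are detected from the trace minima.  A constant trace
    has 0 % occlusion; a trace spanning less than one full cycle raises
    ``ValueError``.
    """
    r = np.asarray(radius, dtype=float)
    if r.ndim != 1 or r.size < 3:
        raise ValueError("radius trace must be a 1-D array of >= 3 samples")
    span = float(r.max() - r.min())
    if span <= rel_tol * max(abs(float(r.max())), 1.0):
        return 0.0
    if cycle_bounds is None:
        minima, _ = find_peaks(-r, prominence=0.25 * span)
        if minima.size < 2:
            raise ValueError(
                "radius trace spans less than one full contraction cycle"
            )
        cycle_bounds = list(minima)
    vals = []
    for lo, hi in zip(cycle_bounds[:-1], cycle_bounds[1:]):
        seg = r[lo:hi + 1]
        if seg.size < 2:
            continue
        relaxed = float(seg.max())
        if relaxed <= 0:
            continue
        vals.append(100.0 * (relaxed - float(seg.min())) / relaxed)
    if not vals:
        raise ValueError("no complete contraction cycle in trace")
    return float(np.mean(vals))
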