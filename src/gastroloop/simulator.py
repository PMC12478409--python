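"""Closed-loop scenario integration.

Assembles the full vago-vagal loop as one stiff ODE system: gastric volume
-> afferent firing -> brainstem maps (or sympathetic override) -> efferent
signalling cascades -> enzyme pools -> Hai-Murphy cross-bridge ODEs (three
contractile systems) -> MLIF slow-wave ODEs (antrum and PS-phasic) ->
stress/viscoelastic stretch ODEs -> compartment geometry -> pyloric outflow
-> (emptying mode) meal-volume mass balance dV_meal/dt = -Q_flow.

All neuro-effector cascades are algebraic (quasi-steady-state); the dynamic
states are the myosin fractions, membrane potentials, tissue stretches, the
slow-wave phase and, in emptying mode, the meal volume.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from . import compartments, mechanics, signaling
from .params import ParameterRegistry, load_registry

__all__ = [
    "Scenario",
    "SolverOptions",
    "Trajectory",
    "ScenarioSummary",
    "SimulationError",
    "STATE_LAYOUT",
    "N_CORE_STATES",
    "assemble_rhs",
    "make_rhs",
    "initial_state",
    "simulate",
    "run_emptying",
    "summarize",
    "scenario_fixtures",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverOptions:
    method: str = "BDF"
    rtol: float = 1e-6
    atol: float = 1e-8
    max_step: float = 0.25


@dataclass(frozen=True)
class Scenario:
    """One simulation scenario.

    mode "fixed_volume": V_tot held constant (motility study);
    mode "emptying": V_tot = V_meal(t) + V_gas with dV_meal/dt = -Q_flow.
    """

    mode: str = "fixed_volume"
    V_tot: float = 0.6          # L (fixed_volume mode)
    V_meal_0: float = 0.3       # L (emptying mode)
    g_cal: float = 0.0          # kcal/cm3
    O_sym: int = 0
    duration: float = 200.0     # s
    output_interval: float = 0.05   # s
    transient: Optional[float] = None  # s discarded before metrics (default
    #                                    two baseline slow-wave periods)
    solver: SolverOptions = field(default_factory=SolverOptions)
    seed: int = 0               # reserved; the model is deterministic
    name: str = ""

    def validate(self, registry: ParameterRegistry) -> "Scenario":
        g = registry.get
        if self.mode not in ("fixed_volume", "emptying"):
            raise ValueError(f"unknown scenario mode {self.mode!r}")
        if self.g_cal < 0:
            raise ValueError("g_cal must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.O_sym not in (0, 1):
            raise ValueError("O_sym must be 0 or 1")
        vmin, vmax = g("auxiliary.V_min"), g("auxiliary.V_max")
        if self.mode == "fixed_volume":
            if not (vmin <= self.V_tot <= vmax):
                raise ValueError(
                    f"V_tot={self.V_tot} L outside [{vmin}, {vmax}] L")
        else:
            if self.V_meal_0 <= 0:
                raise ValueError("V_meal_0 must be positive")
            if self.V_meal_0 + g("auxiliary.V_gas") > vmax:
                raise ValueError(
                    f"V_meal_0 + V_gas = {self.V_meal_0 + g('auxiliary.V_gas')}"
                    f" L exceeds the {vmax} L bound")
        return self

    def transient_s(self, registry: ParameterRegistry) -> float:
        if self.transient is not None:
            return self.transient
        return 2.0 * 60.0 / registry.get("gastric.cpm_ini")


# ---------------------------------------------------------------------------
# state layout
# ---------------------------------------------------------------------------
STATE_LAYOUT: List[Tuple[str, str, str]] = [
    # (name, unit, block)
    ("M_to_1", "-", "fundus_crossbridge"),
    ("Mp_to_1", "-", "fundus_crossbridge"),
    ("AMp_to_1", "-", "fundus_crossbridge"),
    ("AM_to_1", "-", "fundus_crossbridge"),
    ("Vm_ICC_2", "mV", "antrum_membrane"),
    ("Vm_SMC_2", "mV", "antrum_membrane"),
    ("M_p_2", "-", "antrum_crossbridge"),
    ("Mp_p_2", "-", "antrum_crossbridge"),
    ("AMp_p_2", "-", "antrum_crossbridge"),
    ("AM_p_2", "-", "antrum_crossbridge"),
    ("lambda_2", "-", "antrum_stretch"),
    ("phase_2", "cycles", "antrum_clock"),
    ("M_to_3", "-", "ps_tonic_crossbridge"),
    ("Mp_to_3", "-", "ps_tonic_crossbridge"),
    ("AMp_to_3", "-", "ps_tonic_crossbridge"),
    ("AM_to_3", "-", "ps_tonic_crossbridge"),
    ("Vm_ICC_3", "mV", "ps_membrane"),
    ("Vm_SMC_3", "mV", "ps_membrane"),
    ("M_p_3", "-", "ps_phasic_crossbridge"),
    ("Mp_p_3", "-", "ps_phasic_crossbridge"),
    ("AMp_p_3", "-", "ps_phasic_crossbridge"),
    ("AM_p_3", "-", "ps_phasic_crossbridge"),
    ("lambda_3p", "-", "ps_stretch"),
    ("V_meal", "L", "mass_balance"),  # emptying mode only
]
N_CORE_STATES = 23


# ---------------------------------------------------------------------------
# precomputed evaluation context
# ---------------------------------------------------------------------------
class _Ctx:
    """Scenario-constant scalars extracted from the registry for a fast RHS."""

    def __init__(self, scenario: Scenario, registry: ParameterRegistry):
        from .neural import chem_firing, interneuron_chem, nutrient_flow

        g = registry.get
        self.registry = registry
        self.scenario = scenario
        self.emptying = scenario.mode == "emptying"
        self.o_sym = scenario.O_sym
        # volumes
        self.v_gas = g("auxiliary.V_gas")
        self.v_min, self.v_max = g("auxiliary.V_min"), g("auxiliary.V_max")
        self.v_tot_fixed = scenario.V_tot
        # Hai-Murphy rates
        self.kcat_k = g("auxiliary.kcat_MLCK")
        self.km_k = g("auxiliary.km_MLCK")
        self.kcat_p = g("auxiliary.kcat_MLCP")
        self.km_p = g("auxiliary.km_MLCP")
        self.k_a = g("auxiliary.k_a")
        self.k_b = g("auxiliary.k_b")
        self.k_c = g("auxiliary.k_c")
        # enzyme limb
        self.mlcp_rest = g("gastric.MLCP_rest")
        self.mlck_cell = g("auxiliary.MLCK_cell")
        self.k_cam = g("auxiliary.K_CaM")
        self.n_cam = g("auxiliary.n_CaM")
        # fundus constants
        self.ca_rest_1 = g("gastric.Ca_rest_1")
        self.beta_1 = g("gastric.beta_1")
        self.b_max_1 = g("auxiliary.b_max_1")
        self.alpha_1 = g("gastric.alpha_1")
        self.r_ini_1 = g("auxiliary.r_ini_1")
        self.ra_denom_1 = 1.0 - self.beta_1 * self.b_max_1
        # afferent / interneuron
        self.x_mech_a = g("afferent.X_mech_a")
        self.x_mech_b = g("afferent.X_mech_b")
        self.f_min_mech = g("interneuron.f_min_mech")
        self.f_max_mech = g("interneuron.f_max_mech")
        self.f_mid_mech = g("interneuron.f_mid_mech")
        self.k_inter_mech = g("interneuron.k_inter_mech")
        self.k_vol_h = list(g("interneuron.k_vol_h"))
        self.k_vol_l = list(g("interneuron.k_vol_l"))
        self.v_tot_o = g("interneuron.V_tot_o")
        # chemosensitive loop: constant per scenario
        q_cal = nutrient_flow(scenario.g_cal, registry)
        self.q_cal = q_cal
        self.f_chem = chem_firing(q_cal, registry)
        # efferent constants
        if self.o_sym:
            self.f_i_p_2 = g("auxiliary.sym_f_i_p_2")
            self.f_e_p_2_const = g("auxiliary.sym_f_e_p_2")
            self.f_i_to_3 = g("auxiliary.sym_f_i_to_3")
            self.f_e_to_3 = g("auxiliary.sym_f_e_to_3")
        else:
            self.f_i_p_2 = g("auxiliary.f_i_p_2_base")
            self.f_e_p_2_const = None  # dynamic via the mechanosensitive map
            self.f_i_to_3 = interneuron_chem(self.f_chem, registry)
            self.f_e_to_3 = g("auxiliary.f_e_to_3_base")
        self.f_e_to_1 = g("auxiliary.f_e_to_1_base")
        # fundus cholinergic (usually zero drive)
        ach1, dca1 = signaling.fundus_cholinergic(self.f_e_to_1, registry)
        self.dca_to_1 = dca1
        # antral MMEHC curves for the dynamic excitatory chain
        cv = registry.curve
        self.ach_p_2 = (cv("Ach_p_2").A, cv("Ach_p_2").B, cv("Ach_p_2").N)
        self.ea_p_2 = (cv("ea_p_2").A, cv("ea_p_2").B, cv("ea_p_2").N)
        self.ec_p_2 = (cv("ec_p_2").A, cv("ec_p_2").B, cv("ec_p_2").N)
        # antral inhibitory chain: constant per scenario
        no2, pur2, phi_ia, phi_ic, phi_ipsi, psi = \
            signaling.antrum_inhibitory(self.f_i_p_2, registry)
        self.no_2, self.pur_2 = no2, pur2
        self.phi_ia_2, self.phi_ic_2 = phi_ia, phi_ic
        self.psi_2 = psi
        cgmp2 = mechanics.cgmp_from_no(no2, registry)
        self.mlcp_total_2 = self.mlcp_rest + mechanics.mlcp_from_cgmp(
            cgmp2, 2, registry)
        # ICC drive constants
        self.kappa_ini = g("gastric.kappa_ini")
        self.cpm_ini = g("gastric.cpm_ini")
        self.duty_2 = g("auxiliary.t_open_frac_2")
        self.duty_3 = g("auxiliary.t_open_frac_3")
        self.window_eps = g("auxiliary.window_eps")
        self.ps_lag = g("auxiliary.ps_phase_lag")
        # MLIF constants
        self.r_icc = g("auxiliary.R_ICC")
        self.r_smc = g("auxiliary.R_SMC")
        self.tau_icc = g("auxiliary.tau_m_ICC")
        self.tau_smc = g("auxiliary.tau_m_SMC")
        self.vrest_icc = g("auxiliary.Vm_rest_ICC")
        self.vrest_smc = g("auxiliary.Vm_rest_SMC")
        self.g_coup = g("gastric.G_coup")
        # voltage -> Ca map
        self.ca_base = g("auxiliary.Ca_base")
        self.ca_amp = g("auxiliary.Ca_amp")
        self.v_half_ca = g("auxiliary.V_half_Ca")
        self.k_ca = g("auxiliary.k_Ca")
        # stress / stretch
        self.o_a = g("gastric.o_A")
        self.o_b_kpa = g("gastric.o_B") * 1000.0
        self.o_chem = -self.o_a / self.o_b_kpa
        self.o_opt = g("gastric.o_opt")
        self.x_bar = g("gastric.X_bar")
        self.a_poly = list(g("auxiliary.A_poly"))
        self.s3 = g("gastric.S3")
        self.s4 = g("gastric.S4")
        self.s5 = g("gastric.S5")
        self.s6 = g("gastric.S6")
        self.eta_floor = g("auxiliary.eta_floor")
        # antral geometry
        self.r_ini_2_ref = g("auxiliary.r_ini_2")
        self.l_t_2_ref = g("auxiliary.L_t_2")
        self.f_occ_2 = g("auxiliary.f_occ_2")
        self.lam_on_2 = g("auxiliary.lam_on_2")
        self.lam_sat_2 = g("auxiliary.lam_sat_2")
        # PS tonic: constant pool per scenario
        ps_sig = signaling.ps_signals(self.f_e_to_3, self.f_i_to_3,
                                      g("auxiliary.f_e_p_3_base"),
                                      g("auxiliary.f_i_p_3_base"), registry)
        self.ps_signal = ps_sig
        _, ps_pool = compartments.ps_tonic_pool(ps_sig, registry)
        self.mlck_to_3 = ps_pool.mlck_total
        self.mlcp_to_3 = ps_pool.mlcp_total
        self.beta_3 = g("gastric.beta_3")
        self.b_max_3 = g("auxiliary.b_max_3")
        self.ra_denom_3 = 1.0 - self.beta_3 * self.b_max_3
        self.alpha_3 = g("gastric.alpha_3")
        self.r_ini_3 = g("auxiliary.r_ini_3")
        self.r_max_3 = g("gastric.r_max_3")
        self.q_max = g("gastric.Q_max_flow")
        self.lam_on_3 = g("auxiliary.lam_on_3")
        self.lam_sat_3 = g("auxiliary.lam_sat_3")
        # PS phasic: baseline drive, constant inhibitory chain
        ph = ps_sig.phasic
        self.kappa_3 = max(self.kappa_ini * (ph.phi_ea_2 - ph.phi_ia_2 + 1.0),
                           0.0)
        self.psi_3 = ph.psi_2
        cgmp3 = mechanics.cgmp_from_no(ph.NO_2, registry)
        self.mlcp_p_3 = self.mlcp_rest + mechanics.mlcp_from_cgmp(
            cgmp3, 3, registry)
        # fundus NANC curves for dynamic evaluation (emptying mode)
        self.vip_to_1 = (cv("VIP_to_1").A, cv("VIP_to_1").B, cv("VIP_to_1").N)
        self.ipsi_to_1 = (cv("ipsi_to_1").A, cv("ipsi_to_1").B,
                          cv("ipsi_to_1").N)
        self.no_to_1 = (cv("NO_to_1").A, cv("NO_to_1").B, cv("NO_to_1").N)
        self.cgmp_max = g("gastric.cGMP_max")
        self.k_no_um = g("gastric.K_NO") / 1000.0
        self.mlcp_max_1 = g("gastric.MLCP_max_1")
        self.k_cgmp = g("gastric.K_cGMP")
        self.n_cgmp = g("gastric.N_cGMP")
        # fixed-volume mode: precompute the fundic pool
        if not self.emptying:
            kk, kp = self._fundus_pool(self.v_tot_fixed)
            self.fundus_kk_fixed, self.fundus_kp_fixed = kk, kp
            self.f_i_to_1_fixed = self._f_i_to_1(self.v_tot_fixed)
        else:
            self.fundus_kk_fixed = None

    # -- helpers -----------------------------------------------------------
    def _f_i_to_1(self, v_tot: float) -> float:
        coeffs = self.k_vol_h if v_tot <= self.v_tot_o else self.k_vol_l
        out = 0.0
        p = 1.0
        for k in coeffs:
            p *= v_tot
            out += k * p
        return max(out, 0.0)

    def _fundus_pool(self, v_tot: float) -> Tuple[float, float]:
        """(kcat_K*[MLCK]_to_1, kcat_P*[MLCP]_to_1) at volume v_tot."""
        f_i = self._f_i_to_1(v_tot)
        vip = _hill(f_i, *self.vip_to_1)
        phi = _hill(vip, *self.ipsi_to_1)
        no = _hill(f_i, *self.no_to_1)
        cgmp = self.cgmp_max * no / (self.k_no_um + no)
        mlcp_f = _hill(cgmp, self.mlcp_max_1, self.k_cgmp, self.n_cgmp)
        ca = self.ca_rest_1 + self.dca_to_1
        mlck_act = _hill(ca, self.mlck_cell, self.k_cam, self.n_cam)
        mlck = (1.0 - min(phi, 1.0)) * mlck_act
        mlcp = self.mlcp_rest + mlcp_f
        return self.kcat_k * mlck, self.kcat_p * mlcp


def _hill(x: float, a: float, b: float, n: float) -> float:
    if x <= 0.0:
        return 0.0
    log_ratio = n * (math.log(b) - math.log(x))
    if log_ratio > 700.0:
        return 0.0
    return a / (1.0 + math.exp(log_ratio))


def _logistic(z: float) -> float:
    if z < -50.0:
        return 0.0
    if z > 50.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(-z))


def _window(phase: float, duty: float, eps: float) -> float:
    return _logistic((math.cos(2.0 * math.pi * (phase - 0.5 * duty))
                      - math.cos(math.pi * duty)) / eps)


def _hm_derivs(m, mp, amp, am, kk, kp, c: "_Ctx"):
    phos_m = kk * m / (c.km_k + m)
    phos_am = kk * am / (c.km_k + am)
    deph_mp = kp * mp / (c.km_p + mp)
    deph_amp = kp * amp / (c.km_p + amp)
    d_m = -phos_m + deph_mp + c.k_a * am
    d_mp = phos_m - deph_mp - c.k_b * mp + c.k_c * amp
    d_amp = c.k_b * mp - c.k_c * amp + phos_am - deph_amp
    d_am = -phos_am + deph_amp - c.k_a * am
    return d_m, d_mp, d_amp, d_am


def _poly_e(lam: float, coeffs) -> float:
    e = 0.0
    p = 1.0
    for a in coeffs:
        p *= lam
        e += a * p
    return e


def _smoothstep(x: float) -> float:
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    return x * x * (3.0 - 2.0 * x)


def _core(t: float, y, c: _Ctx, collect: bool = False):
    """Evaluate derivatives (and optionally all algebraic observables)."""
    # ---- volumes ---------------------------------------------------------
    if c.emptying:
        v_meal = max(y[23], 0.0)
        v_tot = min(max(v_meal + c.v_gas, c.v_min), c.v_max)
    else:
        v_meal = float("nan")
        v_tot = c.v_tot_fixed

    # ---- fundus ----------------------------------------------------------
    m1, mp1, amp1, am1 = y[0], y[1], y[2], y[3]
    if c.emptying:
        kk1, kp1 = c._fundus_pool(v_tot)
        f_i_to_1 = c._f_i_to_1(v_tot)
    else:
        kk1, kp1 = c.fundus_kk_fixed, c.fundus_kp_fixed
        f_i_to_1 = c.f_i_to_1_fixed
    d_f = _hm_derivs(m1, mp1, amp1, am1, kk1, kp1, c)
    b1 = amp1 + am1
    ra1 = (max(1.0 - c.beta_1 * b1, 0.0) / c.ra_denom_1) ** 2
    lam_f1 = c.alpha_1 * (ra1 - 1.0) + 1.0
    r_fin_1 = ra1 * c.r_ini_1

    # ---- afferents and antral efferent drive -----------------------------
    f_mech = max(c.x_mech_a * lam_f1 + c.x_mech_b, 0.0)
    if c.f_e_p_2_const is None:
        f_e_p_2 = c.f_min_mech + c.f_max_mech * _logistic(
            (f_mech - c.f_mid_mech) / c.k_inter_mech)
    else:
        f_e_p_2 = c.f_e_p_2_const

    # ---- antrum ----------------------------------------------------------
    ach2 = _hill(f_e_p_2, *c.ach_p_2)
    phi_ea = _hill(ach2, *c.ea_p_2)
    phi_ec = _hill(ach2, *c.ec_p_2)
    kappa_2 = max(c.kappa_ini * (phi_ea - c.phi_ia_2 + 1.0), 0.0)
    cpm_2 = max(c.cpm_ini * (phi_ec - c.phi_ic_2 + 1.0), 0.2)
    vm_icc2, vm_smc2 = y[4], y[5]
    phase_2 = y[11]
    frac2 = phase_2 - math.floor(phase_2)
    i_2 = kappa_2 * _window(frac2, c.duty_2, c.window_eps)
    d_vicc2 = (i_2 * c.r_icc - (vm_icc2 - c.vrest_icc)) / c.tau_icc
    i_couple2 = c.g_coup * (vm_icc2 - vm_smc2)
    d_vsmc2 = (c.psi_2 * i_couple2 * c.r_smc
               - (vm_smc2 - c.vrest_smc)) / c.tau_smc
    d_phase2 = cpm_2 / 60.0
    ca_2 = c.ca_base + c.ca_amp * _logistic((vm_smc2 - c.v_half_ca) / c.k_ca)
    kk2 = c.kcat_k * _hill(ca_2, c.mlck_cell, c.k_cam, c.n_cam)
    kp2 = c.kcat_p * c.mlcp_total_2
    m2, mp2, amp2, am2 = y[6], y[7], y[8], y[9]
    d_a = _hm_derivs(m2, mp2, amp2, am2, kk2, kp2, c)
    b2 = amp2 + am2
    # active stress (sliding filament, overlap parabola)
    o_bar_2 = (lam_f1 - 1.0) + c.o_chem
    l_bar_2 = o_bar_2 - o_bar_2 * o_bar_2 / (2.0 * c.o_opt) + c.x_bar
    sigma_2 = c.o_b_kpa * l_bar_2 * b2 * (lam_f1 - o_bar_2 - 1.0)
    lam_2 = y[10]
    e_2 = _poly_e(lam_2, c.a_poly)
    expo = c.s4 + c.s5 * (e_2 - sigma_2)
    expo = min(max(expo, -8.0), 8.0)
    eta2 = c.s3 * math.exp(expo) * math.tanh(c.s6 * (lam_2 - 0.982))
    eta2 = max(eta2, c.eta_floor)
    d_lam2 = (sigma_2 - e_2) / eta2
    # geometry: unstressed antral radius scales with the fundic distension
    r_ini_2 = c.r_ini_2_ref * ra1
    s_occ = _smoothstep((lam_2 - c.lam_on_2) / (c.lam_sat_2 - c.lam_on_2))
    r_d_2 = c.f_occ_2 * r_ini_2 * s_occ
    r_fin_2 = max(r_ini_2 - r_d_2, 1e-9)

    # ---- PS tonic --------------------------------------------------------
    m3, mp3, amp3, am3 = y[12], y[13], y[14], y[15]
    d_pt = _hm_derivs(m3, mp3, amp3, am3, c.kcat_k * c.mlck_to_3,
                      c.kcat_p * c.mlcp_to_3, c)
    b3 = amp3 + am3
    ra3 = (max(1.0 - c.beta_3 * b3, 0.0) / c.ra_denom_3) ** 2
    lam_f3 = c.alpha_3 * (ra3 - 1.0) + 1.0
    r_tonic = min(ra3 * c.r_ini_3, c.r_max_3)

    # ---- PS phasic (phase-locked to the antral wave) ---------------------
    vm_icc3, vm_smc3 = y[16], y[17]
    phase_3 = phase_2 - c.ps_lag
    frac3 = phase_3 - math.floor(phase_3)
    i_3 = c.kappa_3 * _window(frac3, c.duty_3, c.window_eps)
    d_vicc3 = (i_3 * c.r_icc - (vm_icc3 - c.vrest_icc)) / c.tau_icc
    i_couple3 = c.g_coup * (vm_icc3 - vm_smc3)
    d_vsmc3 = (c.psi_3 * i_couple3 * c.r_smc
               - (vm_smc3 - c.vrest_smc)) / c.tau_smc
    ca_3 = c.ca_base + c.ca_amp * _logistic((vm_smc3 - c.v_half_ca) / c.k_ca)
    kk3 = c.kcat_k * _hill(ca_3, c.mlck_cell, c.k_cam, c.n_cam)
    kp3 = c.kcat_p * c.mlcp_p_3
    m3p, mp3p, amp3p, am3p = y[18], y[19], y[20], y[21]
    d_pp = _hm_derivs(m3p, mp3p, amp3p, am3p, kk3, kp3, c)
    b3p = amp3p + am3p
    o_bar_3 = (lam_f3 - 1.0) + c.o_chem
    l_bar_3 = o_bar_3 - o_bar_3 * o_bar_3 / (2.0 * c.o_opt) + c.x_bar
    sigma_3 = c.o_b_kpa * l_bar_3 * b3p * (lam_f3 - o_bar_3 - 1.0)
    sigma_3 = max(sigma_3, 0.0)
    lam_3p = y[22]
    e_3 = _poly_e(lam_3p, c.a_poly)
    expo3 = c.s4 + c.s5 * (e_3 - sigma_3)
    expo3 = min(max(expo3, -8.0), 8.0)
    eta3 = c.s3 * math.exp(expo3) * math.tanh(c.s6 * (lam_3p - 0.982))
    eta3 = max(eta3, c.eta_floor)
    d_lam3 = (sigma_3 - e_3) / eta3
    closure = _smoothstep((lam_3p - c.lam_on_3) / (c.lam_sat_3 - c.lam_on_3))
    r_fin_3 = min(max(r_tonic * (1.0 - closure), 0.0), c.r_max_3)
    q = c.q_max * (r_fin_3 / c.r_max_3) ** 2

    dydt = [d_f[0], d_f[1], d_f[2], d_f[3],
            d_vicc2, d_vsmc2,
            d_a[0], d_a[1], d_a[2], d_a[3],
            d_lam2, d_phase2,
            d_pt[0], d_pt[1], d_pt[2], d_pt[3],
            d_vicc3, d_vsmc3,
            d_pp[0], d_pp[1], d_pp[2], d_pp[3],
            d_lam3]
    if c.emptying:
        dydt.append(-q / 1000.0 if y[23] > 1e-9 else 0.0)

    if not collect:
        return dydt, None

    derived = {
        "t_s": t, "V_tot_L": v_tot, "V_meal_L": v_meal,
        "f_i_to_1_Hz": f_i_to_1, "f_mech_Hz": f_mech,
        "f_chem_Hz": c.f_chem, "f_e_p_2_Hz": f_e_p_2,
        "f_i_p_2_Hz": c.f_i_p_2, "f_i_to_3_Hz": c.f_i_to_3,
        "f_e_to_3_Hz": c.f_e_to_3,
        "RA_1": ra1, "lambda_f_1": lam_f1, "r_fin_1_cm": r_fin_1,
        "bridges_to_1": b1,
        "kappa_2_mA": kappa_2, "cpm_2": cpm_2,
        "Vm_ICC_2_mV": vm_icc2, "Vm_SMC_2_mV": vm_smc2,
        "Ca_2_uM": ca_2, "bridges_p_2": b2,
        "sigma_2_kPa": sigma_2, "lambda_2": lam_2,
        "r_ini_2_cm": r_ini_2, "r_d_2_cm": r_d_2, "r_fin_2_cm": r_fin_2,
        "phase_2": phase_2,
        "bridges_to_3": b3, "RA_3": ra3, "lambda_f_3": lam_f3,
        "r_tonic_3_cm": r_tonic,
        "Vm_ICC_3_mV": vm_icc3, "Vm_SMC_3_mV": vm_smc3,
        "sigma_3_kPa": sigma_3, "lambda_3p": lam_3p,
        "ps_closure": closure, "r_fin_3_cm": r_fin_3,
        "Q_flow_cm3_s": q,
    }
    return dydt, derived


def make_rhs(scenario: Scenario, registry: ParameterRegistry):
    """Build a fast RHS callable f(t, y) -> dydt for solve_ivp."""
    ctx = _Ctx(scenario.validate(registry), registry)
    n = N_CORE_STATES + (1 if ctx.emptying else 0)

    def rhs(t, y):
        dydt, _ = _core(t, y, ctx)
        s = math.fsum(dydt)
        if not math.isfinite(s):
            bad = [STATE_LAYOUT[i][0] for i, v in enumerate(dydt)
                   if not math.isfinite(v)]
            raise SimulationError(
                f"non-finite derivative at t={t:.3f} s in state(s) {bad}")
        return dydt

    rhs.ctx = ctx
    rhs.n_states = n
    return rhs


def assemble_rhs(t: float, state_vector, scenario: Scenario,
                 registry: ParameterRegistry):
    """Evaluate the full closed-loop derivative vector (reference API).

    For repeated evaluation use :func:`make_rhs`, which pre-compiles the
    scenario-constant algebra.
    """
    ctx = _Ctx(scenario.validate(registry), registry)
    dydt, _ = _core(t, state_vector, ctx)
    return np.asarray(dydt)


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------
def initial_state(scenario: Scenario, registry: ParameterRegistry,
                  ctx: Optional[_Ctx] = None) -> np.ndarray:
    """Assemble an initial state near the slow manifold.

    Tonic cross-bridge systems start at their steady state for the scenario's
    initial drive; membranes start at rest; stretches at 1; phases at 0.
    """
    c = ctx or _Ctx(scenario.validate(registry), registry)
    v_tot0 = (scenario.V_tot if not c.emptying
              else min(max(scenario.V_meal_0 + c.v_gas, c.v_min), c.v_max))
    kk1, kp1 = c._fundus_pool(v_tot0)
    pool1 = mechanics.EnzymePool(
        mlck_act=kk1 / c.kcat_k, mlck_total=kk1 / c.kcat_k,
        mlcp_f=kp1 / c.kcat_p - c.mlcp_rest, mlcp_total=kp1 / c.kcat_p)
    ss1 = mechanics.hai_murphy_steady_state(pool1, registry)
    pool3 = mechanics.EnzymePool(
        mlck_act=c.mlck_to_3, mlck_total=c.mlck_to_3,
        mlcp_f=c.mlcp_to_3 - c.mlcp_rest, mlcp_total=c.mlcp_to_3)
    ss3 = mechanics.hai_murphy_steady_state(pool3, registry)
    # phasic systems: steady state at resting membrane potential
    ca_rest = c.ca_base + c.ca_amp * _logistic(
        (c.vrest_smc - c.v_half_ca) / c.k_ca)
    mlck_rest = _hill(ca_rest, c.mlck_cell, c.k_cam, c.n_cam)
    pool2 = mechanics.EnzymePool(
        mlck_act=mlck_rest, mlck_total=mlck_rest,
        mlcp_f=c.mlcp_total_2 - c.mlcp_rest, mlcp_total=c.mlcp_total_2)
    ss2 = mechanics.hai_murphy_steady_state(pool2, registry)
    pool3p = mechanics.EnzymePool(
        mlck_act=mlck_rest, mlck_total=mlck_rest,
        mlcp_f=c.mlcp_p_3 - c.mlcp_rest, mlcp_total=c.mlcp_p_3)
    ss3p = mechanics.hai_murphy_steady_state(pool3p, registry)
    y0 = [ss1.M, ss1.Mp, ss1.AMp, ss1.AM,
          c.vrest_icc, c.vrest_smc,
          ss2.M, ss2.Mp, ss2.AMp, ss2.AM,
          1.0, 0.0,
          ss3.M, ss3.Mp, ss3.AMp, ss3.AM,
          c.vrest_icc, c.vrest_smc,
          ss3p.M, ss3p.Mp, ss3p.AMp, ss3p.AM,
          1.0]
    if c.emptying:
        y0.append(scenario.V_meal_0)
    return np.array(y0)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------
@dataclass
class Trajectory:
    scenario: Scenario
    t: np.ndarray
    states: np.ndarray               # (n_samples, n_states)
    derived: pd.DataFrame
    wall_time_s: float = 0.0

    def state(self, name: str) -> np.ndarray:
        idx = [s[0] for s in STATE_LAYOUT].index(name)
        return self.states[:, idx]

    def to_csv(self, path: str) -> None:
        self.derived.to_csv(path, index=False)


@dataclass(frozen=True)
class ScenarioSummary:
    occlusion_pct: float
    relaxed_antral_radius_cm: float
    contraction_amplitude_cm: float
    ps_open_radius_cm: float
    mean_Q_flow_mL_s: float
    lambda_f_1_plateau: float
    slow_wave_cpm: float
    emptied_volume_L: float = 0.0
    n_cycles: int = 0

    def as_dict(self) -> Dict[str, float]:
        return dict(self.__dict__)


def simulate(scenario: Scenario, registry: Optional[ParameterRegistry] = None
             ) -> Trajectory:
    """Integrate a scenario with a stiff variable-step method.

    Deterministic for fixed solver settings.  Raises
    :class:`SimulationError` if the integrator fails, reporting the last
    valid time.
    """
    registry = registry or load_registry()
    scenario = scenario.validate(registry)
    rhs = make_rhs(scenario, registry)
    y0 = initial_state(scenario, registry, rhs.ctx)
    t_eval = np.arange(0.0, scenario.duration + 1e-9,
                       scenario.output_interval)
    opts = scenario.solver
    start = time.perf_counter()
    sol = solve_ivp(rhs, (0.0, scenario.duration), y0, method=opts.method,
                    rtol=opts.rtol, atol=opts.atol, max_step=opts.max_step,
                    t_eval=t_eval, dense_output=False)
    wall = time.perf_counter() - start
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else 0.0
        raise SimulationError(
            f"integration failed at t={last_t:.3f} s: {sol.message}")
    states = sol.y.T
    rows = []
    for ti, yi in zip(sol.t, states):
        _, d = _core(ti, yi, rhs.ctx, collect=True)
        rows.append(d)
    derived = pd.DataFrame(rows)
    return Trajectory(scenario=scenario, t=sol.t, states=states,
                      derived=derived, wall_time_s=wall)


def run_emptying(scenario: Scenario,
                 registry: Optional[ParameterRegistry] = None
                 ) -> Tuple[Trajectory, pd.DataFrame]:
    """Emptying-mode run; returns the trajectory and the V_meal(t) curve."""
    registry = registry or load_registry()
    if scenario.mode != "emptying":
        raise ValueError("run_emptying requires an emptying-mode scenario")
    traj = simulate(scenario, registry)
    curve = traj.derived[["t_s", "V_meal_L"]].copy()
    return traj, curve


# ---------------------------------------------------------------------------
# summary metrics
# ---------------------------------------------------------------------------
def _cycle_slices(cycle_idx: np.ndarray) -> List[slice]:
    """Slices covering complete cycles of an integer cycle-index array."""
    out = []
    change = np.flatnonzero(np.diff(cycle_idx) != 0) + 1
    for lo, hi in zip(change[:-1], change[1:]):
        out.append(slice(int(lo), int(hi) + 1))
    return out


def summarize(traj: Trajectory,
              registry: Optional[ParameterRegistry] = None) -> ScenarioSummary:
    """Scenario summary metrics over the post-transient window.

    Requires at least three complete slow-wave cycles after the transient.
    """
    registry = registry or load_registry()
    d = traj.derived
    t0 = traj.scenario.transient_s(registry)
    mask = d["t_s"].to_numpy() >= t0
    if mask.sum() < 10:
        raise ValueError("trajectory too short for the transient window")
    dd = d.loc[mask]
    phase = dd["phase_2"].to_numpy()
    r2 = dd["r_fin_2_cm"].to_numpy()
    ant_slices = _cycle_slices(np.floor(phase).astype(int))
    if len(ant_slices) < 3:
        raise ValueError(
            "trajectory spans fewer than three complete slow-wave cycles "
            "after the transient")
    relaxed = np.array([r2[s].max() for s in ant_slices])
    minima = np.array([r2[s].min() for s in ant_slices])
    occl = float(np.mean(100.0 * (relaxed - minima) / relaxed))
    # PS cycles
    lag = registry.get("auxiliary.ps_phase_lag")
    ps_idx = np.floor(phase - lag).astype(int)
    ps_slices = _cycle_slices(ps_idx)
    r3 = dd["r_fin_3_cm"].to_numpy()
    q = dd["Q_flow_cm3_s"].to_numpy()
    if ps_slices:
        ps_open = float(np.mean([r3[s].max() for s in ps_slices]))
        lo, hi = ps_slices[0].start, ps_slices[-1].stop
        mean_q = float(np.mean(q[lo:hi]))
    else:
        ps_open = float(r3.max())
        mean_q = float(np.mean(q))
    # slow-wave frequency from the ICC membrane trace
    vm = dd["Vm_ICC_2_mV"].to_numpy()
    tt = dd["t_s"].to_numpy()
    span = vm.max() - vm.min()
    if span > 1.0:
        peaks, _ = find_peaks(vm, prominence=0.5 * span)
        cpm = (60.0 / float(np.mean(np.diff(tt[peaks])))
               if peaks.size >= 2 else float("nan"))
    else:
        cpm = float("nan")
    emptied = 0.0
    if traj.scenario.mode == "emptying":
        vm_l = d["V_meal_L"].to_numpy()
        emptied = float(vm_l[0] - vm_l[-1])
    return ScenarioSummary(
        occlusion_pct=occl,
        relaxed_antral_radius_cm=float(np.mean(relaxed)),
        contraction_amplitude_cm=float(np.mean(relaxed - minima)),
        ps_open_radius_cm=ps_open,
        mean_Q_flow_mL_s=mean_q,   # cm3/s == mL/s
        lambda_f_1_plateau=float(np.mean(dd["lambda_f_1"].to_numpy())),
        slow_wave_cpm=cpm,
        emptied_volume_L=emptied,
        n_cycles=len(ant_slices),
    )


# ---------------------------------------------------------------------------
# preset scenarios
# ---------------------------------------------------------------------------
def scenario_fixtures() -> Dict[str, Scenario]:
    """The reference scenarios: autonomic contrast at 0.6 L, the volume
    sweep, the high-calorie PS study and the four emptying runs."""
    fixtures = {
        "parasym_0p6L": Scenario(mode="fixed_volume", V_tot=0.6, g_cal=0.0,
                                 O_sym=0, duration=200.0, name="parasym_0p6L"),
        "sympa_0p6L": Scenario(mode="fixed_volume", V_tot=0.6, g_cal=0.0,
                               O_sym=1, duration=200.0, name="sympa_0p6L"),
        "vol_0p2L": Scenario(mode="fixed_volume", V_tot=0.2, g_cal=0.0,
                             O_sym=0, duration=200.0, name="vol_0p2L"),
        "vol_0p5L": Scenario(mode="fixed_volume", V_tot=0.5, g_cal=0.0,
                             O_sym=0, duration=200.0, name="vol_0p5L"),
        "vol_1p1L": Scenario(mode="fixed_volume", V_tot=1.1, g_cal=0.0,
                             O_sym=0, duration=200.0, name="vol_1p1L"),
        "ps_gcal_0p67": Scenario(mode="fixed_volume", V_tot=0.6, g_cal=0.67,
                                 O_sym=0, duration=200.0, name="ps_gcal_0p67"),
    }
    for g in (0.33, 0.38, 0.50, 0.67):
        name = "empty_" + f"{g:.2f}".replace("0.", "0p")
        fixtures[name] = Scenario(mode="emptying", V_meal_0=0.3, g_cal=g,
                                  O_sym=0, duration=440.0, name=name)
    return fixtures
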