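"""Compartment geometry, slow-wave drive and the occlusion metric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from gastroloop.compartments import (
    antrum_radius,
    ca_from_vm,
    drive_window,
    fundus_geometry,
    icc_drive,
    icc_smc_rhs,
    occlusion,
    ps_closure,
    ps_step,
    ps_tonic_radius,
    q_flow,
)
from gastroloop.params import load_registry
from gastroloop.signaling import antrum_signals, mmehc

REG = load_registry()


class TestFundusGeometry:
    def test_reference_bridge_total_gives_unit_distension(self):
        b_max = REG.get("auxiliary.b_max_1")
        ra, r, lam = fundus_geometry(b_max, REG)
        assert ra == pytest.approx(1.0, rel=1e-12)
        assert r == pytest.approx(REG.get("auxiliary.r_ini_1"))
        assert lam == pytest.approx(1.0)

    def test_zero_bridges_is_maximal_distension(self):
        ra0, _, _ = fundus_geometry(0.0, REG)
        ra_max, _, _ = fundus_geometry(REG.get("auxiliary.b_max_1"), REG)
        assert ra0 > ra_max
        # calibrated to the open-cylinder ratio sqrt(V_max/V_min)
        assert ra0 == pytest.approx(np.sqrt(1.2 / 0.08), rel=1e-6)

    def test_stretch_formula(self):
        # lambda = alpha_1*(r/r_ini - 1) + 1 with alpha_1 = 0.21
        ra, _, lam = fundus_geometry(0.0, REG)
        assert lam == pytest.approx(0.21 * (ra - 1.0) + 1.0, rel=1e-12)
        # direct check of the linear law at a ratio of 1.5
        assert 0.21 * (1.5 - 1.0) + 1.0 == pytest.approx(1.105)

    @given(b1=st.floats(0, 0.0237), b2=st.floats(0, 0.0237))
    @settings(max_examples=60, deadline=None)
    def test_distension_decreasing_in_bridges(self, b1, b2):
        lo, hi = sorted((b1, b2))
        assert fundus_geometry(lo, REG)[0] >= fundus_geometry(hi, REG)[0]


class TestICCDrive:
    def test_baseline(self):
        sig = antrum_signals(0.0, 0.0, REG)
        kappa, cpm, t_end = icc_drive(sig, REG)
        assert kappa == pytest.approx(48.0)
        assert cpm == pytest.approx(3.0)
        assert t_end == pytest.approx(20.0)

    def test_excitatory_gain(self):
        sig = antrum_signals(1e9, 0.0, REG)  # saturating cholinergic drive
        kappa, cpm, _ = icc_drive(sig, REG)
        # at saturating firing [ACh] -> A_Ach, so the amplitude gain is the
        # composed limit mmehc(A_Ach; ea params), not the bare 0.15 ceiling
        phi_ea_lim = mmehc(156.43, REG.curve("ea_p_2"))
        assert kappa == pytest.approx(48.0 * (1.0 + phi_ea_lim), rel=1e-3)
        assert kappa > 48.0

    def test_balanced_modulation_keeps_baseline_frequency(self):
        class _S:
            phi_ea_2 = 0.0
            phi_ia_2 = 0.0
            phi_ec_2 = 0.07
            phi_ic_2 = 0.07
        _, cpm, _ = icc_drive(_S, REG)
        assert cpm == pytest.approx(3.0)

    def test_window_periodic_and_bounded(self):
        for ph in np.linspace(0, 1, 33):
            w = drive_window(ph, 0.45, 0.04)
            assert 0.0 <= w <= 1.0
            assert drive_window(ph + 1.0, 0.45, 0.04) == pytest.approx(w)
        assert drive_window(0.2, 0.45, 0.04) > 0.9
        assert drive_window(0.7, 0.45, 0.04) < 0.1


class TestMembranes:
    def test_equal_potentials_no_coupling(self):
        d_icc, d_smc = icc_smc_rhs(-50.0, -50.0, 0.0, 1.0, REG)
        # SMC sees only its leak toward rest
        assert d_smc == pytest.approx(
            -(-50.0 - REG.get("auxiliary.Vm_rest_SMC"))
            / REG.get("auxiliary.tau_m_SMC"))

    def test_unstimulated_icc_relaxes_to_rest(self):
        sol = solve_ivp(lambda t, y: [icc_smc_rhs(y[0], -60.0, 0.0, 1.0,
                                                  REG)[0]],
                        (0, 20), [-30.0], rtol=1e-9, atol=1e-11)
        assert sol.y[0, -1] == pytest.approx(
            REG.get("auxiliary.Vm_rest_ICC"), abs=1e-3)

    def test_decoupled_smc_relaxes_to_rest(self):
        sol = solve_ivp(lambda t, y: [icc_smc_rhs(-20.0, y[0], 0.0, 0.0,
                                                  REG)[1]],
                        (0, 20), [-30.0], rtol=1e-9, atol=1e-11)
        assert sol.y[0, -1] == pytest.approx(
            REG.get("auxiliary.Vm_rest_SMC"), abs=1e-3)

    def test_calcium_map_monotone(self):
        vms = np.linspace(-70, -20, 50)
        ca = [ca_from_vm(v, REG) for v in vms]
        assert np.all(np.diff(ca) > 0)


class TestAntrumGeometry:
    def test_rest_is_undeformed(self):
        r_d, r_fin = antrum_radius(1.0, 1.2, 1.0, REG)
        assert r_d == 0.0
        assert r_fin == pytest.approx(1.2)

    @given(lam=st.floats(0.9, 2.0))
    @settings(max_examples=80, deadline=None)
    def test_radius_never_exceeds_unstressed(self, lam):
        r_d, r_fin = antrum_radius(lam, 1.2, 1.0, REG)
        assert 0.0 < r_fin <= 1.2
        assert r_d >= 0.0

    def test_saturated_contraction_hits_the_occlusion_depth(self):
        f_occ = REG.get("auxiliary.f_occ_2")
        _, r_fin = antrum_radius(2.0, 1.2, 1.0, REG)
        assert r_fin == pytest.approx(1.2 * (1 - f_occ), rel=1e-9)


class TestPylorus:
    def test_flow_law(self):
        assert q_flow(0.0, REG) == 0.0
        assert q_flow(0.48, REG) == pytest.approx(1.67)
        assert q_flow(0.24, REG) == pytest.approx(1.67 * 0.25)

    def test_tonic_radius_closes_at_moderate_bridges(self):
        # numerator hits zero at b = 1/beta_3
        ra, lam, r = ps_tonic_radius(1.0000001 / 236.32, REG)
        assert ra == 0.0 and r == 0.0
        ra2, _, r2 = ps_tonic_radius(2.0 / 236.32, REG)  # beyond closure
        assert r2 == 0.0

    def test_tonic_radius_bounded_by_r_max(self):
        _, _, r = ps_tonic_radius(0.0, REG)
        assert r <= REG.get("gastric.r_max_3")

    def test_closure_fraction_limits(self):
        assert ps_closure(1.0, REG) == 0.0
        assert ps_closure(1.5, REG) == 1.0

    def test_ps_step_composes_tonic_and_phasic(self):
        from gastroloop.mechanics import CrossBridgeState
        from gastroloop.signaling import ps_signals
        sig = ps_signals(0.0, 5.0, 0.0, 0.0, REG)
        xb = CrossBridgeState(1.0, 0.0, 0.0, 0.0)  # zero bridges: max open
        open_state = ps_step(sig, xb, 1.0, REG)
        assert open_state.r_fin_3 == open_state.r_tonic_3 > 0
        assert open_state.Q_flow == pytest.approx(
            q_flow(open_state.r_fin_3, REG))
        closed = ps_step(sig, xb, 1.5, REG)  # phasic stretch past saturation
        assert closed.r_fin_3 == 0.0 and closed.Q_flow == 0.0


class TestOcclusionMetric:
    def _trace(self, relaxed, amplitude, n_cycles=4, n=None):
        # grid aligned with the dip bottoms so the cycle minimum is sampled
        t = np.linspace(0, n_cycles, n or n_cycles * 200 + 1)
        dip = 0.5 * (1 - np.cos(2 * np.pi * t)) ** 8  # narrow dips
        dip = dip / dip.max()
        return relaxed - amplitude * dip

    def test_constant_trace_zero(self):
        assert occlusion(np.full(100, 1.3)) == 0.0

    @pytest.mark.parametrize("relaxed,amplitude,expected", [
        (1.65, 1.31, 79.4),   # printed radius/amplitude pairs
        (0.7, 0.55, 78.6),
        (1.1, 0.89, 80.9),
    ])
    def test_printed_radius_pairs(self, relaxed, amplitude, expected):
        """The radius-based definition reproduces the reported
        amplitude/relaxed-radius ratios."""
        occ = occlusion(self._trace(relaxed, amplitude))
        assert occ == pytest.approx(100.0 * amplitude / relaxed, rel=1e-6)
        assert round(occ, 1) == expected

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            occlusion(self._trace(1.0, 0.5, n_cycles=1, n=50))
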