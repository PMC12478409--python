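"""Enzyme limb, Hai-Murphy kinetics, stress and viscoelastic stretch."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from gastroloop import mechanics
from gastroloop.mechanics import (
    CrossBridgeState,
    EnzymePool,
    active_stress,
    cgmp_from_no,
    combine_enzymes,
    equilibrium_stretch,
    hai_murphy_rhs,
    hai_murphy_steady_state,
    hyperelastic_stress,
    mlck_activation,
    mlcp_from_cgmp,
    total_bridges,
    viscoelastic_rhs,
)
from gastroloop.params import load_registry

REG = load_registry()


def _pool(mlck, mlcp):
    return EnzymePool(mlck_act=mlck, mlck_total=mlck,
                      mlcp_f=max(mlcp - 7.5, 0.0), mlcp_total=mlcp)


class TestEnzymeLimb:
    def test_cgmp_zero_and_half_saturation(self):
        assert cgmp_from_no(0.0, REG) == 0.0
        assert cgmp_from_no(0.02161, REG) == pytest.approx(26.57 / 2,
                                                           rel=1e-12)

    def test_cgmp_direct_evaluation(self):
        expected = 26.57 * 0.68 / (0.02161 + 0.68)
        assert cgmp_from_no(0.68, REG) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(25.75, abs=0.01)

    def test_mlcp_half_saturation_and_direct(self):
        assert mlcp_from_cgmp(0.0, 1, REG) == 0.0
        assert mlcp_from_cgmp(5.5, 1, REG) == pytest.approx(3.75, rel=1e-12)
        c = 13.285
        expected = 2.5 * c ** 2 / (5.5 ** 2 + c ** 2)
        assert mlcp_from_cgmp(c, 2, REG) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.135, abs=0.005)

    def test_mlck_activation_monotone(self):
        assert mlck_activation(0.0, REG) == 0.0
        assert mlck_activation(0.5, REG) <= mlck_activation(1.0, REG)
        # resting fundic calcium reference (regression fixture)
        # independent direct evaluation: 2/(1 + (0.4/0.34)^4)
        base = mlck_activation(0.34, REG)
        assert base == pytest.approx(2.0 / (1.0 + (0.4 / 0.34) ** 4),
                                     rel=1e-10)
        assert base == pytest.approx(0.68595, abs=1e-5)

    def test_combine_modes(self):
        p = combine_enzymes(1.0, 2.5, 0.0, "ps_tonic", REG)
        assert p.mlck_total == 1.0 and p.mlcp_total == 7.5
        p = combine_enzymes(1.0, 2.5, 1.0, "ps_tonic", REG)
        assert p.mlck_total == 0.0 and p.mlcp_total == 10.0
        p = combine_enzymes(1.0, 3.75, 0.0, "fundus", REG)
        assert p.mlcp_total == pytest.approx(11.25)
        with pytest.raises(ValueError):
            combine_enzymes(1.0, 0.0, 1.5, "fundus", REG)


class TestHaiMurphy:
    @given(st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4),
           st.floats(0.0, 3.0), st.floats(7.5, 15.0))
    @settings(max_examples=100, deadline=None)
    def test_conservation_of_rhs(self, state, mlck, mlcp):
        d = hai_murphy_rhs(state, _pool(mlck, mlcp), REG)
        assert abs(d.sum()) < 1e-12

    def test_zero_kinase_relaxes_to_free_myosin(self):
        """With no kinase all mass ends in M: phosphorylated states drain via
        MLCP and latch bridges detach through k_a."""
        pool = _pool(0.0, 7.5)
        ss = hai_murphy_steady_state(pool, REG)
        assert ss.M == pytest.approx(1.0, abs=1e-6)
        assert total_bridges(ss) == pytest.approx(0.0, abs=1e-6)

    def test_conservation_along_trajectory(self):
        pool = _pool(1.5, 7.5)
        y0 = [0.7, 0.1, 0.1, 0.1]
        sol = solve_ivp(lambda t, y: hai_murphy_rhs(y, pool, REG),
                        (0, 100), y0, method="LSODA", rtol=1e-8, atol=1e-10)
        assert np.all(np.abs(sol.y.sum(axis=0) - 1.0) < 1e-7)

    def test_step_increase_monotone_approach(self):
        """After a step increase in kinase the bridge total rises
        monotonically toward the new steady state."""
        lo = hai_murphy_steady_state(_pool(0.2, 7.5), REG)
        pool_hi = _pool(1.5, 7.5)
        sol = solve_ivp(lambda t, y: hai_murphy_rhs(y, pool_hi, REG),
                        (0, 120), list(lo.as_array()), method="LSODA",
                        rtol=1e-9, atol=1e-12, dense_output=True)
        t = np.linspace(0, 120, 400)
        b = sol.sol(t)[2] + sol.sol(t)[3]
        assert np.all(np.diff(b) > -1e-8)
        hi = hai_murphy_steady_state(pool_hi, REG)
        assert b[-1] == pytest.approx(total_bridges(hi), rel=1e-4)

    def test_steady_state_monotone_in_kinase(self):
        bridges = [total_bridges(hai_murphy_steady_state(_pool(m, 7.5), REG))
                   for m in (0.05, 0.2, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(bridges) > 0)

    def test_total_bridges_arithmetic(self):
        s = CrossBridgeState(0.2, 0.3, 0.1, 0.4)
        assert total_bridges(s, "tonic") == pytest.approx(0.5)
        assert total_bridges(CrossBridgeState(0, 0, 0, 0)) == 0.0


class TestStress:
    def test_zero_bridges_zero_stress(self):
        st_ = active_stress(0.0, 1.3, REG)
        assert st_.sigma == 0.0

    def test_o_chem_value(self):
        st_ = active_stress(0.1, 1.0, REG)
        assert st_.o_chem == pytest.approx(-2098.37 / 72980.0, rel=1e-12)
        assert st_.o_mech == 0.0

    def test_identity_collapse(self):
        """(lam_f1 - o_bar - 1) = -o_chem identically, so sigma = o_A*L_bar*b."""
        st_ = active_stress(0.05, 1.4, REG)
        assert st_.sigma == pytest.approx(2098.37 * st_.L_bar * 0.05,
                                          rel=1e-10)

    def test_hyperelastic_polynomial(self):
        reg = load_registry({"auxiliary.A_poly": [1.0, 0.0, 0.0, 0.0, 0.0]})
        assert hyperelastic_stress(2.0, reg) == pytest.approx(2.0)
        reg0 = load_registry({"auxiliary.A_poly": [0.0] * 5})
        assert hyperelastic_stress(1.7, reg0) == 0.0

    def test_default_hyperelastic_increasing_over_operating_range(self):
        lams = np.linspace(1.0, 1.6, 200)
        e = [hyperelastic_stress(x, REG) for x in lams]
        assert np.all(np.diff(e) > 0)
        assert hyperelastic_stress(1.0, REG) == pytest.approx(0.0, abs=1e-12)


class TestViscoelastic:
    def test_equilibrium_and_sign(self):
        lam = 1.25
        e = hyperelastic_stress(lam, REG)
        assert viscoelastic_rhs(lam, e, REG) == pytest.approx(0.0, abs=1e-12)
        assert viscoelastic_rhs(lam, e + 5.0, REG) > 0
        assert viscoelastic_rhs(lam, e - 5.0, REG) < 0

    def test_eta1_at_stress_balance(self):
        # S3*exp(S4) with E = sigma
        lam = 1.2
        e = hyperelastic_stress(lam, REG)
        eta1 = 4.2 * np.exp(-0.19)
        d = viscoelastic_rhs(lam, e + 1.0, REG)
        eta2 = eta1 * np.exp(0.04 * -1.0) * np.tanh(5 * (lam - 0.982))
        assert d == pytest.approx(1.0 / eta2, rel=1e-10)
        assert eta1 == pytest.approx(3.474, abs=0.001)

    @pytest.mark.parametrize("lam0,sigma", [(1.0, 20.0), (1.5, 5.0),
                                            (1.1, 40.0)])
    def test_converges_to_root_finder_equilibrium(self, lam0, sigma):
        """From any initial stretch under constant stress, lambda converges
        to the root of E(lambda) = sigma (independent root-finder oracle)."""
        sol = solve_ivp(lambda t, y: [viscoelastic_rhs(y[0], sigma, REG)],
                        (0, 60.0), [lam0], method="BDF",
                        rtol=1e-9, atol=1e-11)
        target = equilibrium_stretch(sigma, REG)
        assert sol.y[0, -1] == pytest.approx(target, rel=1e-5)
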