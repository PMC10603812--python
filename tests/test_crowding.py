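"""Forward crowding model: exchange equilibrium, ΔΔG decomposition, ΔΓ_S."""

import numpy as np
import pytest

from crowdtherm import (
    aom_free_energy,
    delta_delta_g,
    exchange_potential,
    model_enthalpy_entropy,
    osmotic_pressure,
    molality_to_composition,
    preferential_hydration_change,
    surface_composition,
)
from crowdtherm.params import CosoluteParams, ProteinCrowdingParams


class TestExchangePotential:
    def test_symmetric_point(self):
        assert exchange_potential(0.5, 1.0, 0.0) == pytest.approx(0.0, abs=1e-14)

    def test_langmuir_reduction(self):
        phi = np.array([0.1, 0.3, 0.7])
        np.testing.assert_allclose(exchange_potential(phi, 1.0, 0.0),
                                   np.log(phi / (1 - phi)), rtol=1e-14)

    def test_hand_value(self):
        # ln 0.2 - 2 ln 0.8 - 1
        assert exchange_potential(0.2, 2.0, 0.0) == pytest.approx(-2.1632, abs=1e-4)

    def test_strictly_increasing_for_moderate_chi(self):
        phi = np.linspace(1e-4, 1 - 1e-4, 500)
        for nu, chi in [(1.0, 0.0), (5.0, 0.5), (12.0, 0.3)]:
            mu = exchange_potential(phi, nu, chi)
            assert np.all(np.diff(mu) > 0)

    def test_boundaries_rejected(self):
        for bad in (0.0, 1.0):
            with pytest.raises(ValueError):
                exchange_potential(bad, 2.0, 0.0)


class TestSurfaceComposition:
    def test_no_surface_field(self):
        state = surface_composition(0.17, 8.0, 0.4, 0.0)
        assert state.phi_s == pytest.approx(state.phi_b, abs=1e-10)

    def test_langmuir_closed_form(self):
        # ν=1, χ=0, ϕ_b=0.1, ε=ln 9: ϕ_s/(1-ϕ_s) = (1/9)/9 -> ϕ_s = 1/82
        state = surface_composition(0.1, 1.0, 0.0, np.log(9.0))
        assert state.phi_s == pytest.approx(1.0 / 82.0, rel=1e-10)

    def test_hard_repulsion_limit(self):
        state = surface_composition(0.1, 1.0, 0.0, 20.0)
        assert state.phi_s < 1e-6

    @pytest.mark.parametrize("eps,cmp", [(0.5, np.less), (-0.5, np.greater)])
    def test_sign_of_partitioning(self, eps, cmp):
        state = surface_composition(0.15, 6.0, 0.3, eps)
        assert cmp(state.phi_s, state.phi_b)


class TestDecomposition:
    def test_zero_concentration(self, trehalose_like, miniprotein):
        d = delta_delta_g(0.0, 298.0, trehalose_like, miniprotein)
        assert d.dg_nu == d.dg_chi == d.dg_eps == d.total == 0.0

    def test_null_cosolute_invariance(self):
        """Solvent-sized, chemically neutral cosolute leaves folding unchanged."""
        cos = CosoluteParams(name="null", m_c=18.015, vbar_c=18.07)
        prot = ProteinCrowdingParams(name="p", dsasa=900.0, epsilon=0.0)
        for c in [0.3, 1.0, 2.5]:
            d = delta_delta_g(c, 298.0, cos, prot)
            assert abs(d.total) < 1e-12

    def test_nu_term_unit_oracle(self):
        """ΔSASA=1000 Ų, ν=8: ΔΔG_ν = −Π·ΔSASA·δ ≈ −0.94 kJ/mol per MPa."""
        cos = CosoluteParams(name="c", m_c=250.0, vbar_c=8 * 18.07)
        prot = ProteinCrowdingParams(name="p", dsasa=1000.0)
        # pick the molality whose Π is 1e6 Pa, then check the conversion
        from scipy.optimize import brentq

        def f(m):
            comp = molality_to_composition(m, cos)
            return osmotic_pressure(comp.phi_c, cos, 298.0) - 1e6
        m_star = brentq(f, 1e-6, 2.0)
        d = delta_delta_g(m_star, 298.0, cos, prot)
        assert d.dg_nu == pytest.approx(-0.9356, abs=2e-3)

    def test_closure_bit_exact(self, trehalose_like, miniprotein):
        for c in [0.2, 0.9, 1.5]:
            d = delta_delta_g(c, 305.0, trehalose_like, miniprotein)
            assert d.total == d.dg_nu + d.dg_chi + d.dg_eps  # shared code path

    def test_monotone_stabilization_steric_only(self):
        cos = CosoluteParams(name="c", m_c=342.3, vbar_c=209.5, chi_a=0.3)
        prot = ProteinCrowdingParams(name="p", dsasa=800.0, epsilon=0.0)
        cgrid = np.linspace(0.0, 1.5, 12)
        tot = [delta_delta_g(c, 298.0, cos, prot).total for c in cgrid]
        assert np.all(np.diff(tot) < 0)

    def test_aom_reduction_constant_slope(self):
        """For χ=0, ε=0 the model is exactly ΔΔG = Π·ΔV_ex."""
        cos = CosoluteParams(name="c", m_c=342.3, vbar_c=209.5)
        prot = ProteinCrowdingParams(name="p", dsasa=800.0)
        dv_ex = -prot.dsasa * prot.depletion_thickness(cos.nu)  # A^3
        dv_ex_m3_mol = dv_ex * 1e-30 * 6.02214076e23
        for c in [0.1, 0.7, 1.4]:
            comp = molality_to_composition(c, cos)
            pi = osmotic_pressure(comp.phi_c, cos, 298.0)
            d = delta_delta_g(c, 298.0, cos, prot)
            assert d.total * 1000.0 / pi == pytest.approx(dv_ex_m3_mol, rel=1e-12)
            assert d.dg_chi == 0.0 and d.dg_eps == 0.0

    def test_aom_equals_nu_term(self, trehalose_like, miniprotein):
        for c in [0.3, 1.2]:
            assert aom_free_energy(c, 298.0, trehalose_like, miniprotein) == \
                delta_delta_g(c, 298.0, trehalose_like, miniprotein).dg_nu

    def test_specificity_opposite_epsilon(self, trehalose_like):
        """Equal ΔSASA, opposite ε: identical ν terms, opposite-signed ε terms."""
        attract = ProteinCrowdingParams(name="a", dsasa=800.0, epsilon=-0.4)
        repel = ProteinCrowdingParams(name="r", dsasa=800.0, epsilon=+0.4)
        da = delta_delta_g(1.0, 298.0, trehalose_like, attract)
        dr = delta_delta_g(1.0, 298.0, trehalose_like, repel)
        assert da.dg_nu == dr.dg_nu
        assert da.dg_eps > 0 > dr.dg_eps

    def test_negative_concentration_rejected(self, trehalose_like, miniprotein):
        with pytest.raises(ValueError):
            delta_delta_g(-0.1, 298.0, trehalose_like, miniprotein)


class TestPreferentialHydration:
    def test_steric_only_constant_gamma(self):
        """Linear ΔΔG = ΔV_ex·Π gives ΔΓ_S = ΔV_ex/V̄_S, constant and negative."""
        cos = CosoluteParams(name="c", m_c=342.3, vbar_c=209.5)
        prot = ProteinCrowdingParams(name="p", dsasa=800.0)
        pi_grid = np.linspace(1e5, 2e7, 60)
        gam = preferential_hydration_change(prot, cos, pi_grid)
        dv_ex_m3 = -prot.dsasa * prot.depletion_thickness(cos.nu) * 1e-30 * 6.02214076e23
        expect = dv_ex_m3 / (cos.vbar_s * 1e-6)
        np.testing.assert_allclose(gam, expect, rtol=1e-6)
        assert np.all(gam < 0)

    def test_grid_refinement_converges(self, trehalose_like, miniprotein):
        """Finite-difference ΔΓ_S at a fixed Π converges under step halving."""
        pi0 = 5e6
        vals = []
        for npts in (20, 40, 80):
            grid = np.linspace(pi0 * 0.5, pi0 * 1.5, npts)
            gam = preferential_hydration_change(miniprotein, trehalose_like, grid)
            vals.append(np.interp(pi0, grid, gam))
        assert abs(vals[2] - vals[1]) <= abs(vals[1] - vals[0]) + 1e-9
        assert vals[2] == pytest.approx(vals[1], rel=1e-3)

    def test_stabilizing_cosolute_negative_gamma(self, trehalose_like):
        prot = ProteinCrowdingParams(name="p", dsasa=800.0, epsilon=0.0)
        grid = np.linspace(1e5, 1.5e7, 50)
        gam = preferential_hydration_change(prot, trehalose_like, grid)
        assert np.all(gam < 0)

    def test_bad_grid_rejected(self, trehalose_like, miniprotein):
        with pytest.raises(ValueError):
            preferential_hydration_change(miniprotein, trehalose_like,
                                          np.array([2e6, 1e6]))


class TestEnthalpyEntropy:
    def test_gibbs_helmholtz_identity(self, trehalose_like, miniprotein):
        for c in [0.4, 1.2]:
            ddh, tdds = model_enthalpy_entropy(c, 298.0, trehalose_like, miniprotein)
            ddg = delta_delta_g(c, 298.0, trehalose_like, miniprotein).total
            assert ddg == pytest.approx(ddh - tdds, rel=1e-9)

    def test_athermal_parameterization_zero_enthalpy(self):
        """Purely entropic χ and ε make every term ∝ T, so ΔΔH vanishes."""
        cos = CosoluteParams(name="c", m_c=342.3, vbar_c=209.5, chi_a=0.4, chi_b=0.0)
        prot = ProteinCrowdingParams(name="p", dsasa=800.0, epsilon=0.3,
                                     eps_h=0.0, eps_s=0.3, split_set=True)
        ddh, _ = model_enthalpy_entropy(1.0, 298.0, cos, prot)
        assert abs(ddh) < 1e-6

    def test_compensation_sign_pattern(self):
        """ε_h > 0, ε_s < 0: enthalpic repulsion + entropic attraction yield
        compensating positive ΔΔH_ε and TΔΔS_ε for the ε term."""
        cos = CosoluteParams(name="c", m_c=342.3, vbar_c=209.5)  # chi = 0
        prot0 = ProteinCrowdingParams(name="p", dsasa=800.0)  # eps = 0
        prot = ProteinCrowdingParams(name="p", dsasa=800.0, epsilon=0.3,
                                     eps_h=1.3, eps_s=-1.0, split_set=True)
        ddh0, tdds0 = model_enthalpy_entropy(1.0, 298.0, cos, prot0)
        ddh, tdds = model_enthalpy_entropy(1.0, 298.0, cos, prot)
        assert ddh - ddh0 > 0
        assert tdds - tdds0 > 0
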