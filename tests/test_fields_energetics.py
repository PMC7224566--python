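"""Grid/field data model and the energy/momentum-source operators."""

import math

import numpy as np
import pytest

from clotflow.fields import Grid, SimulationState, integrate, trapezoid_weights
from clotflow.energetics import (bulk_volume_fraction, chemical_potential,
                                 curl_potential_to_F, darcy_drag,
                                 double_well_derivative, elastic_stress,
                                 surface_tension_force, total_energy)
from clotflow.materials import MaterialParams


class TestGrid:
    def test_invariants(self):
        g = Grid((8, 6), (2.0, 1.0))
        assert g.spacing == (2.0 / 7, 1.0 / 5)
        assert g.coords(0)[0] == 0.0
        with pytest.raises(ValueError):
            Grid((3, 8), (1.0, 1.0))
        with pytest.raises(ValueError):
            Grid((8, 8), (1.0, -1.0))

    def test_periodic_spacing_excludes_duplicate_node(self):
        g = Grid((8, 6), (2.0, 1.0), periodic=(True, False))
        assert g.spacing[0] == 2.0 / 8
        assert g.coords(0)[-1] == pytest.approx(2.0 - 2.0 / 8)

    def test_trapezoid_weights_sum_to_volume(self):
        g = Grid((9, 7), (2.0, 1.5))
        assert trapezoid_weights(g).sum() == pytest.approx(3.0)


class TestSimulationState:
    def test_exactly_one_deformation_carrier(self, grid2d):
        with pytest.raises(ValueError):
            SimulationState(grid2d, np.ones(grid2d.shape),
                            [grid2d.zeros(), grid2d.zeros()], grid2d.zeros())

    def test_uniform_blood_psi_gives_identity_F(self, grid2d):
        st = SimulationState.uniform_blood(grid2d, formulation="psi")
        F = st.deformation_gradient()
        assert np.allclose(F[0][0], 1.0) and np.allclose(F[1][1], 1.0)
        assert np.allclose(F[0][1], 0.0) and np.allclose(F[1][0], 0.0)


class TestDoubleWell:
    def test_roots(self):
        for phi in (0.0, 0.5, 1.0):
            assert double_well_derivative(np.array(phi), 0.3) == 0.0

    def test_hand_value(self):
        assert double_well_derivative(np.array(0.25), 1.0) == \
            pytest.approx(0.09375)

    def test_antisymmetry_about_half(self):
        phi = np.linspace(-0.2, 1.2, 41)
        g = double_well_derivative(phi, 0.7)
        gref = double_well_derivative(1.0 - phi, 0.7)
        assert np.allclose(g, -gref)


class TestChemicalPotential:
    def test_uniform_equilibrium_phases_vanish(self, grid2d):
        params = MaterialParams(sigma=1e-3, h=0.1, lambda_e0=1.0)
        F = SimulationState.uniform_blood(grid2d).identity_F()
        for val in (0.0, 1.0):
            mu = chemical_potential(np.full(grid2d.shape, val), F, params,
                                    grid2d, lambda_e=1.0)
            assert np.allclose(mu, 0.0, atol=1e-14)

    def test_uniform_quarter_with_identity_F(self, grid2d):
        params = MaterialParams(sigma=2.0 * math.sqrt(2) / 3.0, h=1.0,
                                gamma=1.0)
        # lambda = 1 with these sigma, h
        F = SimulationState.uniform_blood(grid2d).identity_F()
        mu = chemical_potential(np.full(grid2d.shape, 0.25), F, params,
                                grid2d, lambda_e=1.0)
        assert np.allclose(mu, 0.09375)

    def test_stretched_F_adds_half_trace(self, grid2d):
        params = MaterialParams(sigma=2.0 * math.sqrt(2) / 3.0, h=1.0)
        st = SimulationState.uniform_blood(grid2d)
        F = st.identity_F()
        F[0][0][...] = 2.0  # tr(F^T F - I) = 4 + 1 - 2 = 3 in 2D
        mu = chemical_potential(np.full(grid2d.shape, 0.25), F, params,
                                grid2d, lambda_e=1.0)
        assert np.allclose(mu, 0.09375 + 1.5)


class TestElasticStress:
    def test_undeformed_zero(self, grid2d):
        st = SimulationState.uniform_blood(grid2d)
        S = elastic_stress(st.identity_F(), np.zeros(grid2d.shape), 1.0)
        for row in S:
            for comp in row:
                assert np.allclose(comp, 0.0)

    def test_pure_blood_zero_regardless_of_F(self, grid2d):
        st = SimulationState.uniform_blood(grid2d)
        F = st.identity_F()
        F[0][1][...] = 5.0
        S = elastic_stress(F, np.ones(grid2d.shape), 1.0)
        for row in S:
            for comp in row:
                assert np.allclose(comp, 0.0)

    def test_simple_shear_components(self, grid2d):
        gt = 0.37  # accumulated shear
        st = SimulationState.uniform_blood(grid2d)
        F = st.identity_F()
        F[0][1][...] = gt
        S = elastic_stress(F, np.zeros(grid2d.shape), 1.0)
        assert np.allclose(S[0][0], gt**2)
        assert np.allclose(S[0][1], gt)
        assert np.allclose(S[1][0], gt)
        assert np.allclose(S[1][1], 0.0)


class TestSurfaceTension:
    def test_uniform_phase_gives_zero(self, grid2d):
        f = surface_tension_force(np.full(grid2d.shape, 0.7), 1e-4, grid2d)
        assert all(np.allclose(c, 0.0) for c in f)

    def test_1d_interface_force_is_normal(self):
        g = Grid((64, 16), (2.0, 1.0))
        x, _ = g.meshgrid()
        phi = 0.5 * (1 + np.tanh((x - 1.0) / 0.1))
        f = surface_tension_force(phi, 1e-3, g)
        assert np.max(np.abs(f[1])) < 1e-10  # tangential component vanishes

    def test_linearity_in_lambda(self, grid2d, rng):
        phi = rng.random(grid2d.shape)
        f1 = surface_tension_force(phi, 1.0, grid2d)
        f2 = surface_tension_force(phi, 2.0, grid2d)
        for a, b in zip(f1, f2):
            assert np.allclose(b, 2.0 * a)

    def test_integrates_to_zero_over_closed_interface(self):
        g = Grid((96, 96), (2.0, 2.0))
        x, y = g.meshgrid()
        r = np.hypot(x - 1.0, y - 1.0)
        phi = 0.5 * (1 + np.tanh((r - 0.5) / 0.08))
        f = surface_tension_force(phi, 1e-3, g)
        for comp in f:
            net = abs(integrate(comp, g))
            l1 = integrate(np.abs(comp), g)
            assert net < 1e-8 * l1 + 1e-16


class TestDarcyDrag:
    def test_pure_blood_no_drag(self, grid2d):
        u = [np.ones(grid2d.shape), np.ones(grid2d.shape)]
        d = darcy_drag(u, np.ones(grid2d.shape), 1.0, 1e-4)
        assert all(np.allclose(c, 0.0) for c in d)

    def test_free_flow_limit(self, grid2d):
        u = [np.ones(grid2d.shape), np.zeros(grid2d.shape)]
        d = darcy_drag(u, np.zeros(grid2d.shape), 1.0, 1e12)
        assert np.max(np.abs(d[0])) < 1e-11

    def test_direct_substitution(self, grid2d):
        eta2, kc = 0.3, 1e-4
        u = [np.ones(grid2d.shape), np.zeros(grid2d.shape)]
        d = darcy_drag(u, np.zeros(grid2d.shape), eta2, kc)
        assert np.allclose(d[0], -eta2 / kc)
        assert np.allclose(d[1], 0.0)

    def test_nonpositive_kappa_rejected(self, grid2d):
        with pytest.raises(ValueError):
            darcy_drag([np.ones(grid2d.shape)] * 2, np.zeros(grid2d.shape),
                       1.0, 0.0)


class TestTotalEnergy:
    def test_uniform_phases_zero(self, grid2d):
        params = MaterialParams(sigma=1e-3, h=0.1)
        for val in (0.0, 1.0):
            st = SimulationState.uniform_blood(grid2d)
            st.phi = np.full(grid2d.shape, val)
            assert total_energy(st, params) == pytest.approx(0.0, abs=1e-14)

    def test_tanh_interface_energy_closed_form(self):
        # the equilibrium profile of the [0,1] double well is
        # phi = (1 + tanh(x / 2h)) / 2, and its mixing energy per unit
        # interface area integrates (by hand) to lambda / (6 h)
        sigma, h = 2.5e-3, 0.05
        g = Grid((512, 8), (2.0, 1.0))
        params = MaterialParams(sigma=sigma, h=h, lambda_e0=0.0)
        x, _ = g.meshgrid()
        st = SimulationState.uniform_blood(g)
        st.phi = 0.5 * (1 + np.tanh((x - 1.0) / (2.0 * h)))
        e_mix, _ = total_energy(st, params, parts=True)
        assert e_mix == pytest.approx(params.mixing_lambda / (6.0 * h),
                                      rel=0.02)

    def test_uniform_stretch_elastic_energy(self, grid2d):
        eps, lam_e = 0.1, 0.8
        params = MaterialParams(sigma=0.0, lambda_e0=lam_e)
        st = SimulationState.uniform_blood(grid2d)
        st.phi = np.zeros(grid2d.shape)
        st.F[0][0][...] = 1.0 + eps
        V = 1.2 * 1.0
        expected = 0.5 * lam_e * (2 * eps + eps**2) * V
        _, e_el = total_energy(st, params, parts=True)
        assert e_el == pytest.approx(expected, rel=1e-12)

    def test_mixing_part_nonnegative(self, grid2d, rng):
        params = MaterialParams(sigma=1e-3, h=0.1)
        st = SimulationState.uniform_blood(grid2d)
        st.phi = rng.random(grid2d.shape)
        e_mix, _ = total_energy(st, params, parts=True)
        assert e_mix >= 0.0


class TestBulkVolumeFraction:
    def test_pure_blood_both_conventions(self, grid2d):
        phi = np.ones(grid2d.shape)
        assert bulk_volume_fraction(phi, grid2d) == pytest.approx(0.0)
        assert bulk_volume_fraction(phi, grid2d, "as_printed") == \
            pytest.approx(0.0)

    def test_pure_thrombus(self, grid2d):
        phi = np.zeros(grid2d.shape)
        assert bulk_volume_fraction(phi, grid2d) == pytest.approx(1.0)
        assert bulk_volume_fraction(phi, grid2d, "as_printed") == \
            pytest.approx(0.5)

    def test_half_domain(self):
        g = Grid((64, 8), (1.0, 1.0))
        x, _ = g.meshgrid()
        phi = (x > 0.5).astype(float)
        assert bulk_volume_fraction(phi, g) == pytest.approx(0.5, abs=0.02)


class TestCurlPotential:
    def test_identity_potential(self, grid2d):
        x, y = grid2d.meshgrid()
        F = curl_potential_to_F([y, -x], grid2d)
        assert np.allclose(F[0][0], 1.0) and np.allclose(F[1][1], 1.0)
        assert np.allclose(F[0][1], 0.0) and np.allclose(F[1][0], 0.0)

    def test_linear_potential_constant_F(self, grid2d):
        a1, b1, a2, b2 = 0.3, -0.7, 1.1, 0.2
        x, y = grid2d.meshgrid()
        F = curl_potential_to_F([a1 * x + b1 * y, a2 * x + b2 * y], grid2d)
        assert np.allclose(F[0][0], b1) and np.allclose(F[0][1], -a1)
        assert np.allclose(F[1][0], b2) and np.allclose(F[1][1], -a2)

    def test_rows_discretely_divergence_free(self, rng):
        from clotflow.fields import deriv
        g = Grid((48, 48), (1.0, 1.0), periodic=(True, True))
        x, y = g.meshgrid()
        psi = [np.sin(2 * math.pi * x) * np.cos(2 * math.pi * y),
               np.cos(4 * math.pi * y)]
        F = curl_potential_to_F(psi, g)
        for i in range(2):
            d = deriv(F[i][0], g, 0) + deriv(F[i][1], g, 1)
            assert np.max(np.abs(d)) < 1e-10

    def test_rejects_3d(self):
        g = Grid((6, 6, 6), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            curl_potential_to_F([np.zeros(g.shape)] * 2, g)
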