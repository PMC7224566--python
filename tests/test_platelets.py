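"""Coarse-grained platelet stage: seeding, state machine, interactions,
transport, stationarity and the Lagrangian-to-Eulerian handoff."""

import math

import numpy as np
import pytest
from scipy import stats

from clotflow.fields import Grid, integrate
from clotflow.platelets import (ACTIVATED, PASSIVE, TRIGGERED, FCMConfig,
                                PlateletEnsemble, advect_platelets,
                                fcm_volume_fraction, handoff_to_phasefield,
                                near_wall_profile, pairwise_forces,
                                seed_platelets, simulate_aggregation,
                                stationarity, thrombus_VF, update_states)
from clotflow.scenarios import DepositionSite


def make_site(x_interval=(2.0, 2.5), cy=0.5, cz=0.5, R=0.45,
              capture=0.06, angles=(0.0, 2 * math.pi)):
    return DepositionSite(x_interval, angles, capture_radius=capture,
                          lumen=(cy, cz, lambda x: np.full(np.shape(x), R)))


class TestSeeding:
    def test_exact_count_inside_lumen(self):
        ens = seed_platelets((6.0, 1.0, 1.0), 200, seed=3)
        assert ens.n == 200
        r = np.hypot(ens.x[:, 1] - 0.5, ens.x[:, 2] - 0.5)
        assert np.all(r < 0.45)
        assert np.all((ens.x[:, 0] >= 0) & (ens.x[:, 0] <= 6.0))

    def test_deterministic_given_seed(self):
        a = seed_platelets((6.0, 1.0, 1.0), 50, seed=7)
        b = seed_platelets((6.0, 1.0, 1.0), 50, seed=7)
        assert np.array_equal(a.x, b.x)

    def test_radial_distribution_matches_profile(self):
        # empirical CDF of normalized radius against the configured
        # marginated profile (KS statistic < 0.05 at n = 1e4)
        n = 10_000
        ens = seed_platelets((2.0, 1.0, 1.0), n, seed=11)
        r = np.hypot(ens.x[:, 1] - 0.5, ens.x[:, 2] - 0.5)
        s = r / (0.45 * 0.98)
        grid = np.linspace(0, 1, 1001)
        pdf = near_wall_profile(grid)
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        ks = stats.ks_1samp(s, lambda q: np.interp(q, grid, cdf))
        assert ks.statistic < 0.05


class TestStateMachine:
    def test_isolated_platelet_stays_passive(self):
        ens = seed_platelets((6.0, 1.0, 1.0), 1, seed=0)
        cfg = FCMConfig(r_p=0.01)
        for t in np.linspace(0, 10, 50):
            ens = update_states(ens, [], t, cfg)
        assert ens.state[0] == PASSIVE

    def test_activation_delay_honored(self):
        cfg = FCMConfig(r_p=0.01, tau_act=0.2)
        site = make_site()
        # one platelet parked on the site patch near the wall
        x = np.array([[2.2, 0.5 + 0.44, 0.5]])
        ens = PlateletEnsemble(x, np.zeros((1, 3)), np.full(1, cfg.r_p),
                               np.array([PASSIVE]), np.array([math.nan]),
                               np.zeros(1, bool))
        ens = update_states(ens, [site], 1.0, cfg)
        assert ens.state[0] == TRIGGERED
        ens = update_states(ens, [site], 1.19, cfg)
        assert ens.state[0] == TRIGGERED  # not yet
        ens = update_states(ens, [site], 1.2, cfg)
        assert ens.state[0] == ACTIVATED
        assert ens.radius[0] == pytest.approx(cfg.r_eff)

    def test_activated_radius_is_sixty_fold(self):
        cfg = FCMConfig(r_p=1.5e-6)
        assert cfg.r_eff == pytest.approx(90e-6)

    def test_no_sites_no_activation(self):
        # null model: with all deposition sites removed nothing ever
        # activates
        ens = seed_platelets((6.0, 1.0, 1.0), 100, seed=5)
        cfg = FCMConfig(r_p=0.005)
        for t in np.linspace(0, 5, 30):
            ens = update_states(ens, [], t, cfg)
        assert np.all(ens.state == PASSIVE)

    def test_monotone_progression(self):
        cfg = FCMConfig(r_p=0.01)
        site = make_site()
        x = np.array([[2.2, 0.92, 0.5]])
        ens = PlateletEnsemble(x, np.zeros((1, 3)), np.full(1, cfg.r_p),
                               np.array([PASSIVE]), np.array([math.nan]),
                               np.zeros(1, bool))
        seen = []
        for t in np.linspace(0, 1.0, 30):
            ens = update_states(ens, [site], t, cfg)
            seen.append(int(ens.state[0]))
        assert np.all(np.diff(seen) >= 0)  # never backwards

    def test_tau_act_range_enforced(self):
        with pytest.raises(ValueError):
            FCMConfig(tau_act=0.5)


class TestPairwiseForces:
    def _pair(self, sep, cfg):
        x = np.array([[0.0, 0.0, 0.0], [sep, 0.0, 0.0]])
        return PlateletEnsemble(x, np.zeros((2, 3)),
                                np.full(2, cfg.r_eff),
                                np.full(2, ACTIVATED),
                                np.zeros(2), np.zeros(2, bool))

    def test_zero_morse_force_at_equilibrium(self):
        cfg = FCMConfig(r_p=0.01, repulsion_amplitude=0.0)
        _, beta, r0 = cfg.morse_params(0.0)
        F = pairwise_forces(self._pair(r0, cfg), cfg)
        assert np.allclose(F, 0.0, atol=1e-15)

    def test_zero_beyond_cutoff(self):
        cfg = FCMConfig(r_p=0.01)
        _, beta, r0 = cfg.morse_params(0.0)
        F = pairwise_forces(self._pair(r0 + 6.0 / beta, cfg), cfg)
        assert np.allclose(F, 0.0)

    def test_newtons_third_law_and_finite_difference(self):
        cfg = FCMConfig(r_p=0.01, repulsion_amplitude=0.0)
        depth, beta, r0 = cfg.morse_params(0.0)
        sep = r0 + 0.1 * cfg.repulsion_length
        F = pairwise_forces(self._pair(sep, cfg), cfg)
        assert np.allclose(F[0], -F[1])
        # central difference of the potential
        def U(r):
            e = math.exp(-beta * (r - r0))
            return depth * (e**2 - 2 * e)
        eps = 1e-7
        expect = -(U(sep + eps) - U(sep - eps)) / (2 * eps)
        # force on particle 1 along +x should equal -dU/dr
        assert F[1][0] == pytest.approx(expect, rel=1e-6)

    def test_passive_pairs_do_not_interact(self):
        cfg = FCMConfig(r_p=0.01)
        ens = self._pair(2.0 * cfg.r_eff, cfg)
        ens.state[:] = PASSIVE
        ens.trigger_time[:] = math.nan
        F = pairwise_forces(ens, cfg)
        assert np.allclose(F, 0.0)

    def test_coincident_centers_capped_with_warning(self):
        cfg = FCMConfig(r_p=0.01)
        with pytest.warns(RuntimeWarning, match="coincident"):
            F = pairwise_forces(self._pair(0.0, cfg), cfg)
        assert np.all(np.isfinite(F))


class TestTransport:
    def test_zero_flow_zero_force_static(self):
        cfg = FCMConfig(r_p=0.01)
        ens = seed_platelets((2.0, 1.0, 1.0), 10, seed=0)
        out = advect_platelets(ens, None, 0.1, cfg)
        assert np.array_equal(out.x, ens.x)

    def test_uniform_flow_exact_displacement(self):
        cfg = FCMConfig(r_p=0.01)
        ens = seed_platelets((2.0, 1.0, 1.0), 10, seed=0)
        U = np.array([0.3, -0.1, 0.05])
        out = advect_platelets(ens, lambda p: U, 0.2, cfg)
        assert np.allclose(out.x - ens.x, 0.2 * U)

    def test_envelope_average_in_poiseuille_matches_quadrature(self):
        # particle off the centerline samples the parabola through its
        # Gaussian envelope; the averaged velocity matches an independent
        # fine-grid quadrature
        from clotflow.platelets import envelope_average_velocity
        g = Grid((48, 48), (1.0, 1.0))
        x, y = g.meshgrid()
        flow = [y * (1 - y) * 4.0, np.zeros(g.shape)]
        pos = np.array([0.5, 0.3])
        sigma = 0.05
        v = envelope_average_velocity(flow, g, pos, sigma)
        # closed form: E[4 y (1-y)] over N(0.3, sigma^2) = 4(m - m^2 - s^2)
        expect = 4.0 * (0.3 - 0.3**2 - sigma**2)
        assert v[0] == pytest.approx(expect, rel=0.01)
        assert abs(v[1]) < 1e-12

    def test_outgoing_platelets_removed(self):
        cfg = FCMConfig(r_p=0.01)
        ens = seed_platelets((2.0, 1.0, 1.0), 20, seed=0)
        out = advect_platelets(ens, lambda p: np.array([50.0, 0, 0]), 0.1,
                               cfg, domain=((0, 2.0), (0, 1.0), (0, 1.0)))
        assert out.n == 0

    def test_frozen_platelets_do_not_move(self):
        cfg = FCMConfig(r_p=0.01)
        ens = seed_platelets((2.0, 1.0, 1.0), 5, seed=0)
        ens.frozen[:] = True
        out = advect_platelets(ens, lambda p: np.array([1.0, 0, 0]), 0.1,
                               cfg)
        assert np.array_equal(out.x, ens.x)


class TestStationarity:
    def test_zero_displacement_is_stationary(self):
        assert stationarity(0.0, 1.0)

    def test_full_diameter_is_not(self):
        assert not stationarity(1.0, 1.0)

    def test_half_threshold_is(self):
        assert stationarity(1.0 / 200.0, 1.0)

    def test_threshold_is_strict(self):
        assert not stationarity(1.0 / 100.0, 1.0)


class TestVolumeFraction:
    def _single(self, cfg, pos=(1.0, 0.5, 0.5)):
        x = np.array([list(pos)])
        return PlateletEnsemble(x, np.zeros((1, 3)),
                                np.full(1, cfg.r_eff),
                                np.full(1, ACTIVATED), np.zeros(1),
                                np.zeros(1, bool))

    def test_single_particle_volume_normalization(self):
        cfg = FCMConfig(r_p=0.2 / 60.0)  # r_eff = 0.2
        g = Grid((64, 32, 32), (2.0, 1.0, 1.0))
        psi = fcm_volume_fraction(self._single(cfg), g, cfg)
        Vp = 4.0 / 3.0 * math.pi * cfg.r_eff**3
        assert integrate(psi, g) == pytest.approx(Vp, rel=0.005)

    def test_superposition(self):
        cfg = FCMConfig(r_p=0.2 / 60.0)
        g = Grid((64, 32, 32), (2.0, 1.0, 1.0))
        a = fcm_volume_fraction(self._single(cfg, (0.7, 0.5, 0.5)), g, cfg)
        b = fcm_volume_fraction(self._single(cfg, (1.3, 0.5, 0.5)), g, cfg)
        ens = PlateletEnsemble(
            np.array([[0.7, 0.5, 0.5], [1.3, 0.5, 0.5]]),
            np.zeros((2, 3)), np.full(2, cfg.r_eff),
            np.full(2, ACTIVATED), np.zeros(2), np.zeros(2, bool))
        both = fcm_volume_fraction(ens, g, cfg)
        assert np.allclose(both, a + b, atol=1e-12)

    def test_peak_value_is_gaussian_maximum(self):
        cfg = FCMConfig(r_p=0.2 / 60.0)
        g = Grid((64, 48, 48), (2.0, 1.0, 1.0))
        psi = fcm_volume_fraction(self._single(cfg), g, cfg)
        sigma = cfg.envelope_factor * cfg.r_eff
        Vp = 4.0 / 3.0 * math.pi * cfg.r_eff**3
        expect = Vp / (2 * math.pi * sigma**2) ** 1.5
        assert psi.max() == pytest.approx(expect, rel=0.02)

    def test_under_resolved_envelope_rejected(self):
        cfg = FCMConfig(r_p=0.001)
        g = Grid((8, 8, 8), (2.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="under-resolved"):
            fcm_volume_fraction(self._single(cfg), g, cfg)


class TestThrombusVF:
    def test_zero_field_zero_vf(self):
        cfg = FCMConfig()
        vf = thrombus_VF(np.zeros((4, 4)), 1.0, 0.0, cfg)
        assert np.all(vf == 0.0)

    def test_fibrin_scaling_at_unit_concentration(self):
        cfg = FCMConfig()
        psi = np.full((3, 3), 2.0)
        vf = thrombus_VF(psi, 1.0, 0.0, cfg)
        assert np.allclose(vf, (1.0 / (1400 * 0.13)) * 2.0)

    def test_monotone_in_psi_fcm(self):
        cfg = FCMConfig()
        lo = thrombus_VF(np.full((2, 2), 1.0), 2.0, 0.0, cfg)
        hi = thrombus_VF(np.full((2, 2), 3.0), 2.0, 0.0, cfg)
        assert np.all(hi > lo)


class TestHandoff:
    def test_zero_vf_gives_pure_blood(self):
        g = Grid((24, 24), (1.0, 1.0))
        phi0 = handoff_to_phasefield(np.zeros(g.shape), g, h=0.05)
        assert np.allclose(phi0, 1.0)

    def test_block_mean_conserved_by_smoothing(self):
        g = Grid((64, 64), (2.0, 2.0))
        x, y = g.meshgrid()
        vf = np.where((np.abs(x - 1.0) < 0.4) & (np.abs(y - 1.0) < 0.4),
                      0.66, 0.0)
        phi0 = handoff_to_phasefield(vf, g, h=0.06)
        assert integrate(1.0 - phi0, g) == pytest.approx(
            integrate(vf, g), rel=0.01)

    def test_maximum_principle(self):
        g = Grid((32, 32), (1.0, 1.0))
        rngv = np.random.default_rng(0).random(g.shape)
        phi0 = handoff_to_phasefield(rngv, g, h=0.08)
        assert phi0.min() >= 0.0 and phi0.max() <= 1.0


class TestAggregation:
    def test_aggregates_localize_at_deposition_sites(self):
        from clotflow.materials import MaterialParams
        from clotflow.scenarios import make_aneurysm
        g = Grid((48, 16, 16), (6.0, 1.0, 1.0))
        _, sites = make_aneurysm(g, MaterialParams())
        cfg = FCMConfig(r_p=0.001)
        out = simulate_aggregation(sites, cfg, (6.0, 1.0, 1.0),
                                   sites[0].lumen[2], n_platelets=250,
                                   cycles=4, steps_per_cycle=40, seed=1)
        stats_ = out["stats"]
        assert stats_["stationary"] > 10
        assert stats_["stationary_near_sites"] >= 0.8

    def test_deterministic_given_seed(self):
        site = make_site()
        cfg = FCMConfig(r_p=0.001)
        outs = []
        for _ in range(2):
            out = simulate_aggregation([site], cfg, (6.0, 1.0, 1.0),
                                       site.lumen[2], n_platelets=60,
                                       cycles=2, steps_per_cycle=20, seed=9)
            outs.append(out["ensemble"].x)
        assert np.array_equal(outs[0], outs[1])
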