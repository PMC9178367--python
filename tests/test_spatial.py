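"""Spatial GLV dynamics: Laplacian dispersal, equilibria, coherence, richness."""

import numpy as np
import pytest

from metaglv import (
    CommunityParams,
    CorrelationSpec,
    HabitatEnsemble,
    SpatialEquilibrium,
    build_landscape,
    chain1d,
    coherence_spread,
    dispersal_term,
    global_richness,
    glv_rhs,
    grid2d,
    integrate_adaptive_coherent,
    integrate_to_equilibrium,
    sample_ensemble,
    sample_interaction_matrix,
)


def single_patch():
    return build_landscape(np.zeros((1, 1), dtype=bool), [0])


def zero_ensemble(params, G=1):
    m = sample_interaction_matrix(
        CommunityParams(N=params.N, c=params.c, mu=0.0, sigma=0.0), seed=0)
    return HabitatEnsemble([m] * G, CorrelationSpec("independent"), params)


class TestLandscape:
    def test_grid_neighbor_structure(self):
        land = build_landscape(grid2d(3, 3), np.arange(9))
        assert land.n_patches == 9
        assert land.degrees[4] == 4  # interior patch
        assert land.degrees[0] == 2  # corner

    def test_chain_neighbor_structure(self):
        land = build_landscape(chain1d(5), np.zeros(5, dtype=int))
        assert list(land.degrees) == [1, 2, 2, 2, 1]

    def test_single_patch_has_no_dispersal(self):
        land = single_patch()
        assert land.degrees[0] == 0
        out = dispersal_term(np.array([[0.7, 0.2]]), land, np.array([1.0, 5.0]))
        np.testing.assert_array_equal(out, 0.0)

    def test_rejects_disconnected_or_invalid(self):
        disconnected = np.zeros((3, 3), dtype=bool)
        disconnected[0, 1] = disconnected[1, 0] = True
        with pytest.raises(ValueError):
            build_landscape(disconnected, [0, 0, 0])
        with pytest.raises(ValueError):
            build_landscape(grid2d(2, 2), [0, 0, 0])  # wrong assignment length


class TestDispersalTerm:
    def test_constant_field_gives_zero(self):
        land = build_landscape(grid2d(3, 3), np.arange(9))
        densities = np.full((9, 4), 0.37)
        out = dispersal_term(densities, land, np.ones(4))
        np.testing.assert_allclose(out, 0.0, atol=1e-14)

    def test_interior_spike_stencil(self):
        land = build_landscape(grid2d(3, 3), np.arange(9))
        densities = np.zeros((9, 1))
        densities[4, 0] = 2.0  # center of the 3x3 grid
        out = dispersal_term(densities, land, np.ones(1))[:, 0]
        assert out[4] == pytest.approx(-8.0)  # -4v
        for q in (1, 3, 5, 7):
            assert out[q] == pytest.approx(2.0)  # +v at each neighbor
        for q in (0, 2, 6, 8):
            assert out[q] == 0.0

    @pytest.mark.parametrize("adj", [grid2d(3, 4), chain1d(7), grid2d(1, 1)])
    def test_zero_flux_conserves_mass(self, adj):
        P = adj.shape[0]
        rng = np.random.default_rng(0)
        land = build_landscape(adj, np.zeros(P, dtype=int))
        densities = rng.uniform(0, 2, (P, 5))
        out = dispersal_term(densities, land, rng.uniform(0, 3, 5))
        np.testing.assert_allclose(out.sum(axis=0), 0.0, atol=1e-12)

    def test_negative_dispersal_rejected(self):
        land = single_patch()
        with pytest.raises(ValueError):
            dispersal_term(np.ones((1, 2)), land, np.array([-1.0, 1.0]))


class TestGlvRhs:
    def test_logistic_fixed_point(self):
        params = CommunityParams(N=1)
        out = glv_rhs(np.array([[1.0]]), single_patch(), zero_ensemble(params), params)
        np.testing.assert_allclose(out, 0.0, atol=1e-14)

    def test_extinction_is_absorbing(self):
        params = CommunityParams(N=1)
        out = glv_rhs(np.array([[0.0]]), single_patch(), zero_ensemble(params), params)
        np.testing.assert_array_equal(out, 0.0)

    def test_identical_patches_match_nonspatial_dynamics(self):
        params = CommunityParams(N=6, sigma=0.2)
        ens1 = sample_ensemble(1, CorrelationSpec("independent"), params, seed=3)
        two = build_landscape(chain1d(2), [0, 0])
        phi = np.random.default_rng(1).uniform(0.2, 1.0, 6)
        densities = np.vstack([phi, phi])
        out = glv_rhs(densities, two, ens1, params)
        single = glv_rhs(phi[None, :], single_patch(), ens1, params)
        np.testing.assert_allclose(out[0], single[0], atol=1e-13)
        np.testing.assert_allclose(out[1], single[0], atol=1e-13)


class TestIntegrateToEquilibrium:
    def test_logistic_reaches_carrying_capacity_on_two_patches(self):
        params = CommunityParams(N=1, D=3.0)
        land = build_landscape(chain1d(2), [0, 0])
        eq = integrate_to_equilibrium(land, zero_ensemble(params), params, seed=0)
        assert eq.converged
        np.testing.assert_allclose(eq.densities, 1.0, rtol=1e-6)

    def test_symmetric_competition_fixed_point(self):
        # 1 - phi - 0.5 phi = 0  =>  phi* = 2/3 for both species
        params = CommunityParams(N=2, mu=-0.5, sigma=0.0)
        ens = sample_ensemble(1, CorrelationSpec("independent"), params, seed=0)
        eq = integrate_to_equilibrium(single_patch(), ens, params, seed=1)
        assert eq.converged
        np.testing.assert_allclose(eq.densities, 2.0 / 3.0, rtol=1e-6)

    def test_identical_habitats_reduce_to_single_patch(self, params_small):
        ens = sample_ensemble(1, CorrelationSpec("independent"), params_small, seed=10)
        shared = HabitatEnsemble(ens.matrices * 4, CorrelationSpec("independent"),
                                 params_small)
        land = build_landscape(grid2d(2, 2), np.arange(4))
        eq_single = integrate_to_equilibrium(single_patch(), ens, params_small, seed=2)
        eq_spatial = integrate_to_equilibrium(land, shared, params_small, seed=2)
        assert eq_single.converged and eq_spatial.converged
        extant = eq_single.densities[0] > params_small.extinction_threshold
        for p in range(4):
            np.testing.assert_allclose(eq_spatial.densities[p, extant],
                                       eq_single.densities[0, extant], rtol=1e-6)
        assert eq_spatial.max_coherence_spread < 1e-6

    def test_nonnegative_and_deterministic(self, params_small):
        ens = sample_ensemble(4, CorrelationSpec("independent"), params_small, seed=11)
        land = build_landscape(grid2d(2, 2), np.arange(4))
        eq1 = integrate_to_equilibrium(land, ens, params_small, seed=5)
        eq2 = integrate_to_equilibrium(land, ens, params_small, seed=5)
        assert np.all(eq1.densities >= 0)
        np.testing.assert_array_equal(eq1.densities, eq2.densities)

    def test_rejects_nonpositive_initial(self, params_small):
        ens = sample_ensemble(1, CorrelationSpec("independent"), params_small, seed=0)
        with pytest.raises(ValueError):
            integrate_to_equilibrium(single_patch(), ens, params_small,
                                     initial=np.zeros((1, params_small.N)))


class TestCoherence:
    def test_spread_zero_for_identical_field(self):
        eq = SpatialEquilibrium(
            densities=np.full((4, 3), 0.5), converged=True, residual=0.0,
            t_final=1.0, coherence_spread=np.zeros(3))
        vec, mx = coherence_spread(eq)
        assert mx == 0.0 and np.all(vec == 0.0)

    def test_spread_shrinks_with_dispersal(self, params_small):
        ens = sample_ensemble(9, CorrelationSpec("independent"), params_small, seed=13)
        land = build_landscape(grid2d(3, 3), np.arange(9))
        initial = np.random.default_rng(3).uniform(0.1, 1.0, (9, params_small.N))
        spreads = []
        for D in (1.0, 100.0):
            eq = integrate_to_equilibrium(land, ens, params_small.with_dispersal(D),
                                          initial=initial, on_divergence="flag")
            spreads.append(eq.max_coherence_spread)
        assert spreads[1] < spreads[0]

    def test_adaptive_policy_reaches_coherence(self, params_small):
        ens = sample_ensemble(4, CorrelationSpec("independent"), params_small, seed=14)
        land = build_landscape(grid2d(2, 2), np.arange(4))
        eq, D_used = integrate_adaptive_coherent(land, ens, params_small, seed=4)
        assert eq.converged
        assert eq.max_coherence_spread < 1e-3
        assert D_used >= 1.0


class TestGlobalRichness:
    def _eq(self, means):
        d = np.asarray(means, dtype=float)[None, :]
        return SpatialEquilibrium(densities=d, converged=True, residual=0.0,
                                  t_final=1.0, coherence_spread=np.zeros(d.shape[1]))

    def test_threshold_definition(self):
        params = CommunityParams(N=3)
        n, rel = global_richness(self._eq([0.5, 2e-5, 1e-6]), params)
        assert n == 2 and rel == pytest.approx(2 / 3)

    def test_all_extinct(self):
        params = CommunityParams(N=4)
        n, rel = global_richness(self._eq([0, 0, 0, 0]), params)
        assert n == 0 and rel == 0.0

    def test_exactly_at_threshold_is_extant(self):
        params = CommunityParams(N=1)
        n, _ = global_richness(self._eq([1e-5]), params)
        assert n == 1
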