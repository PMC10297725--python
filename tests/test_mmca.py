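"""MMCA factors, update step, fixed-point iteration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mediaplex import (
    DynamicsParams,
    MMCAState,
    aware_density,
    compute_factors,
    infected_density,
    iterate_to_stationary,
    media_mask,
    mmca_step,
)
from conftest import make_multiplex
from oracles import factors_elementwise, sis_mmca_stationary, tree_step_node


def random_state(n, rng):
    raw = rng.random((n, 4))
    raw /= raw.sum(axis=1, keepdims=True)
    return MMCAState(p_us=raw[:, 0], p_ui=raw[:, 1], p_as=raw[:, 2], p_ai=raw[:, 3])


class TestComputeFactors:
    def test_isolated_untargeted_node(self):
        net = make_multiplex(3, [(1, 2)], [(1, 2)])  # node 0 isolated in both layers
        params = DynamicsParams(beta_u=0.3, delta=0.6)
        mask = media_mask(net, 0.0, 0.5)
        state = random_state(3, np.random.default_rng(0))
        f = compute_factors(state, params, net, mask)
        assert f.r[0] == 1.0 and f.q_u[0] == 1.0 and f.q_a[0] == 1.0
        assert f.f_uu[0] == 1.0
        assert f.f_aa[0] == pytest.approx(1.0 - params.delta)

    def test_single_aware_neighbor(self):
        net = make_multiplex(2, [(0, 1)], [(0, 1)])
        params = DynamicsParams(beta_u=0.0, lambda_=0.15)
        mask = media_mask(net, 0.0, 0.0)
        state = MMCAState(
            p_us=np.array([1.0, 0.0]), p_ui=np.zeros(2),
            p_as=np.array([0.0, 1.0]), p_ai=np.zeros(2),
        )
        f = compute_factors(state, params, net, mask)
        assert f.r[0] == pytest.approx(0.85, abs=1e-15)

    def test_matches_elementwise_oracle(self, small_multiplex):
        rng = np.random.default_rng(5)
        state = random_state(small_multiplex.n_nodes, rng)
        params = DynamicsParams(beta_u=0.37, gamma=0.4, lambda_=0.15, delta=0.6, m=0.7)
        mask = media_mask(small_multiplex, 0.4, params.m)
        f = compute_factors(state, params, small_multiplex, mask)
        r, q_u, q_a, f_uu, f_ua, f_au, f_aa = factors_elementwise(
            state.p_a, state.p_i, params.lambda_, params.beta_u, params.beta_a,
            params.delta, mask.m_i,
            small_multiplex.info_layer.edges, small_multiplex.epi_layer.edges,
        )
        for got, want in [(f.r, r), (f.q_u, q_u), (f.q_a, q_a),
                          (f.f_uu, f_uu), (f.f_ua, f_ua), (f.f_au, f_au), (f.f_aa, f_aa)]:
            np.testing.assert_allclose(got, want, atol=1e-12, rtol=0)

    def test_factor_complementarity(self, small_multiplex):
        state = random_state(small_multiplex.n_nodes, np.random.default_rng(1))
        params = DynamicsParams(beta_u=0.5, m=0.3)
        mask = media_mask(small_multiplex, 0.6, params.m)
        f = compute_factors(state, params, small_multiplex, mask)
        np.testing.assert_allclose(f.f_uu + f.f_ua, 1.0, atol=1e-12)
        np.testing.assert_allclose(f.f_au + f.f_aa, 1.0, atol=1e-12)
        for arr in (f.r, f.q_u, f.q_a, f.f_uu, f.f_ua, f.f_au, f.f_aa):
            assert np.all((arr >= 0) & (arr <= 1))


class TestMMCAStep:
    def test_isolated_infected_node_recovers_at_rate_mu(self):
        net = make_multiplex(1, [], [])
        params = DynamicsParams(beta_u=0.2, mu=0.5, kappa=0.0)
        mask = media_mask(net, 0.0, 0.5)
        state = MMCAState(
            p_us=np.zeros(1), p_ui=np.ones(1), p_as=np.zeros(1), p_ai=np.zeros(1)
        )
        new = mmca_step(state, compute_factors(state, params, net, mask), params)
        assert new.p_us[0] == pytest.approx(0.5)
        assert new.p_ui[0] == pytest.approx(0.5)
        assert new.p_as[0] == 0.0 and new.p_ai[0] == 0.0

    @pytest.mark.parametrize("kappa", [0.0, 0.3])
    def test_matches_transition_tree_oracle(self, four_node_net, kappa):
        rng = np.random.default_rng(17)
        state = random_state(4, rng)
        params = DynamicsParams(
            beta_u=0.45, gamma=0.3, mu=0.4, lambda_=0.2, delta=0.55, m=0.6, kappa=kappa
        )
        mask = media_mask(four_node_net, 0.5, params.m)
        f = compute_factors(state, params, four_node_net, mask)
        new = mmca_step(state, f, params)
        for i in range(4):
            p4 = (state.p_us[i], state.p_ui[i], state.p_as[i], state.p_ai[i])
            want = tree_step_node(
                p4, f.r[i], f.q_u[i], f.q_a[i], mask.m_i[i],
                params.delta, params.mu, params.kappa,
            )
            got = np.array([new.p_us[i], new.p_ui[i], new.p_as[i], new.p_ai[i]])
            np.testing.assert_allclose(got, want, atol=1e-12, rtol=0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_probability_conservation_is_algebraic(self, seed):
        rng = np.random.default_rng(seed)
        net = make_multiplex(
            6,
            [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5)],
            [(0, 2), (1, 3), (2, 4), (3, 5)],
        )
        params = DynamicsParams(
            beta_u=rng.random(), gamma=rng.random(), mu=rng.random(),
            lambda_=rng.random(), delta=rng.random(), m=rng.random(),
            kappa=rng.random(),
        )
        mask = media_mask(net, rng.random(), params.m)
        state = random_state(6, rng)
        new = mmca_step(state, compute_factors(state, params, net, mask), params)
        assert new.conservation_error() < 1e-12


class TestIterateToStationary:
    def test_no_infection_dies_out(self, small_multiplex):
        params = DynamicsParams(beta_u=0.0, mu=0.5, eta=0.3)
        mask = media_mask(small_multiplex, params.eta, params.m)
        res = iterate_to_stationary(
            MMCAState.homogeneous(small_multiplex.n_nodes, 0.2),
            params, small_multiplex, mask,
        )
        assert res.converged
        assert res.rho_i == pytest.approx(0.0, abs=1e-8)

    def test_no_recovery_absorbs_full_infection(self):
        net = make_multiplex(4, [(0, 1)], [(0, 1), (1, 2), (2, 3), (0, 3)])
        params = DynamicsParams(beta_u=0.8, mu=0.0)
        mask = media_mask(net, 0.0, 0.5)
        res = iterate_to_stationary(MMCAState.homogeneous(4, 0.2), params, net, mask)
        assert res.rho_i == pytest.approx(1.0, abs=1e-6)

    def test_nonconvergence_is_flagged_not_raised(self, small_multiplex, reference_params):
        mask = media_mask(small_multiplex, 0.0, 0.5)
        res = iterate_to_stationary(
            MMCAState.homogeneous(small_multiplex.n_nodes, 0.2),
            reference_params, small_multiplex, mask, max_iter=3,
        )
        assert not res.converged
        assert res.residual > 1e-9

    def test_fixed_point_independent_of_initialization(self, small_multiplex, reference_params):
        mask = media_mask(small_multiplex, 0.5, 0.5)
        p = reference_params.replace(eta=0.5)
        res_a = iterate_to_stationary(
            MMCAState.homogeneous(small_multiplex.n_nodes, 0.2), p, small_multiplex, mask
        )
        res_b = iterate_to_stationary(
            MMCAState.homogeneous(small_multiplex.n_nodes, 0.9), p, small_multiplex, mask
        )
        assert abs(res_a.rho_i - res_b.rho_i) < 1e-6

    def test_monotone_in_beta_and_eta(self, small_multiplex):
        mask_cache = {}
        rho = {}
        for eta in (0.0, 0.5, 1.0):
            mask_cache[eta] = media_mask(small_multiplex, eta, 0.5)
            for beta in (0.2, 0.5, 0.8):
                p = DynamicsParams(beta_u=beta, gamma=0.0, eta=eta)
                rho[(eta, beta)] = iterate_to_stationary(
                    MMCAState.homogeneous(small_multiplex.n_nodes, 0.2),
                    p, small_multiplex, mask_cache[eta],
                ).rho_i
        for eta in (0.0, 0.5, 1.0):
            assert rho[(eta, 0.2)] <= rho[(eta, 0.5)] + 1e-9 <= rho[(eta, 0.8)] + 2e-9
        for beta in (0.2, 0.5, 0.8):
            assert rho[(0.0, beta)] + 1e-9 >= rho[(0.5, beta)] >= rho[(1.0, beta)] - 1e-9

    def test_no_media_means_no_awareness(self, small_multiplex, reference_params):
        mask = media_mask(small_multiplex, 0.0, 0.5)
        state = MMCAState.homogeneous(small_multiplex.n_nodes, 0.2)
        for _ in range(50):
            f = compute_factors(state, reference_params, small_multiplex, mask)
            state = mmca_step(state, f, reference_params)
            assert np.all(state.p_a == 0.0)

    def test_decoupled_limit_matches_single_layer_sis(self):
        net = make_multiplex(
            8,
            [(i, (i + 1) % 8) for i in range(8)],
            [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7), (0, 4), (2, 6)],
        )
        params = DynamicsParams(beta_u=0.5, gamma=1.0, mu=0.4, kappa=0.0, eta=0.5)
        mask = media_mask(net, params.eta, params.m)
        res = iterate_to_stationary(
            MMCAState.homogeneous(8, 0.2), params, net, mask, tol=1e-13
        )
        oracle = sis_mmca_stationary(8, net.epi_layer.edges, 0.5, 0.4, rho0=0.2)
        np.testing.assert_allclose(res.state.p_i, oracle, atol=1e-10, rtol=0)


class TestDensities:
    def test_density_examples_and_conservation_identity(self):
        n = 10
        state = MMCAState(
            p_us=np.r_[np.ones(5), np.zeros(5)],
            p_ui=np.zeros(n),
            p_as=np.zeros(n),
            p_ai=np.r_[np.zeros(5), np.ones(5)],
        )
        assert infected_density(state) == pytest.approx(0.5)
        assert aware_density(state) == pytest.approx(0.5)
        rng = np.random.default_rng(3)
        state = random_state(n, rng)
        alt = 1.0 - float((state.p_us + state.p_as).mean())
        assert infected_density(state) == pytest.approx(alt, abs=1e-12)
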