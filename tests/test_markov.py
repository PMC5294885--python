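"""Transition matrix, stationary distribution, spectrum, quasipotential."""

import numpy as np
import pytest

import grnmsm as g
from grnmsm.markov import ReducibleChainError, count_local_minima
from conftest import make_birth_death


class TestTransitionMatrix:
    def test_two_state_flip_closed_form(self, flip):
        """T_12(tau) = h/(h+f) (1 - exp(-(h+f) tau)) for the promoter flip."""
        h, f = flip["h"], flip["f"]
        for tau in (0.1, 1.0, 5.0):
            T = g.transition_matrix(flip["gen"], tau).dense()
            expected = h / (h + f) * (1.0 - np.exp(-(h + f) * tau))
            assert T[0, 1] == pytest.approx(expected, abs=1e-12)
            assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_short_lagtime_approaches_identity(self, flip):
        tau = 1e-6
        T = g.transition_matrix(flip["gen"], tau).dense()
        scale = np.abs(flip["gen"].Q.diagonal()).max()
        assert np.abs(T - np.eye(2)).max() < tau * scale

    def test_rows_stochastic_on_motif(self):
        net = g.build_motif("self_regulating", g.self_regulating_preset())
        gen = g.build_generator(g.enumerate_states(net, 20))
        T = g.transition_matrix(gen, 5.0).dense()
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-9)
        assert T.min() >= 0.0

    def test_nonpositive_lagtime_rejected(self, flip):
        with pytest.raises(ValueError, match="tau"):
            g.transition_matrix(flip["gen"], 0.0)

    def test_exponential_action_matches_dense(self):
        """The matrix-free route must agree with dense exponentiation."""
        net = g.build_motif("self_regulating", g.self_regulating_preset())
        gen = g.build_generator(g.enumerate_states(net, 15))
        T_dense = g.transition_matrix(gen, 3.0)
        T_op = g.transition_matrix(gen, 3.0, dense_cutoff=1)
        rng = np.random.default_rng(1)
        v = rng.random(gen.size)
        assert np.allclose(T_dense.dot(v), T_op.dot(v), atol=1e-10)
        assert np.allclose(T_dense.propagate_dist(v), T_op.propagate_dist(v),
                           atol=1e-10)


class TestPropagate:
    def test_zero_steps_returns_p0(self, flip):
        T = g.transition_matrix(flip["gen"], 1.0)
        p0 = np.array([1.0, 0.0])
        out = g.propagate(p0, T, 0)
        assert np.array_equal(out, p0[None, :])

    def test_stationary_start_stays_constant(self, flip):
        T = g.transition_matrix(flip["gen"], 1.0)
        pi = g.stationary(flip["gen"]).pi
        traj = g.propagate(pi, T, 5)
        assert np.abs(traj - pi[None, :]).max() < 1e-8

    def test_two_state_relaxation_closed_form(self, flip):
        h, f = flip["h"], flip["f"]
        tau, K = 0.5, 10
        T = g.transition_matrix(flip["gen"], tau)
        traj = g.propagate(np.array([1.0, 0.0]), T, K)
        pi0 = f / (h + f)
        ks = np.arange(K + 1)
        expected = pi0 + (1 - pi0) * np.exp(-(h + f) * ks * tau)
        assert np.allclose(traj[:, 0], expected, atol=1e-12)
        assert np.allclose(traj.sum(axis=1), 1.0, atol=1e-9)


class TestStationary:
    def test_two_state_detailed_balance(self, flip):
        h, f = flip["h"], flip["f"]
        pi = g.stationary(flip["gen"]).pi
        assert np.allclose(pi, [f / (h + f), h / (h + f)], atol=1e-12)

    def test_generator_and_lagtime_routes_agree(self):
        net = g.build_motif("self_regulating", g.self_regulating_preset())
        gen = g.build_generator(g.enumerate_states(net, 18))
        pi_gen = g.stationary(gen).pi
        T = g.transition_matrix(gen, 2.0)
        pi_lag = g.stationary(T).pi
        assert 0.5 * np.abs(pi_gen - pi_lag).sum() < 1e-8
        # left fixed point of T
        assert np.abs(T.propagate_dist(pi_gen) - pi_gen).max() < 1e-10

    def test_reducible_chain_raises(self):
        net = make_birth_death(0.0, 1.0)  # pure death: state 0 absorbing
        gen = g.build_generator(g.enumerate_states(net, 4))
        with pytest.raises(ReducibleChainError, match="reducible"):
            g.stationary(gen)

    def test_misa_symmetry_under_label_swap(self):
        """Symmetric rates: pi is invariant under the A<->B permutation."""
        net = g.build_motif("misa", g.misa_preset(g1=6.0, g0=1.0))
        space = g.enumerate_states(net, 8)
        gen = g.build_generator(space)
        pi = g.stationary(gen).pi
        perm = np.array([
            space.index_of((s[1], s[0], s[3], s[2]))
            for s in map(space.state_of, range(space.size))
        ])
        assert 0.5 * np.abs(pi - pi[perm]).sum() < 1e-8


class TestSpectrum:
    def test_perron_eigenvalue_is_one(self, flip):
        T = g.transition_matrix(flip["gen"], 1.0)
        spec = g.spectrum(T, 2)
        assert abs(spec.eigenvalues[0] - 1.0) < 1e-8
        assert np.all(np.abs(spec.eigenvalues) <= 1.0 + 1e-10)

    def test_two_state_timescale_lag_independent(self, flip):
        """t_2 = 1/(h+f) for the flip, at any lagtime."""
        h, f = flip["h"], flip["f"]
        for tau in (0.5, 2.0):
            spec = g.spectrum(g.transition_matrix(flip["gen"], tau), 2)
            assert spec.timescales[1] == pytest.approx(1.0 / (h + f), rel=1e-10)
        assert np.isinf(spec.timescales[0])

    def test_operator_route_matches_dense_route(self):
        net = g.build_motif("self_regulating", g.self_regulating_preset())
        gen = g.build_generator(g.enumerate_states(net, 20))
        lam_dense = g.spectrum(g.transition_matrix(gen, 2.0), 4).eigenvalues
        T_op = g.transition_matrix(gen, 2.0, dense_cutoff=1)
        lam_op = g.spectrum(T_op, 4).eigenvalues
        assert np.allclose(np.abs(lam_dense), np.abs(lam_op), atol=1e-7)

    def test_timescales_lag_consistent_for_exact_model(self):
        """Implied timescales of the exact chain agree at tau and 2 tau."""
        net = g.build_motif("self_regulating", g.self_regulating_preset())
        gen = g.build_generator(g.enumerate_states(net, 15))
        t1 = g.spectrum(g.transition_matrix(gen, 1.0), 4).timescales[1:]
        t2 = g.spectrum(g.transition_matrix(gen, 2.0), 4).timescales[1:]
        assert np.allclose(t1, t2, rtol=0.01)

    def test_left_vector_sign_convention(self, flip):
        spec = g.spectrum(g.transition_matrix(flip["gen"], 1.0), 2,
                          compute_left=True)
        for j in range(2):
            w = spec.left_vectors[:, j]
            assert w[np.argmax(np.abs(w))] > 0


class TestQuasipotential:
    def test_uniform_distribution_flat_landscape(self):
        pi = np.full(8, 1 / 8)
        surf = g.quasipotential(pi)
        assert np.allclose(surf.U, np.log(8))

    def test_zero_probability_maps_to_inf(self):
        surf = g.quasipotential(np.array([0.5, 0.5, 0.0]))
        assert np.isinf(surf.U[2])
        assert surf.argmin in (0, 1)

    def test_projection_minimum_at_marginal_mode(self):
        net = g.build_motif("self_regulating", g.self_regulating_preset())
        space = g.enumerate_states(net, 20)
        pi = g.stationary(g.build_generator(space))
        surf = g.quasipotential(pi, space)
        assert surf.U_proj is not None
        assert np.argmin(surf.U_proj) == np.argmax(surf.pi_proj)
        assert surf.pi_proj.sum() == pytest.approx(1.0)

    def test_local_minimum_counter(self):
        grid = np.full((5, 5), 3.0)
        grid[1, 1] = 0.5
        grid[3, 3] = 0.2
        assert count_local_minima(grid) == 2
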