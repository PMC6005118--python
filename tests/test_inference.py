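"""Belief updating, free energy, and the expected-free-energy decomposition."""

import itertools

import numpy as np
import pytest

from neglectsim import (
    RunConfig,
    bma_states,
    build_flat_model,
    expected_free_energy,
    free_energy,
    generate_display,
    policy_posterior,
    select_action,
    update_state_beliefs,
)
from neglectsim.inference import _salience_value, _unit_update_kl_table
from neglectsim.mdp_core import Modality, random_toy_model


def enumerate_posterior(model, obs, acts):
    """Brute-force smoothing posterior by summing over all state sequences."""
    A = model.modalities[0].A
    S = model.factor_dims[0]
    T = len(obs)
    post = np.zeros((T, S))
    Z = 0.0
    for seq in itertools.product(range(S), repeat=T):
        p = model.D[0][seq[0]] * A[obs[0]["obs"], seq[0]]
        for t in range(1, T):
            p *= model.transitions.B(0, acts[t - 1])[seq[t], seq[t - 1]]
            p *= A[obs[t]["obs"], seq[t]]
        Z += p
        for t in range(T):
            post[t, seq[t]] += p
    return post / Z, Z


class TestStateBeliefs:
    def test_matches_enumeration_on_random_models(self, rng):
        for _ in range(50):
            m = random_toy_model(rng, n_states=int(rng.integers(2, 7)),
                                 n_outcomes=3, n_actions=2)
            T = int(rng.integers(1, 4))
            obs = [{"obs": int(rng.integers(3))} for _ in range(T)]
            acts = [int(rng.integers(2)) for _ in range(T - 1)]
            qs = update_state_beliefs(m, obs, acts)
            post, _ = enumerate_posterior(m, obs, acts)
            np.testing.assert_allclose(qs[0], post, atol=1e-6)

    def test_identity_likelihood_resolves_state_exactly(self, flat_model):
        flat_model.D[0][:] = 1.0 / 64  # uninformative prior over locations
        qs = update_state_beliefs(flat_model, [{"proprioception": 42}], [])
        expected = np.zeros(64)
        expected[42] = 1.0
        np.testing.assert_allclose(qs[0][0], expected, atol=1e-12)

    def test_no_observation_keeps_uniform_prior(self, rng):
        m = random_toy_model(rng, n_states=4)
        m.D[0] = np.full(4, 0.25)
        qs = update_state_beliefs(m, [{}], [])
        np.testing.assert_allclose(qs[0][0], 0.25, atol=1e-12)

    def test_posteriors_normalized(self, rng):
        m = random_toy_model(rng, n_states=5)
        obs = [{"obs": 0}, {"obs": 2}, {"obs": 1}]
        qs = update_state_beliefs(m, obs, [0, 1])
        np.testing.assert_allclose(qs[0].sum(axis=1), 1.0, atol=1e-10)


class TestFreeEnergy:
    def test_bounds_surprise_with_equality_at_exact_posterior(self, rng):
        for _ in range(100):
            m = random_toy_model(rng, n_states=int(rng.integers(2, 6)))
            T = int(rng.integers(1, 4))
            obs = [{"obs": int(rng.integers(3))} for _ in range(T)]
            acts = [int(rng.integers(2)) for _ in range(T - 1)]
            qs = update_state_beliefs(m, obs, acts)
            post, Z = enumerate_posterior(m, obs, acts)
            F = free_energy(m, qs, obs, acts)
            assert F >= -np.log(Z) - 1e-9
            if T == 1:  # posterior factorizes: bound is tight
                assert F == pytest.approx(-np.log(Z), abs=1e-10)

    def test_bound_holds_for_arbitrary_normalized_beliefs(self, rng):
        m = random_toy_model(rng, n_states=4)
        obs = [{"obs": 1}, {"obs": 0}]
        acts = [0]
        _, Z = enumerate_posterior(m, obs, acts)
        for _ in range(20):
            q = rng.dirichlet(np.ones(4), size=2)
            assert free_energy(m, [q], obs, acts) >= -np.log(Z) - 1e-9

    def test_decreases_over_update_sweeps(self, rng):
        for _ in range(10):
            m = random_toy_model(rng, n_states=5)
            obs = [{"obs": int(rng.integers(3))} for _ in range(3)]
            acts = [int(rng.integers(2)) for _ in range(2)]
            _, history = update_state_beliefs(m, obs, acts, return_history=True)
            diffs = np.diff(history)
            assert (diffs <= 1e-9).all()


class TestEFEDecomposition:
    def test_total_is_cost_minus_salience_minus_novelty(self, flat_model):
        efe = expected_free_energy(flat_model)
        np.testing.assert_allclose(
            efe.G, efe.cost - efe.salience - efe.novelty, atol=1e-10)
        assert (efe.novelty >= 0).all()
        assert (efe.salience >= -1e-12).all()

    def test_uniform_preferences_give_policy_constant_cost(self, cfg):
        m = build_flat_model(generate_display(8, "balanced", 0).targets, cfg)
        m.modality("visual").C = np.zeros(3)
        cost = expected_free_energy(m).cost
        assert cost.max() - cost.min() < 1e-10

    def test_cost_orders_believed_outcomes_by_preference(self, flat_model):
        # confident beliefs: white at 0, black at 1, red at 2
        vis = flat_model.modality("visual")
        vis.counts = vis.counts.copy()
        for j, outcome in [(0, 0), (1, 1), (2, 2)]:
            vis.counts[:, j] = 1e-4
            vis.counts[outcome, j] = 100.0
        cost = expected_free_energy(flat_model).cost
        assert cost[1] < cost[0] < cost[2]  # black < white < red

    def test_uncanceled_target_cheaper_than_empty_cell(self, flat_model, display):
        cost = expected_free_energy(flat_model).cost
        target_idx = sorted(t.index for t in display.targets)
        empty_idx = sorted(set(range(64)) - set(target_idx))
        assert cost[target_idx].max() < cost[empty_idx].min()

    def test_salience_policy_constant_in_flat_model(self, flat_model):
        sal = expected_free_energy(flat_model).salience
        assert sal.max() - sal.min() < 1e-10

    def test_salience_zero_for_certain_prediction(self, rng):
        m = random_toy_model(rng, n_states=3)
        m.modalities[0].counts = np.eye(3) * 50 + 1e-6  # near-identity A
        x = np.zeros(3)
        x[1] = 1.0
        assert _salience_value(m, [x]) == pytest.approx(0.0, abs=1e-9)

    def test_salience_matches_outcome_enumeration(self, rng):
        # 2-state toy with a noisy likelihood and an uncertain prediction
        A = np.array([[0.7, 0.2], [0.3, 0.8]])
        m = random_toy_model(rng, n_states=2, n_outcomes=2)
        m.modalities = [Modality(name="obs", n_outcomes=2, factors=(0,),
                                 counts=A * 5.0, learnable=True)]
        x = np.array([0.4, 0.6])
        expected = 0.0
        for o in range(2):
            po = A[o] @ x
            post = A[o] * x / po
            expected += po * float(post @ np.log(post / x))
        assert _salience_value(m, [x]) == pytest.approx(expected, abs=1e-10)

    def test_novelty_vanishes_for_saturated_counts(self, flat_model):
        nov0 = expected_free_energy(flat_model).novelty
        vis = flat_model.modality("visual")
        vis.counts = vis.counts * 1e6
        nov1 = expected_free_energy(flat_model).novelty
        assert nov0.min() > 1e-3
        assert nov1.max() < 1e-4

    def test_novelty_strictly_decreases_with_count_inflation(self, flat_model):
        vis = flat_model.modality("visual")
        nov0 = expected_free_energy(flat_model).novelty
        vis.counts = vis.counts.copy()
        vis.counts[:, 10] *= 2.0
        nov1 = expected_free_energy(flat_model).novelty
        assert nov1[10] < nov0[10]
        np.testing.assert_allclose(np.delete(nov1, 10), np.delete(nov0, 10))

    def test_novelty_closed_form_matches_dirichlet_kl_quadrature(self):
        from scipy.integrate import dblquad
        from scipy.special import gammaln

        a = np.array([1.5, 2.0, 3.0])
        i = 1
        ap = a.copy()
        ap[i] += 1.0

        def ln_beta(al):
            return gammaln(al).sum() - gammaln(al.sum())

        def integrand(y, x):
            z = 1.0 - x - y
            if z <= 0:
                return 0.0
            p = np.array([x, y, z])
            lp_post = ((ap - 1) * np.log(p)).sum() - ln_beta(ap)
            lp_pri = ((a - 1) * np.log(p)).sum() - ln_beta(a)
            return np.exp(lp_post) * (lp_post - lp_pri)

        numeric, _ = dblquad(integrand, 0, 1, 0, lambda x: 1 - x, epsabs=1e-10)
        closed = _unit_update_kl_table(a.reshape(3, 1))[i, 0]
        assert closed == pytest.approx(numeric, abs=1e-6)


class TestPolicyPosterior:
    def test_zero_precision_gives_uniform(self):
        q = policy_posterior(np.full(4, 0.25), np.array([1.0, 5.0, -2.0, 0.0]), 0.0)
        np.testing.assert_allclose(q, 0.25)

    def test_prior_ratio_preserved_under_equal_G(self):
        q = policy_posterior(np.array([1.0, 2.0]), np.zeros(2), 1.0)
        np.testing.assert_allclose(q, [1 / 3, 2 / 3])

    def test_softmax_of_negative_G(self):
        q = policy_posterior(np.array([0.5, 0.5]), np.array([1.0, 2.0]), 1.0)
        np.testing.assert_allclose(q, [0.73105857863, 0.26894142137], atol=1e-10)

    def test_nonfinite_G_rejected(self):
        with pytest.raises(ValueError):
            policy_posterior(np.array([0.5, 0.5]), np.array([np.nan, 0.0]), 1.0)


class TestBMAAndActionSelection:
    def test_single_policy_is_identity(self):
        s = np.array([[0.2, 0.8]])
        np.testing.assert_allclose(bma_states(s, np.array([1.0])), s[0])

    def test_mixture_of_deltas(self):
        s = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        np.testing.assert_allclose(bma_states(s, np.array([0.5, 0.5])),
                                   [0.5, 0.0, 0.5])

    def test_weighted_sum_oracle(self, rng):
        s = rng.dirichlet(np.ones(6), size=10)
        w = rng.dirichlet(np.ones(10))
        expected = sum(w[p] * s[p] for p in range(10))
        np.testing.assert_allclose(bma_states(s, w), expected, atol=1e-12)

    def test_delta_posterior_selects_same_action_in_both_modes(self):
        q = np.zeros(8)
        q[5] = 1.0
        assert select_action(q, "argmax") == 5
        assert select_action(q, "sample", seed=0) == 5

    def test_argmax_breaks_ties_toward_lowest_index(self):
        assert select_action(np.array([0.3, 0.3, 0.3, 0.1]), "argmax") == 0

    def test_sampling_is_seed_reproducible(self):
        q = np.array([0.1, 0.2, 0.3, 0.4])
        draws = [select_action(q, "sample", seed=99) for _ in range(5)]
        assert len(set(draws)) == 1

    def test_sampling_frequencies_match_posterior(self):
        q = np.array([0.1, 0.2, 0.3, 0.4])
        rng = np.random.default_rng(5)
        n = 20_000
        draws = [select_action(q, "sample", rng=rng) for _ in range(n)]
        counts = np.bincount(draws, minlength=4) / n
        se = np.sqrt(q * (1 - q) / n)
        assert (np.abs(counts - q) < 3 * se + 1e-9).all()

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            select_action(np.array([1.0]), "greedy")
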