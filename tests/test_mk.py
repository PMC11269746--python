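import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from convloss import synthetic
from convloss.errors import InvalidArgumentError
from convloss.mk import (
    BinaryRates,
    RateMatrixK,
    autocorrelation,
    fit_ml,
    joint_reconstruct,
    marginal_reconstruct,
    mcmc_sample,
    prune_loglik,
)
from oracles import enumerate_binary, random_binary_instance


class TestTransitionMatrices:
    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0), st.floats(0.0, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_rows_sum_to_one(self, q01, q10, t):
        P = BinaryRates(q01, q10).transition(t)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(P >= 0)

    def test_zero_branch_is_identity(self):
        assert np.allclose(BinaryRates(0.7, 0.3).transition(0.0), np.eye(2))
        q = RateMatrixK.from_offdiagonal(np.ones((4, 4)))
        assert np.allclose(q.transition(0.0), np.eye(4))

    def test_kstate_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        q = RateMatrixK.from_offdiagonal(rng.uniform(0, 2, (5, 5)))
        P = q.transition(0.7)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(InvalidArgumentError):
            RateMatrixK(np.array([[-1.0, 1.0], [1.0, -1.0]]) * -1)  # bad off-diagonal
        with pytest.raises(InvalidArgumentError):
            RateMatrixK(np.array([[1.0, 1.0], [1.0, 1.0]]))  # rows not zero


class TestPruneLoglik:
    def test_two_tips_same_state_equal_rates_long_branches(self, two_tip_tree):
        # infinitely long branches decouple tips from the root: lik -> pi1^2
        from convloss.trees import Phylogeny

        t = Phylogeny(["R", "a", "b"], [-1, 0, 0], [0.0, 500.0, 500.0])
        ll = prune_loglik(t, {"a": 1, "b": 1}, BinaryRates(1.0, 1.0))
        assert np.isclose(ll, math.log(0.25), atol=1e-6)

    def test_two_tip_closed_form(self, two_tip_tree):
        r = BinaryRates(0.6, 0.9)
        P = r.transition(0.4)
        pi = r.stationary()
        exact = math.log(pi[0] * P[0, 1] ** 2 + pi[1] * P[1, 1] ** 2)
        assert np.isclose(prune_loglik(two_tip_tree, {"a": 1, "b": 1}, r), exact, atol=1e-12)

    def test_matches_enumeration_on_random_instances(self):
        maxerr = 0.0
        for seed in range(50):
            tree, rates, states = random_binary_instance(seed)
            ll = prune_loglik(tree, states, rates)
            bll, _, _ = enumerate_binary(tree, rates, states, rates.stationary())
            maxerr = max(maxerr, abs(ll - bll))
        assert maxerr < 1e-8

    def test_kstate_engine_agrees_with_binary(self):
        tree, rates, states = random_binary_instance(11)
        qmat = np.array([[-rates.q01, rates.q01], [rates.q10, -rates.q10]])
        ll_bin = prune_loglik(tree, states, rates)
        ll_k = prune_loglik(tree, states, RateMatrixK(qmat), root_prior=rates.stationary())
        assert abs(ll_bin - ll_k) < 1e-10

    def test_missing_tip_state_integrated_out(self):
        tree, rates, states = random_binary_instance(5)
        tip = tree.tip_names[0]
        missing = dict(states)
        missing[tip] = None
        l0 = prune_loglik(tree, {**states, tip: 0}, rates)
        l1 = prune_loglik(tree, {**states, tip: 1}, rates)
        lm = prune_loglik(tree, missing, rates)
        assert np.isclose(np.exp(lm), np.exp(l0) + np.exp(l1), rtol=1e-10)

    def test_unknown_tip_raises_keyerror(self, two_tip_tree):
        with pytest.raises(KeyError):
            prune_loglik(two_tip_tree, {"a": 1}, BinaryRates(1, 1))

    def test_rerooting_invariance_symmetric_model(self):
        # symmetric rates + stationary (flat) prior: likelihood is root-invariant
        from convloss.trees import Phylogeny

        t1 = Phylogeny.from_newick("((a:0.2,b:0.3)x:0.4,c:0.5)r;")
        t2 = Phylogeny.from_newick("((a:0.2,c:0.9)x:0.0,b:0.3)r;")  # same unrooted tree
        r = BinaryRates(0.8, 0.8)
        states = {"a": 1, "b": 0, "c": 1}
        assert np.isclose(
            prune_loglik(t1, states, r), prune_loglik(t2, states, r), atol=1e-10
        )


class TestFitML:
    def test_all_tips_present_loss_rate_at_boundary(self):
        t = synthetic.simulate_tree(16, seed=1)
        fit = fit_ml(t, {n: 1 for n in t.tip_names})
        assert fit.rates.q10 <= 1e-8
        assert not fit.identifiable or fit.boundary

    def test_parameter_recovery_pooled(self):
        t = synthetic.simulate_tree(128, seed=7)
        table, _ = synthetic.simulate_binary_ogs(t, 0.2, 2.0, 1000, seed=8)
        fit = fit_ml(t, table)
        assert abs(fit.rates.q01 - 0.2) / 0.2 < 0.15
        assert abs(fit.rates.q10 - 2.0) / 2.0 < 0.15

    def test_kstate_fit_dominates_truth(self):
        labels = ("a", "b", "c")
        tree = synthetic.simulate_tree(48, seed=5)
        R = np.zeros((3, 3))
        R[0, 1], R[1, 2], R[2, 0] = 1.0, 0.6, 0.8
        truth = RateMatrixK.from_offdiagonal(R, labels)
        _, node_states = synthetic.simulate_repertoire_states(tree, truth, seed=6)
        tips = {n: node_states[n] for n in tree.tip_names}
        frame = pd.DataFrame({"x": pd.Series(tips)})
        fit = fit_ml(tree, frame, k=3, seed=1, n_starts=3)
        ll_truth = float(np.sum(prune_loglik(tree, frame, truth)))
        assert fit.loglik >= ll_truth - 1e-6


class TestMCMC:
    def test_sample_count_and_determinism(self):
        sc = synthetic.simulate_two_clade_tree(seed=1)
        table, _ = synthetic.simulate_binary_ogs(sc.tree, 0.5, 1.0, 3, seed=3)
        a = mcmc_sample(sc.tree, table, n_samples=40, burn_in=100, thin=5, seed=4)
        b = mcmc_sample(sc.tree, table, n_samples=40, burn_in=100, thin=5, seed=4)
        assert len(a) == 40
        assert np.array_equal(a.samples, b.samples)
        c = mcmc_sample(sc.tree, table, n_samples=40, burn_in=100, thin=5, seed=5)
        assert not np.array_equal(a.samples, c.samples)

    def test_default_sample_count_is_500(self):
        # default n_samples/burn_in/thin = 500/500/10
        t = synthetic.simulate_tree(8, seed=2)
        table, _ = synthetic.simulate_binary_ogs(t, 1.0, 1.0, 1, seed=1)
        ps = mcmc_sample(t, table, seed=0)
        assert len(ps) == 500
        assert ps.burn_in == 500 and ps.thin == 10

    def test_posterior_recovers_rates_within_factor_two(self):
        t = synthetic.simulate_tree(64, seed=9)
        ok = 0
        for seed in range(5):
            table, _ = synthetic.simulate_binary_ogs(t, 0.2, 2.0, 30, seed=100 + seed)
            ps = mcmc_sample(t, table, n_samples=100, burn_in=200, thin=5, seed=seed)
            med = ps.median()
            ok += (0.1 <= med.q01 <= 0.4) and (1.0 <= med.q10 <= 4.0)
        assert ok >= 4


class TestAutocorrelation:
    def test_white_noise_is_uncorrelated(self):
        x = np.random.default_rng(1).normal(size=5000)
        acfv = autocorrelation(x, 10)
        assert acfv[0] == 1.0
        assert np.max(np.abs(acfv[1:])) < 0.05

    def test_two_cycle_alternates(self):
        acfv = autocorrelation(np.array([0.0, 1.0] * 50), 2)
        assert np.isclose(acfv[1], -1.0, atol=1e-6)

    def test_constant_chain_rejected(self):
        with pytest.raises(InvalidArgumentError):
            autocorrelation(np.ones(100), 5)


class TestJointReconstruct:
    def test_all_present_small_loss_rate(self):
        t = synthetic.simulate_tree(12, seed=3)
        j = joint_reconstruct(t, {n: 1 for n in t.tip_names}, BinaryRates(0.5, 0.01))
        assert set(j.states.values()) == {1}

    def test_matches_enumeration_maximum(self):
        maxerr = 0.0
        for seed in range(50):
            tree, rates, states = random_binary_instance(seed)
            j = joint_reconstruct(tree, states, rates)
            _, best, _ = enumerate_binary(tree, rates, states, rates.stationary())
            maxerr = max(maxerr, abs(j.log_prob - best))
        assert maxerr < 1e-9

    def test_symmetric_two_tip_tie_flagged(self, two_tip_tree):
        j = joint_reconstruct(two_tip_tree, {"a": 0, "b": 1}, BinaryRates(1.0, 1.0))
        assert j.tie

    def test_joint_prob_never_exceeds_marginal_likelihood(self):
        for seed in range(20):
            tree, rates, states = random_binary_instance(seed)
            j = joint_reconstruct(tree, states, rates)
            ll = prune_loglik(tree, states, rates)
            assert j.log_prob <= ll + 1e-12


class TestMarginalReconstruct:
    def test_invariant_column_high_posterior(self):
        t = synthetic.simulate_tree(10, seed=4)
        mp = marginal_reconstruct(t, {n: 1 for n in t.tip_names}, BinaryRates(0.05, 0.05))
        assert np.all(mp.probs[:, 0, 1] > 0.99)

    def test_matches_enumeration(self):
        maxerr = 0.0
        for seed in range(50):
            tree, rates, states = random_binary_instance(seed)
            mp = marginal_reconstruct(tree, states, rates)
            _, _, bmarg = enumerate_binary(tree, rates, states, rates.stationary())
            maxerr = max(maxerr, np.abs(mp.probs[:, 0, :] - bmarg).max())
        assert maxerr < 1e-8

    def test_posteriors_sum_to_one(self):
        tree, rates, states = random_binary_instance(8)
        mp = marginal_reconstruct(tree, states, rates)
        assert np.allclose(mp.probs.sum(axis=2), 1.0, atol=1e-9)
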