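import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epochmk import (FitSettings, MkError, MkRates, fit_mk, lambda_transform,
                     marginal_asr, phylo_signal_test, pruning_lnL,
                     transition_matrix)
from epochmk.synthetic_data import simulate_trait

import oracles
from conftest import make_tree, random_states, random_tree


class TestTransitionMatrix:
    def test_zero_rates_identity(self):
        P = transition_matrix(MkRates(0.0, 0.0), 5.0)
        assert np.allclose(P, np.eye(2), atol=0)

    def test_symmetric_stationarity(self):
        P = transition_matrix(MkRates(1.0, 1.0), 200.0)
        assert np.allclose(P, 0.25 + 0.25 * np.ones((2, 2)), atol=1e-12)

    def test_closed_form_values(self):
        # q01 = q10 = 1, t = ln 2: e^{-2t} = 1/4
        P = transition_matrix(MkRates(1.0, 1.0), math.log(2))
        assert P[0, 1] == pytest.approx(0.375, abs=1e-15)
        assert P[1, 1] == pytest.approx(0.625, abs=1e-15)

    def test_matches_matrix_exponential(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            q01, q10 = rng.uniform(0, 5, 2)
            t = rng.uniform(0, 10)
            P = transition_matrix(MkRates(q01, q10), t)
            assert np.allclose(P, oracles.pmat_expm(q01, q10, t), atol=1e-10)

    def test_rows_stochastic(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            P = transition_matrix(MkRates(*rng.uniform(0, 10, 2)),
                                  rng.uniform(0, 5))
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert (P >= 0).all() and (P <= 1).all()

    def test_domain_errors(self):
        with pytest.raises(MkError):
            transition_matrix(MkRates(1.0, 1.0), -0.1)
        with pytest.raises(MkError):
            MkRates(-1.0, 1.0)


class TestPruning:
    def test_two_tip_hand_value(self):
        t = math.log(2)
        tree = make_tree(f"(A:{t:.17g},B:{t:.17g});")
        lnL = pruning_lnL(tree, {"A": 1, "B": 1}, MkRates(1.0, 1.0))
        # 0.5 * (P01^2 + P11^2) = 0.5 (0.375^2 + 0.625^2) = 0.265625
        assert lnL == pytest.approx(math.log(0.265625), abs=1e-12)

    def test_missing_tip_equals_pruned_tree(self):
        tree = random_tree(8, seed=2)
        states = random_states(tree, seed=3)
        gone = tree.tip_labels[4]
        states[gone] = None
        rates = MkRates(0.7, 1.3)
        full = pruning_lnL(tree, states, rates)
        sub = tree.prune_to([lb for lb in tree.tip_labels if lb != gone])
        reduced = pruning_lnL(sub, {lb: states[lb] for lb in sub.tip_labels},
                              rates)
        assert full == pytest.approx(reduced, abs=1e-9)

    def test_zero_rates_monomorphic(self):
        tree = random_tree(6, seed=4)
        lnL = pruning_lnL(tree, {lb: 1 for lb in tree.tip_labels},
                          MkRates(0.0, 0.0))
        assert lnL == pytest.approx(math.log(0.5), abs=1e-12)

    def test_all_missing_errors(self):
        tree = random_tree(4, seed=5)
        with pytest.raises(MkError, match="missing"):
            pruning_lnL(tree, {lb: None for lb in tree.tip_labels},
                        MkRates(1, 1))

    def test_unknown_taxon_errors(self):
        tree = random_tree(3, seed=5)
        states = {lb: 1 for lb in tree.tip_labels}
        states["NOPE"] = 0
        with pytest.raises(MkError, match="NOPE"):
            pruning_lnL(tree, states, MkRates(1, 1))

    def test_matches_enumeration(self):
        rng = np.random.default_rng(99)
        for k in range(30):
            tree = random_tree(int(rng.integers(2, 7)), seed=1000 + k)
            states = random_states(tree, seed=k,
                                   missing_frac=0.2 if k % 3 == 0 else 0.0)
            q01, q10 = rng.uniform(0.05, 3.0, 2)
            got = pruning_lnL(tree, states, MkRates(q01, q10))
            want = oracles.enum_lnL(tree, states, q01, q10)
            assert got == pytest.approx(want, abs=1e-9)

    def test_permutation_invariance(self):
        tree = random_tree(10, seed=6)
        states = random_states(tree, seed=7)
        rates = MkRates(0.4, 0.9)
        base = pruning_lnL(tree, states, rates)
        rng = np.random.default_rng(8)
        labels = tree.tip_labels
        perm = list(rng.permutation(labels))
        relabeled = tree.copy()
        mapping = dict(zip(labels, perm))
        relabeled.label = [mapping.get(lb) if lb in mapping else lb
                           for lb in tree.label]
        permuted_states = {mapping[lb]: states[lb] for lb in labels}
        assert pruning_lnL(relabeled, permuted_states, rates) == \
            pytest.approx(base, abs=1e-12)

    def test_stationary_prior(self):
        tree = random_tree(5, seed=9)
        states = random_states(tree, seed=9)
        rates = MkRates(0.5, 1.5)
        got = pruning_lnL(tree, states, rates,
                          FitSettings(root_prior="stationary"))
        want = oracles.enum_lnL(tree, states, 0.5, 1.5,
                                prior=rates.stationary)
        assert got == pytest.approx(want, abs=1e-9)

    def test_drop_taxon_policy_matches_marginalize(self):
        # with flat priors the two missing-data policies agree
        tree = random_tree(9, seed=10)
        states = random_states(tree, seed=11, missing_frac=0.3)
        rates = MkRates(0.8, 0.6)
        a = pruning_lnL(tree, states, rates,
                        FitSettings(missing_policy="marginalize"))
        b = pruning_lnL(tree, states, rates,
                        FitSettings(missing_policy="drop_taxon"))
        assert a == pytest.approx(b, abs=1e-9)


class TestFitMk:
    def test_monomorphic_boundary(self):
        tree = random_tree(8, seed=12)
        fit = fit_mk(tree, {lb: 1 for lb in tree.tip_labels}, "Mk1",
                     FitSettings(n_restarts=2))
        assert fit.warning is not None
        assert fit.lnL == pytest.approx(math.log(0.5), abs=1e-4)

    def test_mk1_equality_constraint(self):
        tree = random_tree(20, seed=13)
        states = simulate_trait(tree, MkRates(0.8, 0.8), seed=14)
        fit = fit_mk(tree, states, "Mk1", FitSettings(n_restarts=3))
        assert fit.rates.q01 == fit.rates.q10
        assert fit.n_params == 1
        assert fit.AIC == pytest.approx(2 - 2 * fit.lnL)

    def test_mk2_self_consistency(self):
        tree = random_tree(25, seed=15)
        states = simulate_trait(tree, MkRates(0.5, 1.5), seed=16)
        settings = FitSettings(n_restarts=3)
        fit = fit_mk(tree, states, "Mk2", settings)
        assert fit.n_params == 2
        relnL = pruning_lnL(tree, states, fit.rates, settings)
        assert relnL == pytest.approx(fit.lnL, abs=1e-9)

    def test_mk2_beats_or_ties_mk1(self):
        tree = random_tree(30, seed=17)
        states = simulate_trait(tree, MkRates(0.3, 1.8), seed=18)
        s = FitSettings(n_restarts=3)
        assert fit_mk(tree, states, "Mk2", s).lnL >= \
            fit_mk(tree, states, "Mk1", s).lnL - 1e-6

    def test_rate_recovery_order_of_magnitude(self):
        # Mk1 estimate within a factor of 2 of truth in most replicates
        tree = random_tree(134, seed=19, root_age=2.7)
        ok = 0
        n = 20
        for rep in range(n):
            states = simulate_trait(tree, MkRates(0.5, 0.5), seed=500 + rep)
            if len(set(states.values())) < 2:
                continue
            fit = fit_mk(tree, states, "Mk1", FitSettings(n_restarts=2))
            if 0.25 <= fit.rates.q01 <= 1.0:
                ok += 1
        assert ok >= 0.75 * n

    def test_unknown_model(self):
        tree = random_tree(4, seed=20)
        with pytest.raises(MkError):
            fit_mk(tree, {lb: 0 for lb in tree.tip_labels}, "Mk3")


class TestLambdaTransform:
    def test_identity_at_one(self):
        tree = random_tree(12, seed=21)
        out = lambda_transform(tree, 1.0)
        assert np.allclose(out.length, tree.length, atol=1e-12)

    def test_star_at_zero(self):
        tree = random_tree(12, seed=22, root_age=2.0)
        out = lambda_transform(tree, 0.0)
        for t in out.tips():
            path = 0.0
            i = t
            while out.parent[i] >= 0:
                path += out.length[i]
                i = out.parent[i]
            assert path == pytest.approx(2.0, abs=1e-12)
        for i in range(out.n_nodes):
            if out.children[i] and i != out.root:
                assert out.length[i] == pytest.approx(0.0, abs=1e-12)

    def test_half_lambda_hand_example(self):
        tree = make_tree("((A:1.0,B:1.0):1.0,C:2.0);")
        out = lambda_transform(tree, 0.5)
        lengths = {}
        for i in range(out.n_nodes):
            if out.label[i]:
                lengths[out.label[i]] = out.length[i]
            elif out.parent[i] >= 0:
                lengths["internal"] = out.length[i]
        assert lengths["internal"] == pytest.approx(0.5, abs=1e-12)
        assert lengths["A"] == pytest.approx(1.5, abs=1e-12)
        assert lengths["B"] == pytest.approx(1.5, abs=1e-12)
        assert lengths["C"] == pytest.approx(2.0, abs=1e-12)

    @given(st.floats(0.0, 1.0), st.integers(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_ultrametric_and_root_age_preserved(self, lam, seed):
        tree = random_tree(8, seed=seed, root_age=2.7)
        out = lambda_transform(tree, lam)
        out.validate(tol=1e-8)
        assert out.root_age == pytest.approx(2.7, abs=1e-9)

    def test_domain_error(self):
        tree = random_tree(4, seed=23)
        with pytest.raises(MkError):
            lambda_transform(tree, 1.5)


class TestPhyloSignal:
    def test_monomorphic_degenerate(self):
        tree = random_tree(6, seed=24)
        fit = phylo_signal_test(tree, {lb: 0 for lb in tree.tip_labels})
        assert fit.p_value == 1.0
        assert fit.warning is not None

    def test_lr_nonnegative_and_bounds(self):
        for seed in range(5):
            tree = random_tree(15, seed=25 + seed)
            states = random_states(tree, seed=seed)
            fit = phylo_signal_test(tree, states, FitSettings(n_restarts=2))
            assert fit.LR_stat >= 0
            assert 0.0 <= fit.lambda_hat <= 1.0
            assert fit.lnL_hat >= fit.lnL_lambda0 - 1e-9

    def test_star_tree_no_signal(self):
        # on a star tree lambda has no effect: LR = 0, p = 1
        tree = lambda_transform(random_tree(15, seed=30), 0.0)
        states = random_states(tree, seed=31)
        fit = phylo_signal_test(tree, states, FitSettings(n_restarts=2))
        assert fit.LR_stat == pytest.approx(0.0, abs=1e-6)
        assert fit.p_value > 0.99

    def test_strong_signal_detected(self):
        tree = random_tree(60, seed=32, root_age=2.7)
        states = simulate_trait(tree, MkRates(1.5, 1.5), seed=33)
        fit = phylo_signal_test(tree, states, FitSettings(n_restarts=2))
        assert fit.lambda_hat > 0.5

    def test_mixture_halves_p(self):
        tree = random_tree(30, seed=34, root_age=2.7)
        states = simulate_trait(tree, MkRates(1.0, 1.0), seed=35)
        s = FitSettings(n_restarts=2)
        plain = phylo_signal_test(tree, states, s)
        mix = phylo_signal_test(tree, states, s, p_mixture=True)
        if plain.LR_stat > 0:
            assert mix.p_value == pytest.approx(plain.p_value / 2, rel=1e-9)


class TestMarginalASR:
    def test_observed_tip_point_mass(self):
        tree = random_tree(5, seed=36)
        states = random_states(tree, seed=36)
        marg = marginal_asr(tree, states, MkRates(0.5, 0.5))
        for i in tree.tips():
            st_i = states[tree.label[i]]
            if st_i is not None:
                assert marg[i][st_i] == pytest.approx(1.0, abs=1e-12)

    def test_two_tip_symmetry(self):
        tree = make_tree("(A:1.0,B:1.0);")
        marg = marginal_asr(tree, {"A": 0, "B": 1}, MkRates(1.0, 1.0))
        assert marg[tree.root][0] == pytest.approx(0.5, abs=1e-12)

    def test_sums_to_one(self):
        tree = random_tree(12, seed=37)
        states = random_states(tree, seed=38, missing_frac=0.2)
        marg = marginal_asr(tree, states, MkRates(0.9, 0.3))
        for p0, p1 in marg.values():
            assert p0 + p1 == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(321)
        for k in range(15):
            tree = random_tree(int(rng.integers(3, 6)), seed=2000 + k)
            states = random_states(tree, seed=k,
                                   missing_frac=0.25 if k % 2 else 0.0)
            q01, q10 = rng.uniform(0.1, 2.5, 2)
            got = marginal_asr(tree, states, MkRates(q01, q10))
            want = oracles.enum_marginals(tree, states, q01, q10)
            for i in range(tree.n_nodes):
                assert got[i][0] == pytest.approx(want[i][0], abs=1e-9)
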