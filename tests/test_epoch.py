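import math

import numpy as np
import pytest

from epochmk import (CumulativeProfile, EpochParams, FitSettings, MkError,
                     MkRates, cumulative_support, epoch_asr, epoch_lnL,
                     fit_epoch, fit_joint, fit_mk, marginal_asr, profile_scan,
                     pruning_lnL, shift_grid)
from epochmk.epoch import LikelihoodProfile
from epochmk.synthetic_data import SynthConfig, generate_trait_matrix, \
    simulate_trait

import oracles
from conftest import make_tree, random_states, random_tree


class TestEpochLnL:
    def test_unit_multipliers_nest_exactly(self):
        tree = random_tree(15, seed=1, root_age=2.0)
        states = random_states(tree, seed=2)
        rates = MkRates(0.7, 1.1)
        constant = pruning_lnL(tree, states, rates)
        for t in (0.3, 1.0, 1.9):
            params = EpochParams(base=rates, t_shift=t, r01=1.0, r10=1.0)
            assert epoch_lnL(tree, states, params) == constant  # bit-for-bit

    def test_shift_at_root_reduces_to_multiplied_rates(self):
        tree = random_tree(10, seed=3, root_age=2.0)
        states = random_states(tree, seed=4)
        q01, q10, r01, r10 = 0.5, 0.8, 0.2, 3.0
        params = EpochParams(base=MkRates(q01, q10),
                             t_shift=2.0 * (1 - 1e-12), r01=r01, r10=r10)
        got = epoch_lnL(tree, states, params)
        want = pruning_lnL(tree, states, MkRates(q01 * r01, q10 * r10))
        assert got == pytest.approx(want, abs=1e-8)

    def test_single_spanning_branch_matrix_product(self):
        # 2-tip cherry of depth 2 with the shift at age 1
        tree = make_tree("(A:2.0,B:2.0);")
        q01, q10, r01, r10 = 0.4, 0.9, 0.1, 2.0
        params = EpochParams(base=MkRates(q01, q10), t_shift=1.0,
                             r01=r01, r10=r10)
        got = epoch_lnL(tree, {"A": 0, "B": 1}, params)
        M = oracles.edge_matrix_epoch(q01, q10, r01, r10, 1.0, 2.0, 0.0)
        want = math.log(0.5 * (M[0, 0] * M[0, 1] + M[1, 0] * M[1, 1]))
        assert got == pytest.approx(want, abs=1e-12)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for k in range(25):
            tree = random_tree(int(rng.integers(2, 7)), seed=3000 + k,
                               root_age=2.0)
            states = random_states(tree, seed=k,
                                   missing_frac=0.2 if k % 4 == 0 else 0.0)
            q01, q10 = rng.uniform(0.1, 3.0, 2)
            r01, r10 = 10.0 ** rng.uniform(-1, 1, 2)
            t = rng.uniform(0.05, 1.95)
            params = EpochParams(base=MkRates(q01, q10), t_shift=t,
                                 r01=r01, r10=r10)
            got = epoch_lnL(tree, states, params)
            want = oracles.enum_lnL(tree, states, q01, q10, r01, r10, t)
            assert got == pytest.approx(want, abs=1e-9)

    def test_shift_outside_domain(self):
        tree = random_tree(4, seed=8, root_age=2.0)
        states = random_states(tree, seed=8)
        with pytest.raises(MkError, match="t_shift"):
            epoch_lnL(tree, states,
                      EpochParams(MkRates(1, 1), t_shift=2.5, r01=1, r10=1))


class TestShiftGrid:
    def test_default_38_points(self):
        g = shift_grid(2.7)
        assert len(g) == 38
        assert g[0] > 0 and g[-1] < 2.7
        assert np.allclose(np.diff(g), g[1] - g[0])

    def test_too_few_points(self):
        with pytest.raises(MkError):
            shift_grid(2.7, 1)


@pytest.fixture(scope="module")
def shifted_data():
    cfg = SynthConfig(n_tips=40, root_age=2.7, tree_model="balanced",
                      age_curve=0.5, seed=5)
    from epochmk import generate_chronogram
    tree = generate_chronogram(cfg)
    params = EpochParams(base=MkRates(1.0, 1.0), t_shift=1.7, r01=0.1, r10=0.1)
    states = simulate_trait(tree, params, seed=6)
    return tree, states


class TestFitEpoch:
    def test_self_consistency(self, shifted_data):
        tree, states = shifted_data
        settings = FitSettings(n_restarts=2)
        fit = fit_epoch(tree, states, settings, "free", n_grid=8)
        relnL = epoch_lnL(tree, states, fit.params, settings)
        assert relnL == pytest.approx(fit.lnL, abs=1e-9)
        assert fit.n_params == 5

    def test_nesting_chain(self, shifted_data):
        tree, states = shifted_data
        s = FitSettings(n_restarts=2)
        mk1 = fit_mk(tree, states, "Mk1", s)
        mk2 = fit_mk(tree, states, "Mk2", s)
        ep = fit_epoch(tree, states, s, "free", n_grid=8, constant_fit=mk2)
        assert mk2.lnL >= mk1.lnL - 1e-6
        assert ep.lnL >= mk2.lnL - 1e-6
        assert ep.delta_lnL_vs_constant >= -1e-6

    def test_fixed_mode(self, shifted_data):
        tree, states = shifted_data
        s = FitSettings(n_restarts=2)
        free = fit_epoch(tree, states, s, "free", n_grid=8)
        fixed = fit_epoch(tree, states, s, ("fixed", 1.7))
        assert fixed.params.t_shift == 1.7
        assert fixed.n_params == 4
        assert free.lnL >= fixed.lnL - 1e-6

    def test_equal_rates_variant(self, shifted_data):
        tree, states = shifted_data
        s = FitSettings(n_restarts=2)
        fit = fit_epoch(tree, states, s, "free", n_grid=8, equal_rates=True)
        assert fit.params.base.q01 == fit.params.base.q10
        assert fit.log10_r01 == fit.log10_r10
        assert fit.n_params == 3
        assert fit.constant_fit.model == "Mk1"
        relnL = epoch_lnL(tree, states, fit.params, s)
        assert relnL == pytest.approx(fit.lnL, abs=1e-9)

    def test_bad_shift_mode(self, shifted_data):
        tree, states = shifted_data
        with pytest.raises(MkError):
            fit_epoch(tree, states, shift_mode="nonsense")


class TestProfileScan:
    def test_grid_and_bounds(self, shifted_data):
        tree, states = shifted_data
        s = FitSettings(n_restarts=2)
        const = fit_mk(tree, states, "Mk2", s)
        prof = profile_scan(tree, states, s, n_grid=10, constant_fit=const)
        assert len(prof.grid) == 10
        assert (prof.delta_lnL >= -1e-6).all()
        free = fit_epoch(tree, states, s, "free", n_grid=10,
                         constant_fit=const)
        assert np.nanmax(prof.delta_lnL) <= \
            free.delta_lnL_vs_constant + 1e-6
        assert prof.argmax_age in prof.grid
        assert prof.argmax_age == min(prof.tied_ages)


class TestCumulativeSupport:
    def _profile(self, grid, values):
        return LikelihoodProfile(grid=np.asarray(grid, float),
                                 delta_lnL=np.asarray(values, float),
                                 argmax_age=float(grid[int(np.argmax(values))]))

    def test_single_profile_identity(self):
        p = self._profile([1, 2, 3], [0.5, 4.0, 2.0])
        cum = cumulative_support([p])
        assert np.allclose(cum.summed_support, p.delta_lnL)

    def test_threshold_zeroing(self):
        p1 = self._profile([1, 2, 3], [0.0, 10.0, 5.0])
        p2 = self._profile([1, 2, 3], [0.0, 10.0, 1.0])
        cum = cumulative_support([p1, p2], threshold=6.0)
        assert cum.summed_support.tolist() == [0.0, 20.0, 6.0]
        assert cum.thresholded_support.tolist() == [0.0, 20.0, 0.0]
        # thresholded peaks are a subset of raw peaks
        assert np.argmax(cum.thresholded_support) == \
            np.argmax(cum.summed_support)

    def test_flat_sum_survives_threshold(self):
        p1 = self._profile([1, 2], [3.0, 1.0])
        p2 = self._profile([1, 2], [1.0, 3.0])
        cum = cumulative_support([p1, p2], threshold=6.0)
        assert np.allclose(cum.thresholded_support, [4.0, 4.0])

    def test_mismatched_grids_error(self):
        p1 = self._profile([1, 2, 3], [0, 1, 2])
        p2 = self._profile([1, 2], [0, 1])
        with pytest.raises(MkError, match="grid"):
            cumulative_support([p1, p2])


class TestFitJoint:
    def test_single_trait_equals_fit_epoch(self):
        from epochmk.treeio import TraitMatrix
        import pandas as pd
        tree = random_tree(16, seed=9, root_age=2.7)
        states = simulate_trait(tree, MkRates(0.8, 0.8), seed=10)
        tm = TraitMatrix(pd.DataFrame(
            {"t1": pd.Series(states, dtype=object)}).loc[tree.tip_labels])
        s = FitSettings(n_restarts=2)
        joint = fit_joint(tree, tm, s, "shared_pair", n_grid=8)
        single = fit_epoch(tree, states, s, "free", n_grid=8)
        assert joint.lnL_total == pytest.approx(single.lnL, abs=1e-6)
        assert joint.n_params == 5

    def test_param_bookkeeping_25_traits(self):
        from epochmk import generate_chronogram
        cfg = SynthConfig(n_tips=8, root_age=2.7, n_traits=25,
                          missing_frac=0.0, seed=11)
        tree = generate_chronogram(cfg)
        tm, _ = generate_trait_matrix(tree, cfg, "all_constant",
                                      rates=MkRates(0.5, 0.5))
        s = FitSettings(n_restarts=1)
        joint = fit_joint(tree, tm, s, "shared_pair", n_grid=4)
        assert joint.n_params == 53
        assert joint.n_params_no_shift == 50
        # self-consistency of the total
        tot = sum(epoch_lnL(tree, tm.binary_column(nm),
                            EpochParams(joint.per_trait_base[nm],
                                        joint.shared_t_shift,
                                        joint.shared_r01, joint.shared_r10),
                            s)
                  for nm in tm.traits)
        assert tot == pytest.approx(joint.lnL_total, abs=1e-9)

    def test_shared_scalar_mode(self):
        from epochmk import generate_chronogram
        cfg = SynthConfig(n_tips=8, root_age=2.7, n_traits=3,
                          missing_frac=0.0, seed=12)
        tree = generate_chronogram(cfg)
        tm, _ = generate_trait_matrix(tree, cfg, "all_constant",
                                      rates=MkRates(0.5, 0.5))
        joint = fit_joint(tree, tm, FitSettings(n_restarts=1),
                          "shared_scalar", n_grid=4)
        assert joint.shared_r01 == joint.shared_r10
        assert joint.n_params == 2 * 3 + 2


class TestEpochASR:
    def test_unit_multipliers_match_constant_asr(self):
        tree = random_tree(10, seed=13, root_age=2.0)
        states = random_states(tree, seed=14)
        rates = MkRates(0.6, 1.2)
        fitlike = EpochParams(base=rates, t_shift=1.0, r01=1.0, r10=1.0)
        got = epoch_asr(tree, states, fitlike)
        want = marginal_asr(tree, states, rates)
        for i in range(tree.n_nodes):
            assert got[i][0] == pytest.approx(want[i][0], abs=1e-12)

    def test_tips_point_mass_and_sums(self):
        tree = random_tree(8, seed=15, root_age=2.0)
        states = random_states(tree, seed=16)
        params = EpochParams(base=MkRates(1.0, 0.5), t_shift=0.9,
                             r01=0.2, r10=0.3)
        marg = epoch_asr(tree, states, params)
        for p0, p1 in marg.values():
            assert p0 + p1 == pytest.approx(1.0, abs=1e-12)
        for i in tree.tips():
            st_i = states[tree.label[i]]
            if st_i is not None:
                assert marg[i][st_i] == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_mid_shift(self):
        rng = np.random.default_rng(77)
        for k in range(12):
            tree = random_tree(int(rng.integers(2, 5)), seed=4000 + k,
                               root_age=2.0)
            states = random_states(tree, seed=k)
            q01, q10 = rng.uniform(0.2, 2.0, 2)
            r01, r10 = 10.0 ** rng.uniform(-1, 1, 2)
            t = rng.uniform(0.4, 1.6)
            params = EpochParams(base=MkRates(q01, q10), t_shift=t,
                                 r01=r01, r10=r10)
            got = epoch_asr(tree, states, params)
            want = oracles.enum_marginals(tree, states, q01, q10, r01, r10, t)
            for i in range(tree.n_nodes):
                assert got[i][0] == pytest.approx(want[i][0], abs=1e-9)
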