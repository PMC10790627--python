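import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oscsync import (
    DegenerateModelError,
    build_dataset,
    build_dataset_from_binary,
    connectivity_grid_from_weights,
    directed_information,
    fit_lasso_logistic_cv,
    shapley_attribution,
    split_train_test,
)
from oscsync.synth import CouplingSpec, gen_coupled_binary_trains


class TestBuildDataset:
    def test_toy_example_matches_manual_enumeration(self):
        """1 trial, 30 bins, Y spikes at {12, 15}, X silent.

        Rows t = 0..9 are dropped (incomplete 10-bin history); t = 10, 11
        are dropped by the imbalance rule (no activity at t or in the
        preceding 100 ms); every t >= 12 is kept (Y's spike at 12 stays
        inside the look-back window).  Features enumerated by hand.
        """
        trains = np.zeros((1, 2, 30), dtype=np.uint8)
        trains[0, 0, [12, 15]] = 1
        ds = build_dataset_from_binary(trains, target=0, candidates=[1])
        np.testing.assert_array_equal(ds.bin_index, np.arange(12, 30))
        np.testing.assert_array_equal(
            ds.y, [1, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        )
        expected_refr = [0, 1, 1, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        expected_self = [0, 0, 0, 1, 1, 1, 2, 2, 2, 2, 2, 1, 1, 1, 0, 0, 0, 0]
        np.testing.assert_array_equal(ds.X[:, 0], expected_refr)
        np.testing.assert_array_equal(ds.X[:, 1], expected_self)
        np.testing.assert_array_equal(ds.X[:, 2], np.zeros(18))

    def test_refractory_vs_self_history_split(self):
        trains = np.zeros((1, 2, 30), dtype=np.uint8)
        trains[0, 0, 14] = 1  # Y spike at t-1 relative to t=15
        ds = build_dataset_from_binary(trains, 0, [1])
        row = np.flatnonzero(ds.bin_index == 15)[0]
        assert ds.X[row, 0] == 1 and ds.X[row, 1] == 0

    def test_empty_trains_zero_rows(self):
        trains = np.zeros((2, 2, 50), dtype=np.uint8)
        ds = build_dataset_from_binary(trains, 0, [1])
        assert ds.n_rows == 0

    def test_candidate_spike_keeps_rows(self):
        trains = np.zeros((1, 2, 30), dtype=np.uint8)
        trains[0, 1, 11] = 1  # only the candidate fires
        ds = build_dataset_from_binary(trains, 0, [1])
        np.testing.assert_array_equal(ds.bin_index, np.arange(11, 30))

    def test_target_among_candidates_rejected(self):
        trains = np.zeros((1, 2, 30), dtype=np.uint8)
        with pytest.raises(ValueError, match="target"):
            build_dataset_from_binary(trains, 0, [0, 1])

    def test_mask_units_keep_rows_identical_across_models(self):
        rng = np.random.default_rng(0)
        trains = (rng.random((3, 3, 200)) < 0.05).astype(np.uint8)
        full = build_dataset_from_binary(trains, 0, [1, 2])
        sub = build_dataset_from_binary(trains, 0, [1], mask_units=[1, 2])
        np.testing.assert_array_equal(full.bin_index, sub.bin_index)
        np.testing.assert_array_equal(full.trial_index, sub.trial_index)


class TestSplitTrainTest:
    def _dataset(self, seed=0, n_trials=4, rate=0.1, n_bins=400):
        rng = np.random.default_rng(seed)
        trains = (rng.random((n_trials, 2, n_bins)) < rate).astype(np.uint8)
        return build_dataset_from_binary(trains, 0, [1])

    def test_half_split_per_trial(self):
        ds = self._dataset()
        tr, te = split_train_test(ds, seed=1)
        assert tr.n_rows + te.n_rows == ds.n_rows
        for t in np.unique(ds.trial_index):
            n_tr = np.count_nonzero(tr.trial_index == t)
            n_te = np.count_nonzero(te.trial_index == t)
            assert abs(n_tr - n_te) <= 1

    def test_seed_determinism(self):
        ds = self._dataset()
        tr1, te1 = split_train_test(ds, seed=2)
        tr2, te2 = split_train_test(ds, seed=2)
        np.testing.assert_array_equal(tr1.bin_index, tr2.bin_index)
        np.testing.assert_array_equal(te1.bin_index, te2.bin_index)

    def test_stratification_fraction(self):
        fracs = []
        for i in range(200):
            ds = self._dataset(seed=i, n_trials=2)
            tr, te = split_train_test(ds, seed=1000 + i)
            fracs.append(tr.n_rows / ds.n_rows)
        assert np.all(np.abs(np.array(fracs) - 0.5) < 0.05)


class TestLassoLogisticCV:
    def test_single_class_raises_degenerate(self):
        trains = np.zeros((1, 2, 60), dtype=np.uint8)
        trains[0, 1, ::5] = 1  # candidate fires, target never
        ds = build_dataset_from_binary(trains, 0, [1])
        with pytest.raises(DegenerateModelError):
            fit_lasso_logistic_cv(ds, seed=0)

    def test_heavy_shrinkage_zeroes_weak_candidates(self):
        spec = CouplingSpec(cross_weights={(0, 1): 0.1})
        trains = gen_coupled_binary_trains(spec, 10, 1000, seed=1)
        ds = build_dataset_from_binary(trains, 1, [0])
        tr, _ = split_train_test(ds, seed=0)
        m = fit_lasso_logistic_cv(tr, lambda_grid=[10.0], seed=0)
        assert m.coef[2] == 0.0

    def test_seed_determinism(self):
        spec = CouplingSpec(cross_weights={(0, 1): 1.0})
        trains = gen_coupled_binary_trains(spec, 10, 500, seed=2)
        ds = build_dataset_from_binary(trains, 1, [0])
        tr, _ = split_train_test(ds, seed=0)
        m1 = fit_lasso_logistic_cv(tr, seed=5)
        m2 = fit_lasso_logistic_cv(tr, seed=5)
        assert m1.lambda_ == m2.lambda_
        np.testing.assert_array_equal(m1.coef, m2.coef)

    def test_recovers_coefficient_signs(self):
        spec = CouplingSpec(cross_weights={(0, 1): 1.0})
        trains = gen_coupled_binary_trains(spec, 60, 1000, seed=3)
        ds = build_dataset_from_binary(trains, 1, [0])
        tr, _ = split_train_test(ds, seed=0)
        m = fit_lasso_logistic_cv(tr, seed=1)
        assert m.coef[0] < 0          # refractory
        assert m.coef[2] > 0.5        # cross-coupling (truth 1.0)


class TestDirectedInformation:
    def _fitted(self, coupling, seed, n_trials=30):
        spec = CouplingSpec(cross_weights={(0, 1): coupling} if coupling else {})
        trains = gen_coupled_binary_trains(spec, n_trials, 1000, seed=seed)
        ds = build_dataset_from_binary(trains, 1, [0])
        tr, te = split_train_test(ds, seed=seed)
        full = fit_lasso_logistic_cv(tr, seed=seed + 1)
        none = fit_lasso_logistic_cv(tr, [], seed=seed + 2)
        return te, full, none

    def test_full_equals_reduced_gives_exact_zero(self):
        te, _, none = self._fitted(0.0, seed=4, n_trials=5)
        assert directed_information(te, none, none) == 0.0

    def test_true_coupling_positive(self):
        te, full, none = self._fitted(1.0, seed=5)
        assert directed_information(te, full, none) > 0.0

    def test_independent_near_zero(self):
        vals = [directed_information(*self._fitted(0.0, seed=100 + i, n_trials=8))
                for i in range(10)]
        assert abs(np.median(vals)) < 0.01

    def test_reduced_not_subset_rejected(self):
        te, full, none = self._fitted(0.0, seed=6, n_trials=5)
        with pytest.raises(ValueError, match="subset"):
            directed_information(te, none, full)


class TestShapley:
    def test_printed_formula_values(self):
        s1, s2 = shapley_attribution(0.4, 0.3, 0.2, 0.0)
        assert s1 == pytest.approx(0.25)
        assert s2 == pytest.approx(0.15)

    def test_symmetric_inputs_equal_shares(self):
        s1, s2 = shapley_attribution(0.5, 0.2, 0.2, 0.0)
        assert s1 == s2

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.tuples(*[st.floats(-1, 1) for _ in range(4)]))
    def test_shares_sum_to_total_exactly(self, vals):
        i_all, i_v1, i_hva, i_none = vals
        s1, s2 = shapley_attribution(i_all, i_v1, i_hva, i_none)
        assert s1 + s2 == pytest.approx(i_all - i_none, abs=1e-14, rel=1e-12)


class TestConnectivityGrid:
    def _weights(self, seed, shift=0.0, cell=None):
        rng = np.random.default_rng(seed)
        pre = {sid: rng.standard_normal(15) * 0.01 for sid in range(25)}
        post = {sid: rng.standard_normal(15) * 0.01
                + (shift if (cell is None or sid == cell) else 0.0)
                for sid in range(25)}
        return pre, post

    def test_seed_determinism(self):
        pre, post = self._weights(0)
        g1 = connectivity_grid_from_weights(pre, post, "V1", "LM", n_perm=500, seed=3)
        g2 = connectivity_grid_from_weights(pre, post, "V1", "LM", n_perm=500, seed=3)
        np.testing.assert_array_equal(g1.pvalues, g2.pvalues)
        np.testing.assert_array_equal(g1.reject, g2.reject)

    def test_shifted_cell_detected(self):
        pre, post = self._weights(1, shift=0.05, cell=12)
        g = connectivity_grid_from_weights(pre, post, "V1", "LM", n_perm=2000, seed=0)
        assert g.reject[2, 2]
        assert g.diff[2, 2] > 0.03

    def test_missing_cell_marked(self):
        pre, post = self._weights(2)
        del post[7]
        g = connectivity_grid_from_weights(pre, post, "V1", "LM", n_perm=200, seed=0)
        assert np.isnan(g.diff[1, 2])
        assert not g.reject[1, 2]
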