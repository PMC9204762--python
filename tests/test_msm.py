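"""Splits, Koopman estimation, VAMP-2 scoring, training, state alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import softmsm as sm
from softmsm.msm import _pair_indices, vamp2_from_chi

from conftest import count_transition_matrix


class TestSplits:
    def test_stated_fractions(self):
        plan = sm.make_splits(100, seed=0)
        assert len(plan.test_idx) == 10
        for train, val in plan.splits:
            assert len(train) == 81 and len(val) == 9

    def test_partition_property(self):
        plan = sm.make_splits(237, seed=1)
        all_frames = set(range(237))
        for train, val in plan.splits:
            parts = [set(plan.test_idx), set(train), set(val)]
            assert set().union(*parts) == all_frames
            assert sum(len(p) for p in parts) == 237  # pairwise disjoint

    def test_determinism(self):
        a = sm.make_splits(500, seed=42)
        b = sm.make_splits(500, seed=42)
        assert (a.test_idx == b.test_idx).all()
        for (t1, v1), (t2, v2) in zip(a.splits, b.splits):
            assert (t1 == t2).all() and (v1 == v2).all()

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            sm.make_splits(19, seed=0)


class TestBoundFrameFilter:
    def test_threshold_and_counting_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.2, 1.0, (300, 4))
        d = sm.DistanceSeries([vals], [f"r{i}" for i in range(4)], 250.0, "nm")
        masks = sm.filter_bound_frames(d, cutoff=0.5)
        expected = (vals.min(axis=1) <= 0.5)
        assert (masks[0] == expected).all()
        # explicit spot checks at the cutoff
        row_in = np.full((1, 4), 0.6); row_in[0, 2] = 0.4
        row_out = np.full((1, 4), 0.6)
        d2 = sm.DistanceSeries([np.vstack([row_in, row_out])],
                               list("abcd"), 250.0, "nm")
        m = sm.filter_bound_frames(d2)[0]
        assert m[0] and not m[1]


class TestKoopmanEstimator:
    def test_hard_assignment_equals_count_msm(self, hard_assignment,
                                              small_benchmark):
        lag = 5
        model = sm.estimate_koopman(hard_assignment, lag)
        oracle = count_transition_matrix(
            small_benchmark.ground_truth.state_paths, 2, lag=lag)
        assert np.abs(model.K - oracle).max() < 1e-12

    def test_single_state(self):
        assign = sm.StateAssignment([np.ones((50, 1))], 250.0)
        model = sm.estimate_koopman(assign, 1)
        assert np.allclose(model.K, [[1.0]])
        assert np.allclose(model.pi, [1.0])

    def test_stationary_distribution_recovery(self, hard_assignment,
                                              small_spec):
        model = sm.estimate_koopman(hard_assignment, 1)
        target = small_spec.stationary_distribution()
        # correlated-sample standard error via the relaxation time
        t2 = sm.analytic_timescales(small_spec.transition_matrix,
                                    small_spec.dt_ns)[0]
        n_eff = hard_assignment.n_frames * small_spec.dt_ns / (2 * t2)
        se = np.sqrt(target[0] * (1 - target[0]) / n_eff)
        assert abs(model.pi[0] - target[0]) < 3 * se

    def test_empty_state_rejected(self):
        chi = np.zeros((30, 2)); chi[:, 0] = 1.0
        with pytest.raises(ValueError, match="zero transition mass"):
            sm.estimate_koopman(sm.StateAssignment([chi], 250.0), 1)


class TestVamp2:
    def test_hard_two_state_score_is_one_plus_lambda_sq(self, hard_assignment,
                                                        small_spec):
        lam2 = np.sort(np.linalg.eigvals(small_spec.transition_matrix))[0]
        score = sm.vamp2_score(hard_assignment, 1)
        assert score == pytest.approx(1 + lam2**2, abs=0.02)

    def test_constant_assignment_scores_one(self):
        chi = np.tile([0.5, 0.5], (200, 1))
        assert sm.vamp2_score(sm.StateAssignment([chi], 250.0), 1) == \
            pytest.approx(1.0, abs=1e-6)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_score_never_exceeds_k(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        chi = rng.dirichlet(np.ones(k), size=100)
        assign = sm.StateAssignment([chi], 250.0)
        assert sm.vamp2_score(assign, 1) <= k + 1e-9


class TestTraining:
    def test_recovers_well_separated_states(self, angle_features,
                                            small_benchmark):
        model = sm.train_assignment_model(angle_features, k=2, lag_frames=20,
                                          config="desk", seed=1)
        chi = model.assignment.stacked
        true = np.concatenate(small_benchmark.ground_truth.state_paths)
        pred = chi.argmax(axis=1)
        acc = max((pred == true).mean(), ((1 - pred) == true).mean())
        assert acc >= 0.95
        confident_correct = (chi.max(axis=1) >= 0.9).mean()
        assert confident_correct >= 0.95
        assert not model.metadata["degenerate_collapse"]

    def test_single_state_is_degenerate_constant(self, angle_features):
        cfg = sm.TrainingConfig(max_epochs=2, n_trials=1)
        model = sm.train_assignment_model(angle_features, k=1, lag_frames=20,
                                          config=cfg, seed=0)
        assert np.allclose(model.assignment.stacked, 1.0)
        assert sm.vamp2_score(model.assignment, 20) == pytest.approx(1.0, abs=1e-9)

    def test_time_shuffling_destroys_slow_process(self, angle_features):
        rng = np.random.default_rng(0)
        shuffled = sm.FeatureSeries(
            [a[rng.permutation(len(a))] for a in angle_features.arrays],
            angle_features.labels, 250.0, "dimensionless")
        cfg = sm.TrainingConfig(max_epochs=10, n_trials=1)
        model = sm.train_assignment_model(shuffled, k=2, lag_frames=20,
                                          config=cfg, seed=0)
        ts = sm.relaxation_timescales(model.koopman)[0]
        # i.i.d. frames: relaxation collapses to the order of the lag time
        assert ts < 2 * model.koopman.tau_ns

    def test_nonfinite_features_rejected(self):
        bad = sm.FeatureSeries([np.full((30, 2), np.nan)], ["a", "b"],
                               250.0, "dimensionless")
        with pytest.raises(ValueError, match="non-finite"):
            sm.train_assignment_model(bad, k=2, lag_frames=1, seed=0)

    def test_pairs_never_cross_trajectory_boundaries(self):
        lengths = np.array([7, 3, 9])
        t0, t1 = _pair_indices(lengths, 4)
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        bounds = [(s, s + n) for s, n in zip(starts, lengths)]
        for a, b in zip(t0, t1):
            assert b - a == 4
            assert any(lo <= a < hi and lo <= b < hi for lo, hi in bounds)


class TestStateAlignment:
    def _fake_model(self, pi):
        K = np.array([[0.9, 0.1], [0.2, 0.8]])
        chi = np.tile(pi, (30, 1))
        assign = sm.StateAssignment([chi / chi.sum(1, keepdims=True)], 250.0)
        koop = sm.KoopmanModel(K, np.array([2 / 3, 1 / 3]), 1, 250.0)
        return sm.TrainedModel(None, assign, koop, {})

    def test_identity_for_identical_models(self):
        m = self._fake_model(np.array([0.6, 0.4]))
        maps = [np.array([[1.0, 0.0], [0.0, 1.0]])] * 2
        perms = sm.align_states_across_models([m, m], maps)
        assert perms == [(0, 1), (0, 1)]

    def test_swap_recovered(self):
        m = self._fake_model(np.array([0.6, 0.4]))
        ref = np.array([[1.0, 0.2], [0.1, 0.9]])
        perms = sm.align_states_across_models([m, m], [ref, ref[::-1]])
        assert perms[1] == (1, 0)

    def test_alignment_never_increases_total_rmsd(self):
        rng = np.random.default_rng(3)
        m = self._fake_model(np.array([0.5, 0.5]))
        for _ in range(10):
            ref = rng.uniform(0, 1, (2, 6))
            other = rng.uniform(0, 1, (2, 6))
            perms = sm.align_states_across_models([m, m], [ref, other])
            p = perms[1]
            before = sum(np.sqrt(np.mean((other[i] - ref[i]) ** 2)) for i in range(2))
            after = sum(np.sqrt(np.mean((other[p[i]] - ref[i]) ** 2)) for i in range(2))
            assert after <= before + 1e-12
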