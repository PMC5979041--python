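"""Transition counting, reversible maximum-likelihood MSMs, implied
timescales and k-means discretization."""

import numpy as np
import pytest

import bindkin as bk
from bindkin.markov import (
    MarkovModel,
    cluster_kmeans,
    count_matrix,
    estimate_reversible,
    implied_timescales,
    reversible_log_likelihood,
)
from bindkin.synthetic import DiscreteTrajectory


class TestCountMatrix:
    def test_hand_counts(self):
        d = DiscreteTrajectory([0, 1, 0, 1], 1.0)
        cr = count_matrix(d, 1.0)
        assert np.array_equal(cr.counts, [[0, 2], [1, 0]])

    def test_self_transitions_only(self):
        d = DiscreteTrajectory([0, 0, 0], 1.0)
        cr = count_matrix(d, 1.0)
        assert np.array_equal(cr.counts, [[2]])

    def test_matches_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(0)
        s = rng.integers(0, 3, size=1000)
        d = DiscreteTrajectory(s, 0.5)
        for lag_frames in (1, 3, 7):
            cr = count_matrix(d, 0.5 * lag_frames)
            expected = np.zeros((3, 3), dtype=int)
            for t in range(len(s) - lag_frames):
                expected[s[t], s[t + lag_frames]] += 1
            assert np.array_equal(cr.counts, expected)

    def test_lag_not_multiple_of_frame_rejected(self):
        d = DiscreteTrajectory([0, 1, 0], 0.3)
        with pytest.raises(ValueError, match="multiple"):
            count_matrix(d, 0.5)

    def test_lag_longer_than_every_trajectory_rejected(self):
        d = DiscreteTrajectory([0, 1], 1.0)
        with pytest.raises(ValueError, match="exceeds"):
            count_matrix(d, 5.0)

    def test_active_set_excludes_disconnected_state(self):
        d1 = DiscreteTrajectory([0, 1, 0, 1, 0], 1.0)
        d2 = DiscreteTrajectory([2, 2, 2], 1.0)
        cr = count_matrix([d1, d2], 1.0)
        assert set(cr.active_set) == {0, 1}


class TestReversibleMLE:
    def test_symmetric_counts_give_row_normalized_matrix(self):
        C = np.array([[10.0, 4.0, 2.0], [4.0, 8.0, 3.0], [2.0, 3.0, 6.0]])
        m = estimate_reversible(C, lag_time=1.0)
        assert np.allclose(m.transition_matrix, C / C.sum(axis=1, keepdims=True),
                           atol=1e-9)

    def test_detailed_balance_and_likelihood(self):
        C = np.array([[90.0, 10.0], [40.0, 60.0]])
        m = estimate_reversible(C, lag_time=1.0)
        pi, T = m.stationary_distribution, m.transition_matrix
        assert np.max(np.abs(pi[:, None] * T - (pi[:, None] * T).T)) < 1e-10
        naive = C / C.sum(axis=1, keepdims=True)  # reversible for 2 states
        assert reversible_log_likelihood(T, C) >= reversible_log_likelihood(naive, C) - 1e-9

    def test_two_state_closed_form_stationary(self):
        # every 2-state chain is reversible, so the constrained MLE equals the
        # row-normalized counts; pi has the standard closed form
        C = np.array([[50.0, 7.0], [13.0, 30.0]])
        m = estimate_reversible(C, lag_time=1.0)
        T = C / C.sum(axis=1, keepdims=True)
        assert np.allclose(m.transition_matrix, T, atol=1e-8)
        pi0 = T[1, 0] / (T[0, 1] + T[1, 0])
        assert np.allclose(m.stationary_distribution, [pi0, 1 - pi0], atol=1e-8)

    def test_disconnected_counts_rejected(self):
        C = np.array([[5.0, 0.0], [0.0, 5.0]])
        with pytest.raises(bk.synthetic.NotIrreducibleError
                           if hasattr(bk.synthetic, "NotIrreducibleError")
                           else Exception):
            estimate_reversible(C, 1.0)

    def test_estimator_facade_exposes_fitted_attributes(self):
        rng = np.random.default_rng(1)
        d = DiscreteTrajectory(rng.integers(0, 3, 2000), 1.0)
        est = bk.MaximumLikelihoodMSM(lag_time=2.0).fit(d)
        assert est.transition_matrix_.shape == (3, 3)
        assert est.stationary_distribution_.sum() == pytest.approx(1.0)
        assert est.eigenvalues_[0] == pytest.approx(1.0)
        assert est.get_params()["lag_time"] == 2.0


class TestMarkovModelInvariants:
    def test_rejects_non_stochastic_rows(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MarkovModel(np.array([[0.9, 0.2], [0.1, 0.9]]), 1.0,
                        np.array([0.5, 0.5]))

    def test_rejects_detailed_balance_violation(self):
        T = np.array([[0.9, 0.1, 0.0], [0.0, 0.9, 0.1], [0.1, 0.0, 0.9]])
        pi = np.full(3, 1 / 3)
        with pytest.raises(ValueError, match="detailed balance"):
            MarkovModel(T, 1.0, pi)

    def test_timescale_formula(self):
        # lambda_2 = exp(-1) at lag 10 ns -> t2 = 10 ns
        lam = np.exp(-1.0)
        T = np.array([[1 - (1 - lam) / 2, (1 - lam) / 2],
                      [(1 - lam) / 2, 1 - (1 - lam) / 2]])
        m = MarkovModel(T, 10.0, np.array([0.5, 0.5]))
        assert m.timescales(1)[0] == pytest.approx(10.0)


class TestImpliedTimescales:
    def test_markov_chain_gives_flat_profile(self):
        rng = np.random.default_rng(2)
        T = np.array([[0.95, 0.05], [0.10, 0.90]])
        # sample the chain exactly at its own lag
        s = np.empty(200_000, dtype=np.int64)
        s[0] = 0
        r = rng.random(len(s))
        for t in range(1, len(s)):
            s[t] = int(r[t] > T[s[t - 1], 0])
        d = DiscreteTrajectory(s, 1.0)
        table = implied_timescales(d, [1.0, 2.0, 4.0, 8.0], n_timescales=1)
        t2 = table["t2"].to_numpy()
        assert np.all(np.abs(t2 / t2[0] - 1.0) < 0.25)

    def test_two_state_ctmc_relaxation_time(self, two_state_net):
        # k = k01 + k10 = 3/ns -> t2 = 1/3 ns
        d = [bk.simulate_ctmc(two_state_net, 3000, 0.05, seed=s) for s in range(4)]
        table = implied_timescales(d, [0.1, 0.2], n_timescales=1)
        assert table["t2"].iloc[-1] == pytest.approx(1 / 3, rel=0.10)

    def test_invariant_under_trajectory_duplication(self):
        rng = np.random.default_rng(4)
        d = DiscreteTrajectory(rng.integers(0, 3, 5000), 1.0)
        a = implied_timescales([d], [1.0, 2.0], n_timescales=2)
        b = implied_timescales([d, d], [1.0, 2.0], n_timescales=2)
        assert np.allclose(a[["t2", "t3"]].to_numpy(), b[["t2", "t3"]].to_numpy(),
                           rtol=1e-8, equal_nan=True)

    def test_negative_eigenvalue_reported_as_nan(self):
        # alternating sequence -> lambda_2 < 0 at lag 1
        d = DiscreteTrajectory([0, 1] * 500, 1.0)
        table = implied_timescales(d, [1.0], n_timescales=1)
        assert np.isnan(table["t2"].iloc[0])


class TestKMeans:
    def _clouds(self, k=4, n=200, seed=0):
        rng = np.random.default_rng(seed)
        centers = rng.uniform(-10, 10, size=(k, 2))
        X = np.concatenate([c + 0.05 * rng.standard_normal((n, 2)) for c in centers])
        return X, np.repeat(np.arange(k), n)

    @pytest.mark.parametrize("init", ["maximin", "kmeans++"])
    def test_separated_clouds_recovered(self, init):
        X, truth = self._clouds()
        dts, centers = cluster_kmeans(X, k=4, seed=1, init=init)
        labels = dts.states
        # relabel-invariant partition equality
        for c in range(4):
            block = labels[truth == c]
            assert len(set(block.tolist())) == 1
        assert len(set(labels.tolist())) == 4

    def test_k_equal_one_gives_global_mean(self):
        X, _ = self._clouds()
        dts, centers = cluster_kmeans(X, k=1, seed=0)
        assert np.allclose(centers[0], X.mean(axis=0))
        assert np.all(dts.states == 0)

    def test_same_seed_identical(self):
        X, _ = self._clouds(seed=5)
        a, ca = cluster_kmeans(X, k=7, seed=3, init="kmeans++")
        b, cb = cluster_kmeans(X, k=7, seed=3, init="kmeans++")
        assert np.array_equal(a.states, b.states)
        assert np.allclose(ca, cb)

    def test_fewer_frames_than_clusters_rejected(self):
        with pytest.raises(ValueError, match="clusters"):
            cluster_kmeans(np.zeros((5, 2)), k=10, seed=0)

    def test_maximin_covers_tiny_far_cluster(self):
        # 10 points at distance ~30 among 50k others must get their own cell
        rng = np.random.default_rng(9)
        X = np.vstack([rng.standard_normal((50_000, 3)),
                       rng.standard_normal((10, 3)) * 0.1 + 30.0])
        dts, _ = cluster_kmeans(X, k=20, seed=0, init="maximin", max_iter=10)
        far_labels = set(dts.states[-10:].tolist())
        assert len(far_labels) >= 1
        assert not far_labels & set(dts.states[:-10].tolist())
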