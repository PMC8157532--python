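"""Tests for MSM estimation, lumping, MFPTs and bootstrap intervals."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from dyndesign import msm as M
from dyndesign.errors import ConnectivityError, ValidationError
from dyndesign.synthetic import (build_canonical_model, expand_to_microstates,
                                 simulate_dtrajs)


def _brute_force_pairs(dtrajs, lag):
    pairs = []
    for d in dtrajs:
        for t in range(len(d) - lag):
            pairs.append((d[t], d[t + lag]))
    return pairs


def _brute_force_scc(adj):
    """Strongly connected components via reachability matrix powers."""
    n = adj.shape[0]
    reach = np.eye(n, dtype=bool) | (adj > 0)
    for _ in range(n):
        reach = reach | (reach @ reach)
    mutual = reach & reach.T
    comps, seen = [], set()
    for i in range(n):
        if i in seen:
            continue
        comp = set(np.where(mutual[i])[0])
        comps.append(sorted(comp))
        seen |= comp
    return comps


class TestCounting:
    def test_alternating_hand_count(self):
        cm = M.count_transitions([np.array([0, 1, 0, 1, 0])], lag=1)
        assert cm.counts.tolist() == [[0, 2], [2, 0]]

    def test_self_transitions_hand_count(self):
        cm = M.count_transitions([np.array([0, 0, 0])], lag=1)
        assert cm.counts[0, 0] == 2 and cm.counts.sum() == 2

    def test_total_counts_match_brute_force(self, rng):
        dtrajs = [rng.integers(0, 3, size=rng.integers(5, 40))
                  for _ in range(6)]
        for lag in (1, 2, 3):
            cm = M.count_transitions(dtrajs, lag=lag)
            pairs = _brute_force_pairs(dtrajs, lag)
            assert cm.counts.sum() == len(pairs)
            expected = sum(max(0, len(d) - lag) for d in dtrajs)
            assert cm.counts.sum() == expected

    def test_strided_mode_subsamples(self):
        cm = M.count_transitions([np.arange(10) % 2], lag=2, mode="strided")
        assert cm.counts.sum() == 4  # pairs at t = 0, 2, 4, 6

    def test_all_short_trajectories_rejected(self):
        with pytest.raises(ValidationError, match="lag"):
            M.count_transitions([np.array([0, 1])], lag=5)


class TestConnectivity:
    def test_fully_connected(self):
        cm = M.CountMatrix(np.ones((4, 4)), 1, "sliding", 16)
        assert M.largest_connected_set(cm).tolist() == [0, 1, 2, 3]

    def test_block_diagonal_picks_larger_block(self):
        C = np.zeros((5, 5))
        C[:3, :3] = 1.0
        C[3:, 3:] = 5.0
        cm = M.CountMatrix(C, 1, "sliding", 0)
        assert M.largest_connected_set(cm).tolist() == [0, 1, 2]

    def test_matches_brute_force_scc(self, rng):
        for _ in range(20):
            C = (rng.random((7, 7)) < 0.25).astype(float)
            if C.sum() == 0:
                continue
            cm = M.CountMatrix(C, 1, "sliding", 0)
            got = M.largest_connected_set(cm).tolist()
            comps = _brute_force_scc(C)
            best = max(comps, key=lambda c: (
                len(c), C[np.ix_(c, c)].sum(), -c[0]))
            assert got == best


class TestReversibleMLE:
    def test_symmetric_two_state(self):
        cm = M.CountMatrix(np.array([[0., 2.], [2., 0.]]), 1, "sliding", 4)
        est = M.estimate_reversible_T(cm)
        assert np.allclose(est.T, [[0, 1], [1, 0]])
        assert np.allclose(est.pi, [0.5, 0.5])

    def test_symmetric_counts_give_row_normalised(self, rng):
        A = rng.random((4, 4)) + 0.1
        C = A + A.T
        est = M.estimate_reversible_T(M.CountMatrix(C, 1, "sliding", 0))
        assert np.allclose(est.T, C / C.sum(axis=1, keepdims=True),
                           atol=1e-8)

    def test_estimate_satisfies_invariants(self, rng):
        C = rng.integers(1, 50, size=(5, 5)).astype(float)
        est = M.estimate_reversible_T(M.CountMatrix(C, 1, "sliding", 0))
        est.validate()  # row-stochastic 1e-10, detailed balance 1e-8

    def test_mle_beats_perturbed_reversible_matrices(self, rng):
        """Likelihood of the MLE exceeds 1000 random detailed-balanced
        perturbations of it."""
        C = rng.integers(1, 30, size=(5, 5)).astype(float)
        est = M.estimate_reversible_T(M.CountMatrix(C, 1, "sliding", 0))
        logmask = C > 0

        def loglik(T):
            return float(np.sum(C[logmask] * np.log(T[logmask])))

        best = loglik(est.T)
        x_star = est.pi[:, None] * est.T
        for _ in range(1000):
            x = x_star * np.exp(rng.normal(0, 0.05, size=(5, 5)))
            x = 0.5 * (x + x.T)  # keep the flux symmetric -> reversible T
            T = x / x.sum(axis=1, keepdims=True)
            assert loglik(T) <= best + 1e-9


@pytest.fixture(scope="module")
def markov_traj():
    model = expand_to_microstates(build_canonical_model("D66A"), 4)
    return model, simulate_dtrajs(model, 20, 8000, seed=55)


class TestValidation:
    def test_implied_timescales_flat_and_ck_small(self, markov_traj):
        model, traj = markov_traj
        its, ck = M.validate_msm(traj.dtrajs, lags=[1, 2, 4], n_macro=5)
        assert its.shape == (3, 5)  # lag column + 4 timescales
        # Markovian input: slowest timescale flat across a lag doubling
        ts = its["ts_1"].to_numpy()
        assert abs(ts[2] - ts[0]) / ts[0] < 0.25
        assert all(dev < 0.02 for dev in ck.values())
        assert set(ck) == {2, 3, 4, 5}

    def test_returns_n_minus_one_timescales(self, markov_traj):
        _, traj = markov_traj
        its, _ = M.validate_msm(traj.dtrajs, lags=[1, 2], n_macro=3,
                                max_ck=2)
        assert list(its.columns) == ["lag", "ts_1", "ts_2"]


class TestClustering:
    def test_k1_all_zero(self, rng):
        labels = M.cluster_features([rng.random((50, 2))], k=1, seed=0)
        assert np.all(labels[0] == 0)

    def test_planted_gaussians_recovered(self, rng):
        centers = np.array([[0, 0], [5, 0], [0, 5], [5, 5]])
        planted = rng.integers(0, 4, size=500)
        X = centers[planted] + 0.1 * rng.standard_normal((500, 2))
        labels = M.cluster_features([X], k=4, seed=1)[0]
        assert adjusted_rand_score(planted, labels) == 1.0

    def test_wcss_non_increasing_in_k(self, rng):
        X = rng.random((200, 2))
        wcss = []
        for k in range(1, 7):
            labels = M.cluster_features([X], k=k, seed=2)[0]
            centers = np.array([X[labels == j].mean(axis=0)
                                for j in range(k)])
            wcss.append(float(np.sum((X - centers[labels]) ** 2)))
        assert all(a >= b - 1e-9 for a, b in zip(wcss, wcss[1:]))

    def test_k_exceeding_frames_rejected(self, rng):
        with pytest.raises(ValidationError, match="frames"):
            M.cluster_features([rng.random((5, 2))], k=10, seed=0)

    def test_preserves_trajectory_boundaries(self, rng):
        parts = [rng.random((30, 2)), rng.random((20, 2))]
        labels = M.cluster_features(parts, k=3, seed=3)
        assert [len(l) for l in labels] == [30, 20]


class TestLumping:
    def test_identity_lumping(self, rng):
        C = rng.integers(1, 20, size=(4, 4)).astype(float)
        est = M.estimate_reversible_T(M.CountMatrix(C, 1, "sliding", 0))
        lump = M.pcca_lump(est, 4)
        assert len(np.unique(lump.membership)) == 4
        assert np.allclose(np.sort(lump.macro_pi), np.sort(est.pi))

    def test_planted_macrostates_recovered(self, wt_micro_model,
                                           wt_traj_small):
        est = M.estimate_reversible_T(
            M.count_transitions(wt_traj_small, lag=1))
        lump = M.pcca_lump(est, 5)
        truth = wt_micro_model.micro_to_macro[est.active_set]
        assert adjusted_rand_score(truth, lump.membership) == 1.0

    def test_ground_state_population_near_41(self, wt_traj_small):
        est = M.estimate_reversible_T(
            M.count_transitions(wt_traj_small, lag=1))
        lump = M.pcca_lump(est, 5)
        assert max(lump.macro_pi) == pytest.approx(0.41, abs=0.08)

    def test_lumping_permutation_invariant(self, wt_traj_small, rng):
        dtrajs = [d.copy() for d in wt_traj_small.dtrajs]
        n = int(max(d.max() for d in dtrajs)) + 1
        perm = rng.permutation(n)
        relabeled = [perm[d] for d in dtrajs]
        lump_a = M.pcca_lump(M.estimate_reversible_T(
            M.count_transitions(dtrajs, 1)), 5, timestep_ns=2000.0)
        lump_b = M.pcca_lump(M.estimate_reversible_T(
            M.count_transitions(relabeled, 1)), 5, timestep_ns=2000.0)
        assert np.allclose(np.sort(lump_a.macro_pi),
                           np.sort(lump_b.macro_pi), atol=1e-8)
        assert np.allclose(np.sort(lump_a.mfpt_matrix, axis=None),
                           np.sort(lump_b.mfpt_matrix, axis=None), rtol=1e-6)


class TestMFPT:
    def test_geometric_escape(self):
        est = M.MSMEstimate(np.array([[0.9, 0.1], [0.1, 0.9]]),
                            np.array([0.5, 0.5]), 1, np.arange(2), 0.0)
        assert M.mfpt(est, [0], [1], timestep_ns=1.0) == \
            pytest.approx(10.0 * 1e-6)  # 10 steps at 1 ns, in ms

    def test_linear_solve_matches_monte_carlo(self, wt_macro_model, rng):
        """Linear-solve MFPT equals the mean of simulated first passages."""
        model = wt_macro_model
        T = model.macro_T()
        est = M.MSMEstimate(T, model.macro_pi, 1, np.arange(5), 0.0)
        solve = M.mfpt(est, [0, 1], [3, 4], model.timestep_ns)

        n_walk = 5000
        cum = np.cumsum(T, axis=1)
        start_w = model.macro_pi[:2] / model.macro_pi[:2].sum()
        states = rng.choice(2, size=n_walk, p=start_w)
        steps = np.zeros(n_walk)
        alive = np.ones(n_walk, dtype=bool)
        for _ in range(200_000):
            u = rng.random(alive.sum())
            states[alive] = (cum[states[alive]] < u[:, None]).sum(axis=1)
            steps[alive] += 1
            alive &= ~np.isin(states, [3, 4])
            if not alive.any():
                break
        assert not alive.any()
        mc = steps.mean() * model.timestep_ns * 1e-6
        se = steps.std(ddof=1) / np.sqrt(n_walk) * model.timestep_ns * 1e-6
        assert abs(solve - mc) < 3.0 * se

    def test_unreachable_target_rejected(self):
        T = np.array([[1.0, 0.0], [0.5, 0.5]])
        est = M.MSMEstimate(T, np.array([1.0, 0.0]), 1, np.arange(2), 0.0)
        est_ok = M.MSMEstimate.__new__(M.MSMEstimate)  # bypass validate
        est_ok.__dict__.update(est.__dict__)
        with pytest.raises(ConnectivityError):
            M.mfpt(est_ok, [0], [1])

    def test_overlapping_sets_rejected(self, wt_macro_model):
        est = M.MSMEstimate(wt_macro_model.macro_T(), wt_macro_model.macro_pi,
                            1, np.arange(5), 0.0)
        with pytest.raises(ValidationError, match="disjoint"):
            M.mfpt(est, [0, 1], [1, 2])


class TestBootstrap:
    def test_single_trajectory_zero_width(self, wt_micro_model):
        traj = simulate_dtrajs(wt_micro_model, 1, 6000, seed=21)
        boot = M.bootstrap_msm(traj.dtrajs, lag=1, n_macro=5, n_boot=20,
                               seed=0, timestep_ns=2000.0)
        level, lo, hi = boot.ci["macro_pi"]
        assert np.allclose(lo, hi)

    def test_seed_reproducibility(self, wt_traj_small):
        a = M.bootstrap_msm(wt_traj_small, 1, 5, n_boot=15, seed=4,
                            timestep_ns=2000.0)
        b = M.bootstrap_msm(wt_traj_small, 1, 5, n_boot=15, seed=4,
                            timestep_ns=2000.0)
        assert np.allclose(a.ci["macro_pi"][1], b.ci["macro_pi"][1])
        assert np.allclose(a.ci["mfpt"][2], b.ci["mfpt"][2])

    def test_interval_coverage(self):
        """80% bootstrap CIs cover the true ground-state population in
        40 +/- 7 of 50 regenerated datasets (binomial 3 sigma)."""
        model = expand_to_microstates(build_canonical_model("D66A"), 4)
        truth = model.macro_pi
        hits = 0
        for i in range(50):
            traj = simulate_dtrajs(model, 25, 1500, seed=1000 + i)
            boot = M.bootstrap_msm(traj.dtrajs, 1, 5, n_boot=40, level=0.80,
                                   seed=i, timestep_ns=model.timestep_ns)
            # align estimated macrostates to truth by membership majority
            memb_truth = model.micro_to_macro[
                M.estimate_reversible_T(
                    M.count_transitions(traj.dtrajs, 1)).active_set]
            level, lo, hi = boot.ci["macro_pi"]
            k_est = next(
                a for a in range(5)
                if np.bincount(memb_truth[boot.membership == a],
                               minlength=5).argmax() == 2)
            if lo[k_est] - 1e-12 <= truth[2] <= hi[k_est] + 1e-12:
                hits += 1
        assert 33 <= hits <= 47
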