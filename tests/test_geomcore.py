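import itertools

import numpy as np
import pytest

from dyncore.errors import ConfigError, DataFormatError
from dyncore.geomcore import (
    AnnealSchedule,
    CoreScoreProfile,
    TransitionParams,
    anneal_assignment,
    core_quality,
    core_score_summary,
    core_scores,
    rscore_landscape,
    transition_vector,
)
from dyncore.geomcore import _normalized_transition
from dyncore.synth import SyntheticConfig, generate_adjacency_tensor

FAST = AnnealSchedule.fast()


class TestTransitionVector:
    def test_alpha_one_is_binary(self):
        C = transition_vector(8, TransitionParams(1.0, 0.5))
        np.testing.assert_array_equal(C[:4], 0.0)
        np.testing.assert_array_equal(C[4:], 1.0)

    def test_derived_example_n10(self):
        C = transition_vector(10, TransitionParams(0.0, 0.5))
        np.testing.assert_allclose(C, np.arange(1, 11) / 10.0, atol=1e-12)

    def test_alpha_zero_fuzziest_boundary(self):
        C = transition_vector(10, TransitionParams(0.0, 0.5))
        jumps = np.diff(C)
        assert jumps.max() == pytest.approx(jumps.min(), abs=1e-12)

    def test_monotone_nondecreasing_max_one(self):
        for alpha in (0.0, 0.3, 0.7, 1.0):
            for beta in (0.0, 0.2, 0.5, 0.9, 1.0):
                C = transition_vector(12, TransitionParams(alpha, beta))
                assert np.all(np.diff(C) >= -1e-12)
                assert C.max() <= 1.0 + 1e-12
                assert C.min() >= 0.0

    def test_invalid_params(self):
        with pytest.raises(ConfigError):
            TransitionParams(1.5, 0.5)


class TestCoreQuality:
    def test_two_node_hand_formula(self):
        w = 0.7
        A = np.array([[0.0, w], [w, 0.0]])
        params = TransitionParams(0.4, 0.5)
        c = _normalized_transition(2, params)
        assert core_quality(A, np.array([0, 1]), params) == pytest.approx(
            2.0 * w * c[0] * c[1], abs=1e-12
        )

    def test_empty_graph_zero(self):
        A = np.zeros((5, 5))
        assert core_quality(A, np.arange(5), TransitionParams(0.5, 0.5)) == 0.0

    def test_joint_relabelling_invariance(self, rng):
        A = rng.random((6, 6))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        params = TransitionParams(0.5, 0.5)
        order = rng.permutation(6)
        perm = rng.permutation(6)  # node relabelling
        A2 = A[np.ix_(perm, perm)]
        inv = np.empty(6, dtype=int)
        inv[perm] = np.arange(6)
        order2 = inv[order]
        assert core_quality(A, order, params) == pytest.approx(
            core_quality(A2, order2, params), abs=1e-12
        )

    def test_asymmetric_rejected(self, rng):
        with pytest.raises(DataFormatError):
            core_quality(rng.random((4, 4)), np.arange(4), TransitionParams(0.5, 0.5))


class TestAnnealing:
    def test_beats_degree_ranked_start(self, rng):
        A = rng.random((12, 12))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        params = TransitionParams(0.5, 0.6)
        degree_order = np.argsort(A.sum(axis=0), kind="stable")
        base = core_quality(A, degree_order, params)
        a = anneal_assignment(A, params, FAST, n_restarts=2, seed=0)
        assert a.R >= base - 1e-12

    def test_best_of_k_monotone(self, rng):
        A = rng.random((10, 10))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        params = TransitionParams(0.5, 0.5)
        r_values = [anneal_assignment(A, params, FAST, n_restarts=k, seed=9).R
                    for k in (1, 3, 5)]
        assert r_values[0] <= r_values[1] + 1e-12 <= r_values[2] + 2e-12

    def test_matches_exhaustive_small_n(self, rng):
        hits = 0
        for rep in range(20):
            A = rng.random((6, 6))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0)
            params = TransitionParams(0.5, 0.5)
            C = _normalized_transition(6, params)
            best = -np.inf
            for perm in itertools.permutations(range(6)):
                v = np.empty(6)
                v[list(perm)] = C
                best = max(best, float(v @ A @ v))
            a = anneal_assignment(A, params, FAST, n_restarts=3, seed=rep)
            hits += abs(a.R - best) < 1e-9
        assert hits >= 19  # >= 95% of instances

    def test_star_hub_gets_top_value(self):
        A = np.zeros((6, 6))
        A[0, 1:] = A[1:, 0] = 0.9  # dominant hub node 0
        a = anneal_assignment(A, TransitionParams(0.5, 0.8), FAST, n_restarts=3, seed=1)
        assert a.local_values[0] == pytest.approx(a.local_values.max())

    def test_planted_core_recovery(self):
        hits = 0
        for seed in range(10):
            cfg = SyntheticConfig(n_regions=30, n_layers=2, core_fraction=0.2,
                                  periphery_fraction=0.8, seed=seed)
            tensor, truth = generate_adjacency_tensor(cfg, block_params=(0.9, 0.4, 0.05))
            a = anneal_assignment(tensor.weights[:, :, 0], TransitionParams(0.5, 0.8),
                                  FAST, n_restarts=3, seed=seed)
            top = set(a.permutation[-6:].tolist())
            hits += top == set(truth.planted_core_nodes.tolist())
        assert hits >= 9

    def test_determinism(self, rng):
        A = rng.random((8, 8))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        params = TransitionParams(0.4, 0.6)
        a1 = anneal_assignment(A, params, FAST, n_restarts=2, seed=11)
        a2 = anneal_assignment(A, params, FAST, n_restarts=2, seed=11)
        assert a1.R == a2.R
        np.testing.assert_array_equal(a1.permutation, a2.permutation)


class TestLandscape:
    def test_output_shape_and_argmax(self, rng):
        A = rng.random((10, 10))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        alphas = np.linspace(0, 1, 4)
        betas = np.linspace(0, 1, 5)
        R, best = rscore_landscape(A, alphas, betas, FAST, seed=0)
        assert R.shape == (4, 5)
        i, j = np.unravel_index(np.argmax(R), R.shape)
        assert best.alpha == pytest.approx(alphas[i])
        assert best.beta == pytest.approx(betas[j])

    def test_planted_core_fraction_recovered(self):
        # planted core fraction 0.15 -> argmax beta near 0.85 (low-segment
        # boundary-fraction convention)
        betas = []
        for seed in range(5):
            cfg = SyntheticConfig(n_regions=40, n_layers=2, core_fraction=0.15,
                                  periphery_fraction=0.85, seed=seed)
            tensor, _ = generate_adjacency_tensor(cfg, block_params=(0.9, 0.3, 0.05))
            _, best = rscore_landscape(tensor.weights[:, :, 0],
                                       np.array([0.5]), np.linspace(0.5, 0.95, 10),
                                       FAST, seed=seed)
            betas.append(best.beta)
        assert abs(np.mean(betas) - 0.85) < 0.1

    def test_grid_outside_unit_square_rejected(self, rng):
        A = np.zeros((4, 4))
        with pytest.raises(ConfigError):
            rscore_landscape(A, np.array([0.5, 1.2]), np.array([0.5]), FAST)


class TestCoreScores:
    def test_normalized_max_one(self, rng):
        A = rng.random((10, 10))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        profile = core_scores(A, 0.5, 0.7, FAST, n_restarts=2, seed=0)
        assert profile.scores.max() == pytest.approx(1.0)
        assert profile.scores.min() >= 0.0

    def test_planted_gap(self):
        gaps = []
        for seed in range(5):
            cfg = SyntheticConfig(n_regions=30, n_layers=2, core_fraction=0.2,
                                  periphery_fraction=0.8, seed=seed)
            tensor, truth = generate_adjacency_tensor(cfg, block_params=(0.9, 0.4, 0.05))
            profile = core_scores(tensor.weights[:, :, 0], 0.5, 0.8, FAST,
                                  n_restarts=2, seed=seed)
            gaps.append(profile.scores[truth.planted_core_nodes].mean()
                        - profile.scores[truth.planted_periphery_nodes].mean())
        assert np.mean(gaps) > 0

    def test_aggregate_mode_runs(self, rng):
        A = rng.random((8, 8))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        profile = core_scores(A, 0.5, 0.7, FAST, n_restarts=1, seed=0,
                              mode="aggregate", alphas=np.array([0.3, 0.7]),
                              betas=np.array([0.5, 0.8]))
        assert profile.scores.max() == pytest.approx(1.0)

    def test_minority_core_shape(self):
        # a minority of nodes carry high scores; the majority sit near
        # periphery-level values
        cfg = SyntheticConfig(n_regions=40, n_layers=2, core_fraction=0.15,
                              periphery_fraction=0.85, seed=3)
        tensor, _ = generate_adjacency_tensor(cfg, block_params=(0.9, 0.3, 0.05))
        profile = core_scores(tensor.weights[:, :, 0], 0.5, 0.85, FAST,
                              n_restarts=2, seed=0)
        assert (profile.scores > 0.6).sum() <= 12
        assert (profile.scores < 0.4).sum() >= 20


class TestSummary:
    def test_identical_profiles(self, rng):
        scores = rng.random(10)
        scores[0] = 1.0
        p = CoreScoreProfile(scores=scores, alpha_used=0.5, beta_used=0.8,
                             R_best=1.0, n_restarts=1)
        mean, var = core_score_summary([p, p, p])
        np.testing.assert_allclose(mean, scores)
        assert var == pytest.approx(scores.var())

    def test_all_equal_scores_zero_variance(self):
        p = CoreScoreProfile(scores=np.ones(5), alpha_used=0.5, beta_used=0.8,
                             R_best=1.0, n_restarts=1)
        _, var = core_score_summary([p])
        assert var == 0.0

    def test_shuffled_scores_variance_shrinks(self, rng):
        base = rng.random(20)
        many = [CoreScoreProfile(scores=rng.permutation(base), alpha_used=0.5,
                                 beta_used=0.8, R_best=1.0, n_restarts=1)
                for _ in range(50)]
        _, var_many = core_score_summary(many)
        _, var_one = core_score_summary(many[:1])
        assert var_many < var_one / 5

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            core_score_summary([])
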