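"""Neighbor distributions and the KL embedding loss against hand oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurotsne import (
    NeighborDistribution,
    PerplexitySpec,
    RankSpec,
    gaussian_neighbor_probs,
    kl_loss,
    kl_loss_grad_y,
    pairwise_sq_distances,
    rank_neighbor_probs,
    student_t_probs,
)


class TestPairwiseSqDistances:
    def test_two_points_distance_three(self):
        d2 = pairwise_sq_distances(np.array([[0.0, 0.0], [0.0, 3.0]]))
        assert np.allclose(d2, [[0, 9], [9, 0]])

    def test_identical_rows_all_zero(self):
        d2 = pairwise_sq_distances(np.ones((4, 3)))
        assert np.allclose(d2, 0.0)

    def test_matches_double_loop(self, rng):
        X = rng.standard_normal((5, 4))
        d2 = pairwise_sq_distances(X)
        brute = np.array(
            [[np.sum((a - b) ** 2) for b in X] for a in X]
        )
        assert np.allclose(d2, brute, atol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            pairwise_sq_distances(np.array([[0.0, np.nan], [1.0, 2.0]]))


class TestRankNeighborProbs:
    def test_four_collinear_points_hand_enumeration(self):
        Z = np.array([[0.0], [1.0], [3.0], [7.0]])
        P = rank_neighbor_probs(Z, RankSpec(n_neighbors=1, low_mass_fraction=0.01))
        lo, hi = 0.005, 0.99
        cond = np.array(
            [
                [0.0, hi, lo, lo],  # nearest to 0 is 1
                [hi, 0.0, lo, lo],  # nearest to 1 is 0
                [lo, hi, 0.0, lo],  # nearest to 3 is 1
                [lo, lo, hi, 0.0],  # nearest to 7 is 3
            ]
        )
        expected = (cond + cond.T) / 8.0
        assert np.allclose(P.probs, expected, atol=1e-15)

    def test_all_equidistant_tie_broken_by_index(self):
        # 4 vertices of a regular simplex in 3-D: every pair equidistant
        Z = np.eye(4)[:, :4]
        P = rank_neighbor_probs(Z, RankSpec(n_neighbors=2))
        assert P.probs.sum() == pytest.approx(1.0, abs=1e-12)
        # row 0's neighbors must be the two smallest indices 1, 2
        cond_high = (1 - 0.01) / 2 / (2 * 4)
        assert P.probs[0, 1] >= cond_high and P.probs[0, 2] >= cond_high

    def test_monotone_transform_invariance(self, rng):
        Z = rng.standard_normal((20, 5))
        a = rank_neighbor_probs(Z, RankSpec(3)).probs
        b = rank_neighbor_probs(7.0 * Z, RankSpec(3)).probs
        assert np.array_equal(a, b)

    def test_batch_too_small_raises(self):
        with pytest.raises(ValueError, match="n_neighbors"):
            rank_neighbor_probs(np.zeros((4, 2)), RankSpec(n_neighbors=3))

    def test_conditional_rows_have_exactly_n_high_entries(self, rng):
        spec = RankSpec(n_neighbors=5, symmetrize=False)
        Z = rng.standard_normal((50, 7))
        P = rank_neighbor_probs(Z, spec)
        cond = P.probs * 50  # undo joint normalization of conditionals
        low = spec.low_mass_fraction / (50 - 1 - 5)
        n_high = np.sum(cond > low * 1.5, axis=1)
        assert np.all(n_high == 5)


class TestGaussianNeighborProbs:
    @pytest.mark.parametrize("perplexity", [2.0, 5.0, 30.0])
    def test_achieved_perplexity_per_row(self, rng, perplexity):
        from neurotsne.objective import gaussian_conditionals

        X = rng.standard_normal((100, 10))
        cond = gaussian_conditionals(X, PerplexitySpec(perplexity=perplexity))
        assert np.allclose(cond.sum(axis=1), 1.0, atol=1e-12)
        # recompute 2**H from the returned conditionals, row by row
        for i in range(100):
            p = cond[i][cond[i] > 0]
            achieved = 2.0 ** (-np.sum(p * np.log2(p)))
            assert achieved == pytest.approx(perplexity, abs=1e-3)

    def test_joint_matrix_normalized(self, rng):
        X = rng.standard_normal((100, 4))
        P = gaussian_neighbor_probs(X, PerplexitySpec(perplexity=5.0))
        assert P.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(np.diag(P.probs), 0.0)

    def test_three_equidistant_points_uniform(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        P = gaussian_neighbor_probs(X, PerplexitySpec(perplexity=2.0))
        assert np.allclose(P.probs[P.probs > 0], 1.0 / 6.0, atol=1e-9)


class TestStudentTProbs:
    def test_two_points_always_half(self):
        for d in (0.1, 1.0, 100.0):
            Q = student_t_probs(np.array([[0.0, 0.0], [d, 0.0]]))
            assert np.allclose(Q.probs, [[0, 0.5], [0.5, 0]])

    def test_coincident_pair_plus_one(self):
        Y = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        Q = student_t_probs(Y)
        expected = np.array(
            [[0.0, 0.25, 0.125], [0.25, 0.0, 0.125], [0.125, 0.125, 0.0]]
        )
        assert np.allclose(Q.probs, expected, atol=1e-15)

    def test_equilateral_triangle_uniform(self):
        Y = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        Q = student_t_probs(Y)
        assert np.allclose(Q.probs[~np.eye(3, dtype=bool)], 1.0 / 6.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            student_t_probs(np.array([[0.0, np.inf], [1.0, 0.0]]))


class TestKlLoss:
    def test_identical_distributions_zero(self, rng):
        Y = rng.standard_normal((6, 2))
        Q = student_t_probs(Y)
        assert kl_loss(Q, Q) == pytest.approx(0.0, abs=1e-15)

    def test_two_point_hand_value(self):
        P = NeighborDistribution(np.array([[0.0, 0.5], [0.5, 0.0]]), "rank")
        Q = NeighborDistribution(np.array([[0.0, 0.4], [0.6, 0.0]]), "student_t")
        expected = 0.5 * np.log(0.5 / 0.4) + 0.5 * np.log(0.5 / 0.6)
        assert kl_loss(P, Q) == pytest.approx(expected, abs=1e-15)

    def test_matches_double_loop_brute_force(self, rng):
        P = rank_neighbor_probs(rng.standard_normal((6, 3)), RankSpec(2))
        Q = student_t_probs(rng.standard_normal((6, 2)))
        brute = 0.0
        for i in range(6):
            for j in range(6):
                if i != j and P.probs[i, j] > 0:
                    brute += P.probs[i, j] * np.log(
                        P.probs[i, j] / max(Q.probs[i, j], 1e-12)
                    )
        assert kl_loss(P, Q) == pytest.approx(brute, abs=1e-12)

    def test_positive_when_distributions_differ(self, rng):
        P = rank_neighbor_probs(rng.standard_normal((10, 3)), RankSpec(2))
        Q = student_t_probs(rng.standard_normal((10, 2)))
        assert kl_loss(P, Q) > 0

    def test_shape_mismatch_raises(self):
        P = NeighborDistribution(np.zeros((3, 3)), "rank")
        Q = NeighborDistribution(np.zeros((4, 4)), "student_t")
        with pytest.raises(ValueError):
            kl_loss(P, Q)

    def test_analytic_gradient_matches_finite_differences(self, rng):
        Y = rng.standard_normal((7, 2))
        P = rank_neighbor_probs(rng.standard_normal((7, 4)), RankSpec(3))
        _, grad = kl_loss_grad_y(P, Y)
        eps = 1e-6
        for i in range(7):
            for j in range(2):
                Yp, Ym = Y.copy(), Y.copy()
                Yp[i, j] += eps
                Ym[i, j] -= eps
                num = (
                    kl_loss(P, student_t_probs(Yp)) - kl_loss(P, student_t_probs(Ym))
                ) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-7)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    b=st.sampled_from([3, 10, 100]),
    seed=st.integers(min_value=0, max_value=10_000),
    kind=st.sampled_from(["rank", "gaussian", "student_t"]),
)
def test_distributions_sum_to_one_with_zero_diagonal(b, seed, kind):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((b, 4))
    if kind == "rank":
        if b <= 3:
            return
        dist = rank_neighbor_probs(X, RankSpec(n_neighbors=min(5, b - 2)))
    elif kind == "gaussian":
        dist = gaussian_neighbor_probs(X, PerplexitySpec(perplexity=min(5.0, b - 1)))
    else:
        dist = student_t_probs(rng.standard_normal((b, 2)))
    assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(np.diag(dist.probs), 0.0)
    assert np.all(dist.probs >= 0)
    if kind in ("rank", "student_t"):
        assert np.allclose(dist.probs, dist.probs.T)
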