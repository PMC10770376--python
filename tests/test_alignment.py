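import itertools

import numpy as np
import pytest

from gspgcn.alignment import (
    align_graphs,
    build_prior,
    extract_permutation,
    ineat_objective,
    kronecker_fixed_point,
    matching_objective,
    reorganize_channels,
    row_normalize,
)
from gspgcn.connectivity import knn_graph, pcc_matrix
from gspgcn.containers import EpochSet
from gspgcn.errors import InvalidArgumentError

from conftest import random_adjacency


def _perm_matrix(perm):
    n = len(perm)
    P = np.zeros((n, n))
    P[np.arange(n), perm] = 1.0
    return P


class TestMatchingObjective:
    def test_exact_isomorphism_scores_zero(self):
        rng = np.random.default_rng(0)
        A1 = random_adjacency(rng, 5)
        P = _perm_matrix([2, 0, 4, 1, 3])
        A2 = P.T @ A1 @ P
        assert matching_objective(P, A1, A2) == pytest.approx(0.0, abs=1e-12)

    def test_identity_on_equal_graphs(self):
        A = random_adjacency(np.random.default_rng(1), 4)
        assert matching_objective(np.eye(4), A, A) == pytest.approx(0.0)

    def test_brute_force_minimum_found_by_enumeration(self):
        """The objective at the exhaustive argmin permutation lower-bounds
        all other permutations (n = 4, all 24 candidates)."""
        rng = np.random.default_rng(2)
        A1, A2 = random_adjacency(rng, 4), random_adjacency(rng, 4)
        values = {
            perm: matching_objective(_perm_matrix(perm), A1, A2)
            for perm in itertools.permutations(range(4))
        }
        best = min(values, key=values.get)
        assert all(values[best] <= v + 1e-12 for v in values.values())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            matching_objective(np.eye(3), np.zeros((4, 4)), np.zeros((3, 3)))


class TestPrior:
    def test_identical_group_means_give_dominant_diagonal(self):
        A = random_adjacency(np.random.default_rng(3), 4)
        H, h = build_prior(A, A)
        for i in range(4):
            assert H[i, i] >= H[i].max() - 1e-12
        assert h.sum() == pytest.approx(1.0)

    def test_orthogonal_rows_give_zero_entry(self):
        A0 = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        A1 = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        # row 0 of A0 = e1; row 1 of A1 = 0 -> cosine 0 -> sin(0) = 0
        H, _ = build_prior(A0, A1)
        assert H[0, 1] == 0.0

    def test_normalised_to_unit_sum(self):
        rng = np.random.default_rng(4)
        H, h = build_prior(random_adjacency(rng, 5), random_adjacency(rng, 5))
        assert H.sum() == pytest.approx(1.0)
        assert (h >= 0).all()

    def test_all_zero_means_fall_back_to_uniform(self):
        with pytest.warns(UserWarning):
            H, _ = build_prior(np.zeros((3, 3)), np.zeros((3, 3)))
        assert np.allclose(H, 1.0 / 9.0)


class TestKroneckerFixedPoint:
    def test_alpha_zero_returns_prior(self):
        rng = np.random.default_rng(5)
        A1, A2 = random_adjacency(rng, 3), random_adjacency(rng, 3)
        h = rng.random(9)
        s, info = kronecker_fixed_point(A1, A2, h, alpha=0.0)
        assert np.array_equal(s, h)

    def test_matches_dense_linear_solve(self):
        """Oracle: the 9 x 9 system (I - alpha A1 (x) A2) s = (1-alpha) h
        solved densely."""
        rng = np.random.default_rng(6)
        A1, A2 = random_adjacency(rng, 3), random_adjacency(rng, 3)
        h = rng.random(9)
        h /= h.sum()
        s, _ = kronecker_fixed_point(A1, A2, h, alpha=0.5, tol=1e-12)
        K = np.kron(row_normalize(A1), row_normalize(A2))
        s_direct = np.linalg.solve(np.eye(9) - 0.5 * K, 0.5 * h)
        assert np.abs(s - s_direct).max() < 1e-8

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_dense_solve_equivalence_all_small_sizes(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(3):
            A1, A2 = random_adjacency(rng, n), random_adjacency(rng, n)
            h = rng.random(n * n)
            s, _ = kronecker_fixed_point(A1, A2, h, alpha=0.3, tol=1e-12)
            K = np.kron(row_normalize(A1), row_normalize(A2))
            s_direct = np.linalg.solve(np.eye(n * n) - 0.3 * K, 0.7 * h)
            assert np.abs(s - s_direct).max() < 1e-8

    def test_nonnegativity_preserved(self):
        rng = np.random.default_rng(7)
        A1, A2 = random_adjacency(rng, 4), random_adjacency(rng, 4)
        s, _ = kronecker_fixed_point(A1, A2, rng.random(16), alpha=0.8)
        assert (s >= 0).all()


class TestIneatObjective:
    def test_zero_for_prior_solution_on_empty_graphs(self):
        h = np.random.default_rng(8).random(9)
        assert ineat_objective(h, np.zeros((3, 3)), np.zeros((3, 3)), h) == 0.0

    def test_nonnegative_quadratic_form(self):
        """D - A1 (x) A2 is the Laplacian of the Kronecker graph, hence PSD:
        the alpha-term is nonnegative for any s (checked on 3 x 3 toys)."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            A1, A2 = random_adjacency(rng, 3), random_adjacency(rng, 3)
            s = rng.standard_normal(9)
            val = ineat_objective(s, A1, A2, np.zeros(9), alpha=1.0 - 1e-12)
            assert val >= -1e-9

    def test_fixed_point_improves_on_prior(self):
        rng = np.random.default_rng(10)
        better = 0
        for _ in range(10):
            A1 = row_normalize(random_adjacency(rng, 3))
            A2 = row_normalize(random_adjacency(rng, 3))
            h = rng.random(9)
            h /= h.sum()
            s, _ = kronecker_fixed_point(A1, A2, h, alpha=0.5, normalize=False)
            f_s = ineat_objective(s, A1, A2, h, alpha=0.5)
            f_h = ineat_objective(h, A1, A2, h, alpha=0.5)
            if f_s <= f_h + 1e-12:
                better += 1
        assert better >= 8  # descent sanity on the large majority of toys


class TestExtractPermutation:
    def test_identity(self):
        assert np.array_equal(extract_permutation(np.eye(4)), np.eye(4))

    def test_permutation_matrix_recovered(self):
        P = _perm_matrix([3, 1, 0, 2])
        assert np.array_equal(extract_permutation(P), P)

    def test_matches_brute_force_assignment(self):
        rng = np.random.default_rng(11)
        S = rng.random((5, 5))
        P = extract_permutation(S)
        score = float((S * P).sum())
        best = max(
            sum(S[i, p[i]] for i in range(5))
            for p in itertools.permutations(range(5))
        )
        assert score == pytest.approx(best)


class TestReorganize:
    def test_identity_permutation_is_noop(self, small_cohort):
        _, sets, _ = small_cohort
        out = reorganize_channels(sets[0], np.eye(64))
        assert np.array_equal(out.data, sets[0].data)

    def test_round_trip(self):
        rng = np.random.default_rng(12)
        W = random_adjacency(rng, 6)
        P = _perm_matrix([2, 0, 1, 5, 3, 4])
        back = reorganize_channels(reorganize_channels(W, P), P.T)
        assert np.allclose(back, W)

    def test_commutes_with_connectivity(self):
        """Connectivity of permuted epochs equals permuted connectivity."""
        rng = np.random.default_rng(13)
        data = rng.standard_normal((3, 6, 120))
        es = EpochSet(data, 1000.0, (-20.0, 100.0))
        P = _perm_matrix([5, 3, 0, 1, 4, 2])
        W_then_P = reorganize_channels(pcc_matrix(es), P)
        P_then_W = pcc_matrix(reorganize_channels(es, P))
        assert np.abs(W_then_P - P_then_W).max() < 1e-10


def test_self_alignment_returns_identity():
    """Aligning a graph pair whose group means coincide (diagonal-dominant
    prior) returns the identity reorganisation."""
    rng = np.random.default_rng(14)
    W = random_adjacency(rng, 8)
    A1, A2 = knn_graph(W, 1), knn_graph(W, 5)
    _, h = build_prior(A2, A2)
    res = align_graphs(A1, A2, h, alpha=0.5)
    assert np.array_equal(res.P, np.eye(8))
    assert res.residual <= 1e-8
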