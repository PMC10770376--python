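import itertools

import numpy as np
import pytest

from gspgcn.chebnet import (
    ChebGCN,
    auc_rank,
    cheb_filter,
    coarsen,
    compare_models,
    cross_entropy,
    cross_validate,
    evaluate,
    graph_fourier,
    inverse_fourier,
    laplacian,
    prepare_subject,
    spectrum,
    train_model,
)
from gspgcn.errors import InvalidArgumentError

from conftest import random_adjacency


class TestLaplacian:
    def test_triangle_combinatorial(self):
        A = np.ones((3, 3)) - np.eye(3)
        L = laplacian(A, normalized=False)
        assert np.allclose(np.diag(L), 2.0)
        assert np.allclose(L - np.diag(np.diag(L)), -(np.ones((3, 3)) - np.eye(3)))

    def test_combinatorial_row_sums_zero(self):
        A = random_adjacency(np.random.default_rng(0), 7)
        L = laplacian(A, normalized=False)
        assert np.abs(L.sum(axis=1)).max() < 1e-12

    def test_path_graph_normalized_eigenvalues(self):
        A = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        sp = spectrum(A)
        assert np.allclose(sp.eigenvalues, [0.0, 1.0, 2.0], atol=1e-10)

    def test_normalized_eigenvalues_in_0_2(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            sp = spectrum(random_adjacency(rng, 8))
            assert sp.eigenvalues.min() >= -1e-10
            assert sp.eigenvalues.max() <= 2.0 + 1e-10

    def test_asymmetric_rejected(self):
        A = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(InvalidArgumentError):
            laplacian(A)

    def test_orthonormal_eigenbasis(self):
        sp = spectrum(random_adjacency(np.random.default_rng(2), 6))
        assert np.linalg.norm(sp.U.T @ sp.U - np.eye(6)) < 1e-8


class TestFourier:
    def test_eigenvector_maps_to_unit_coordinate(self):
        sp = spectrum(random_adjacency(np.random.default_rng(3), 5))
        chi = graph_fourier(sp.U[:, 0], sp.U)
        e0 = np.zeros(5)
        e0[0] = 1.0
        assert np.allclose(chi, e0, atol=1e-10)

    def test_round_trip_and_parseval(self):
        rng = np.random.default_rng(4)
        sp = spectrum(random_adjacency(rng, 6))
        x = rng.standard_normal(6)
        chi = graph_fourier(x, sp.U)
        assert np.allclose(inverse_fourier(chi, sp.U), x, atol=1e-10)
        assert np.linalg.norm(chi) == pytest.approx(np.linalg.norm(x))


class TestChebFilter:
    def test_order_one_is_scaling(self):
        sp = spectrum(random_adjacency(np.random.default_rng(5), 4))
        x = np.arange(4.0)
        assert np.allclose(cheb_filter(x, sp.L_scaled, [0.7]), 0.7 * x)

    def test_theta_e1_applies_scaled_laplacian(self):
        sp = spectrum(random_adjacency(np.random.default_rng(6), 5))
        x = np.random.default_rng(7).standard_normal(5)
        y = cheb_filter(x, sp.L_scaled, [0.0, 1.0])
        assert np.allclose(y, sp.L_scaled @ x, atol=1e-12)

    def test_recursion_matches_spectral_evaluation_on_random_graphs(self):
        """Oracle: y = U g(Lambda) U^T x with g evaluated on the scaled
        eigenvalues — 50 random graphs, K up to 5, agreement to 1e-8."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(4, 11))
            K = int(rng.integers(1, 6))
            A = random_adjacency(rng, n)
            sp = spectrum(A)
            theta = rng.standard_normal(K)
            x = rng.standard_normal(n)
            lam_s = 2.0 * sp.eigenvalues / sp.eigenvalues[-1] - 1.0
            g = sum(
                theta[k] * np.cos(k * np.arccos(np.clip(lam_s, -1.0, 1.0)))
                for k in range(K)
            )
            oracle = sp.U @ (g * (sp.U.T @ x))
            got = cheb_filter(x, sp.L_scaled, theta)
            assert np.abs(got - oracle).max() < 1e-8

    def test_empty_theta_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cheb_filter(np.zeros(3), np.eye(3), [])


class TestArchitecture:
    @pytest.mark.parametrize("K1,K2", list(itertools.product(range(1, 6), repeat=2)))
    def test_parameter_counts_match_formulas(self, K1, K2):
        model = ChebGCN(K1=K1, K2=K2, M=2)
        counts = model.param_counts()
        assert counts["conv1"] == 4096 * K1 + 64
        assert counts["conv2"] == 2048 * K2 + 32
        assert counts["fc"] == 1056

    def test_fully_connected_is_1056(self):
        assert ChebGCN().param_counts()["fc"] == 1056

    def test_invalid_dims_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ChebGCN(K1=0)
        with pytest.raises(InvalidArgumentError):
            ChebGCN(M=1)


class TestCoarsen:
    def test_halves_node_count(self):
        A = random_adjacency(np.random.default_rng(9), 8)
        A2, C = coarsen(A)
        assert A2.shape == (4, 4)
        assert C.shape == (4, 8)
        assert np.allclose(C.sum(axis=1), 1.0)  # mean pooling rows

    def test_pooled_graph_symmetric_zero_diagonal(self):
        A = random_adjacency(np.random.default_rng(10), 10)
        A2, _ = coarsen(A)
        assert np.allclose(A2, A2.T)
        assert np.allclose(np.diag(A2), 0.0)

    def test_every_node_assigned_once(self):
        A = random_adjacency(np.random.default_rng(11), 12)
        _, C = coarsen(A)
        assert np.allclose((C > 0).sum(axis=0), 1)


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        assert cross_entropy([1], [[0.0, 1.0]]) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_prediction_is_ln2(self):
        assert cross_entropy([0], [[0.5, 0.5]]) == pytest.approx(np.log(2.0))

    def test_matches_hand_computation(self):
        probs = np.array([[0.8, 0.2], [0.3, 0.7]])
        expected = -(np.log(0.8) + np.log(0.7)) / 2.0
        assert cross_entropy([0, 1], probs) == pytest.approx(expected, abs=1e-10)

    def test_non_probability_rows_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cross_entropy([0], [[0.9, 0.9]])


class TestEvaluate:
    def test_perfect_separation(self):
        probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        m = evaluate(probs, [0, 0, 1, 1])
        assert m["ACC"] == 1.0 and m["AUC"] == 1.0

    def test_reversed_scores_auc_zero(self):
        probs = np.array([[0.1, 0.9], [0.2, 0.8], [0.9, 0.1], [0.8, 0.2]])
        m = evaluate(probs, [0, 0, 1, 1])
        assert m["AUC"] == 0.0

    def test_single_error_and_concordance_oracle(self):
        probs = np.array([[0.9, 0.1], [0.4, 0.6], [0.1, 0.9], [0.2, 0.8]])
        labels = np.array([0, 0, 1, 1])
        m = evaluate(probs, labels)
        assert m["ACC"] == 0.75
        # brute-force pairwise concordance of the positive-class score
        scores = probs[:, 0]
        pos = scores[labels == 0]
        neg = scores[labels == 1]
        conc = np.mean([
            1.0 if p > q else (0.5 if p == q else 0.0)
            for p in pos for q in neg
        ])
        assert m["AUC"] == pytest.approx(conc)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            auc_rank([0.1, 0.9], [0, 0])


class TestCompareModels:
    def test_identical_vectors_give_p_one(self):
        x = np.array([0.8, 0.9, 0.85, 0.8, 0.9])
        P = compare_models({"a": x, "b": x.copy()})
        assert P.loc["a", "b"] == 1.0

    def test_disjoint_ranges_match_exact_u_distribution(self):
        # all 5 values of a below all 5 of b: U = 0, exact two-sided
        # p = 2 * 5!5!/10! = 2/252
        a = np.array([0.1, 0.2, 0.15, 0.12, 0.18])
        b = np.array([0.9, 0.8, 0.85, 0.95, 0.88])
        P = compare_models({"a": a, "b": b})
        assert P.loc["a", "b"] == pytest.approx(2.0 / 252.0, rel=1e-6)

    def test_matrix_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(12)
        P = compare_models({k: rng.random(5) for k in "abc"})
        assert np.allclose(P.values, P.values.T)
        assert np.allclose(np.diag(P.values), 1.0)


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_problem(self):
        """Linearly separable toy graphs: two classes with shifted features."""
        rng = np.random.default_rng(13)
        inputs, labels = [], []
        A = random_adjacency(rng, 8)
        for i in range(12):
            y = i % 2
            X = rng.standard_normal((8, 6)) + (2.5 if y else -2.5)
            inputs.append(prepare_subject(A, X, K1=2, K2=2, subject_id=f"s{i}"))
            labels.append(y)
        return inputs, np.array(labels)

    def test_same_seed_identical_metrics(self, tiny_problem):
        inputs, labels = tiny_problem
        kw = dict(n_folds=2, epochs=30, K1=2, K2=2, seed=4)
        a = cross_validate(inputs, labels, **kw)
        b = cross_validate(inputs, labels, **kw)
        assert [r.metrics["ACC"] for r in a] == [r.metrics["ACC"] for r in b]
        assert np.array_equal(a[0].test_probs, b[0].test_probs)

    def test_loss_decreases_over_first_epochs(self, tiny_problem):
        inputs, labels = tiny_problem
        for seed in (0, 1, 2):
            _, hist = train_model(inputs, labels, K1=2, K2=2, epochs=10,
                                  patience=10, seed=seed)
            assert hist.loss[-1] < hist.loss[0]

    def test_subject_level_split_disjoint(self, tiny_problem):
        inputs, labels = tiny_problem
        res = cross_validate(inputs, labels, n_folds=3, epochs=5, K1=2, K2=2, seed=0)
        all_ids = [sid for r in res for sid in r.test_ids]
        assert sorted(all_ids) == sorted(s.subject_id for s in inputs)

    def test_learns_separable_toy(self, tiny_problem):
        inputs, labels = tiny_problem
        res = cross_validate(inputs, labels, n_folds=2, epochs=60, K1=2, K2=2,
                             seed=1)
        mean_acc = np.mean([r.metrics["ACC"] for r in res])
        assert mean_acc >= 0.9
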