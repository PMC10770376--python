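import numpy as np
import pytest

from gspgcn.errors import InvalidArgumentError
from gspgcn.sparse_graph import (
    apply_sparse_graph,
    build_dictionary,
    fit_all_electrodes,
    fit_sparse_graph,
    pairwise_similarities,
    sparse_objective,
)


@pytest.fixture()
def toy_signals():
    rng = np.random.default_rng(0)
    return rng.standard_normal((3, 5, 40))  # subjects, channels, samples


class TestDictionary:
    def test_target_excluded_from_its_dictionary(self, toy_signals):
        x, X = build_dictionary(toy_signals, 2)
        assert X.shape == (3, 40, 4)
        for i in range(3):
            for col in range(4):
                assert not np.array_equal(X[i, :, col], x[i])

    def test_column_count(self, toy_signals):
        _, X = build_dictionary(toy_signals, 0)
        assert X.shape[2] == toy_signals.shape[1] - 1

    def test_single_channel_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_dictionary(np.zeros((2, 1, 10)), 0)

    def test_exact_reconstruction_of_linear_combination(self):
        """A channel that is a linear mix of two others is recovered with
        zero residual at lambda = 0."""
        rng = np.random.default_rng(1)
        base = rng.standard_normal((1, 4, 60))
        base[0, 0] = 2.0 * base[0, 1] - 0.5 * base[0, 3]
        x, X = build_dictionary(base, 0)
        model = fit_sparse_graph(x, X, lambdas=(0, 0, 0, 0), tol=0.0, max_iter=30_000)
        resid = np.linalg.norm(x[0] - X[0] @ model.W[:, 0])
        assert resid < 1e-8


class TestSimilarities:
    def test_self_similarity_one(self, toy_signals):
        S = pairwise_similarities(toy_signals, 1)
        assert np.allclose(np.diag(S), 1.0)

    def test_anticorrelated_clipped_to_zero(self):
        x = np.random.default_rng(2).standard_normal(50)
        sig = np.stack([np.stack([x, x]), np.stack([-x, x])])  # 2 subj, 2 ch
        S = pairwise_similarities(sig, 0)
        assert S[0, 1] == 0.0

    def test_symmetric(self, toy_signals):
        S = pairwise_similarities(toy_signals, 3)
        assert np.allclose(S, S.T)


class TestObjective:
    def test_zero_everything(self):
        W = np.zeros((4, 2))
        x = np.zeros((2, 10))
        X = np.zeros((2, 10, 4))
        assert sparse_objective(W, x, X, (1, 1, 1, 1)) == 0.0

    def test_lambda_zero_is_pure_reconstruction(self, toy_signals):
        x, X = build_dictionary(toy_signals, 0)
        rng = np.random.default_rng(3)
        W = rng.standard_normal((4, 3))
        expected = sum(
            0.5 * np.sum((x[i] - X[i] @ W[:, i]) ** 2) for i in range(3)
        )
        assert sparse_objective(W, x, X, (0, 0, 0, 0)) == pytest.approx(expected)

    def test_matches_term_by_term_evaluation(self, toy_signals):
        x, X = build_dictionary(toy_signals, 1)
        rng = np.random.default_rng(4)
        W = rng.standard_normal((4, 3))
        lam = (0.3, 0.2, 0.1, 0.05)
        pairs = [(0, 1), (1, 2)]
        sim = pairwise_similarities(toy_signals, 1)
        got = sparse_objective(W, x, X, lam, pairs_g=pairs, sim_g=sim,
                               pairs_t=pairs, sim_t=sim)
        recon = sum(0.5 * np.sum((x[i] - X[i] @ W[:, i]) ** 2) for i in range(3))
        l21 = np.linalg.norm(W, axis=1).sum()
        smooth = sum(sim[i, j] * np.sum((W[:, i] - W[:, j]) ** 2) for i, j in pairs)
        expected = recon + (lam[0] + lam[2]) * l21 + (lam[1] + lam[3]) * smooth
        assert abs(got - expected) < 1e-10

    def test_negative_lambda_rejected(self, toy_signals):
        x, X = build_dictionary(toy_signals, 0)
        with pytest.raises(InvalidArgumentError):
            sparse_objective(np.zeros((4, 3)), x, X, (-0.1, 0, 0, 0))


class TestFit:
    def test_lambda_zero_matches_least_squares(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((2, 30))
        X = rng.standard_normal((2, 30, 4))
        model = fit_sparse_graph(x, X, lambdas=(0, 0, 0, 0), tol=1e-14, max_iter=5000)
        for i in range(2):
            w_ls = np.linalg.lstsq(X[i], x[i], rcond=None)[0]
            assert np.linalg.norm(model.W[:, i] - w_ls) < 1e-6

    def test_huge_l1_shrinks_to_zero(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((2, 20))
        X = rng.standard_normal((2, 20, 3))
        model = fit_sparse_graph(x, X, lambdas=(1e6, 0, 0, 0), max_iter=200)
        assert np.linalg.norm(model.W, axis=1).max() < 1e-6

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((3, 25))
        X = rng.standard_normal((3, 25, 6))
        model = fit_sparse_graph(x, X, lambdas=(0.5, 0.1, 0.2, 0.0),
                                 pairs_g=[(0, 1), (1, 2)],
                                 tol=1e-12, max_iter=500)
        trace = np.asarray(model.objective_trace)
        assert (np.diff(trace) <= 1e-9).all()

    def test_lambda_continuity(self):
        """Nearby penalty weights give nearby solutions on a toy."""
        rng = np.random.default_rng(8)
        x = rng.standard_normal((2, 30))
        X = rng.standard_normal((2, 30, 4))
        w_a = fit_sparse_graph(x, X, lambdas=(0.100, 0, 0, 0), tol=1e-12, max_iter=2000).W
        w_b = fit_sparse_graph(x, X, lambdas=(0.101, 0, 0, 0), tol=1e-12, max_iter=2000).W
        assert np.linalg.norm(w_a - w_b) < 0.05 * max(np.linalg.norm(w_a), 1e-9)

    def test_planted_support_recovery(self):
        """Electrode 0 generated sparsely from electrodes {1, 3}: at a
        calibrated l1 the fitted support hits those rows with precision
        >= 0.8 and the true edges carry >= 90% of the weight mass."""
        rng = np.random.default_rng(9)
        signals = rng.standard_normal((4, 8, 120))
        for s in range(4):
            signals[s, 0] = (
                1.5 * signals[s, 1] - 1.0 * signals[s, 3]
                + 0.01 * rng.standard_normal(120)
            )
        x, X = build_dictionary(signals, 0)
        model = fit_sparse_graph(x, X, lambdas=(0.5, 0, 0, 0), tol=1e-12, max_iter=3000)
        row_mass = np.abs(model.W).sum(axis=1)
        support = np.flatnonzero(row_mass > 1e-3 * row_mass.max())
        true_rows = {0, 2}  # channels 1 and 3 after removing channel 0
        precision = len(true_rows & set(support)) / max(len(support), 1)
        assert precision >= 0.8
        assert row_mass[[0, 2]].sum() / row_mass.sum() >= 0.9


class TestApply:
    def test_all_zero_fits_give_empty_graph(self, toy_signals):
        models = fit_all_electrodes(toy_signals, lambdas=(1e6, 0, 1e6, 0), max_iter=100)
        A = apply_sparse_graph(models, 5)
        assert np.allclose(A, 0.0)

    def test_output_symmetric(self, toy_signals):
        models = fit_all_electrodes(toy_signals, lambdas=(0.1, 0.01, 0.1, 0.0),
                                    groups=np.array([0, 0, 1]), max_iter=100)
        A = apply_sparse_graph(models, 5)
        assert np.allclose(A, A.T)
        assert np.allclose(np.diag(A), 0.0)

    def test_missing_electrode_rejected(self, toy_signals):
        models = fit_all_electrodes(toy_signals, max_iter=10)
        del models[2]
        with pytest.raises(InvalidArgumentError):
            apply_sparse_graph(models, 5)
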