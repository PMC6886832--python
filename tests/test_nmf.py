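"""Multiplicative-update NMF: exactness, monotonicity, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metasig import (
    MetaboliteMatrix,
    SignatureNMF,
    StudyConfig,
    factorize,
    generate_study,
    normalize_signatures,
    reconstruction_error,
)
from metasig.exceptions import DegenerateSignatureError, ValidationError
from tests.conftest import random_matrix


def best_of_restarts(X, k, seeds=range(5), **kwargs):
    """Standard practice: several random restarts, keep the best fit."""
    fits = [factorize(X, k=k, seed=s, **kwargs) for s in seeds]
    return min(fits, key=lambda r: reconstruction_error(X, r))


class TestFactorize:
    def test_exact_rank_one_matrix(self):
        X = np.outer([1.0, 2.0], [3.0, 1.0, 2.0])
        res = factorize(X, k=1, rel_tol=1e-12, max_iter=5000)
        assert reconstruction_error(X, res) <= 1e-6

    def test_zero_metabolite_row_gets_zero_weight(self):
        X = np.abs(np.random.default_rng(0).normal(size=(10, 6))) + 0.1
        X[3] = 0.0
        res = factorize(X, k=2, seed=1)
        assert np.all(res.signatures.weights.to_numpy()[3] <= 1e-12)

    @pytest.mark.parametrize("objective", ["frobenius", "kl"])
    def test_objective_trace_non_increasing(self, rng, objective):
        X = random_matrix(rng, 20, 8)
        res = factorize(X, k=3, objective=objective, seed=0)
        trace = res.objective_trace
        slack = 1e-10 * max(abs(trace[0]), 1.0)
        assert np.all(np.diff(trace) <= slack)

    def test_reproducible_under_seed(self, rng):
        X = random_matrix(rng, 15, 6)
        r1 = factorize(X, k=2, seed=7)
        r2 = factorize(X, k=2, seed=7)
        np.testing.assert_array_equal(
            r1.signatures.weights.to_numpy(), r2.signatures.weights.to_numpy()
        )
        np.testing.assert_array_equal(
            r1.loadings.loadings.to_numpy(), r2.loadings.loadings.to_numpy()
        )

    def test_k_out_of_range_rejected(self, rng):
        X = random_matrix(rng, 10, 5)
        with pytest.raises(ValueError):
            factorize(X, k=0)
        with pytest.raises(ValueError):
            factorize(X, k=6)

    def test_negative_matrix_rejected(self):
        with pytest.raises(ValidationError):
            factorize(np.array([[1.0, -1.0], [2.0, 3.0]]), k=1)

    def test_scale_invariance_of_normalized_signatures(self):
        config = StudyConfig(
            n_metabolites=40, n_per_group={"A": 3, "B": 3}, n_signatures=2,
            noise_cv=0.0, seed=2,
        )
        X, _ = generate_study(config)
        c = 7.3
        r1 = factorize(X, k=2, seed=0, rel_tol=1e-10, max_iter=5000)
        r2 = factorize(
            MetaboliteMatrix(c * X.values, X.metabolite_ids, X.sample_ids),
            k=2, seed=0, rel_tol=1e-10, max_iter=5000,
        )
        W1 = r1.signatures.weights.to_numpy()
        W2 = r2.signatures.weights.to_numpy()
        # match columns greedily by cosine similarity before comparing
        sims = W1.T @ W2 / (
            np.linalg.norm(W1, axis=0)[:, None] * np.linalg.norm(W2, axis=0)
        )
        perm = np.argmax(sims, axis=1)
        assert sorted(perm) == [0, 1]
        np.testing.assert_allclose(W1, W2[:, perm], atol=1e-6)
        H1 = r1.loadings.loadings.to_numpy()
        H2 = r2.loadings.loadings.to_numpy()[perm]
        np.testing.assert_allclose(c * H1, H2, rtol=1e-4)

    def test_recovery_of_planted_signatures(self):
        """Noiseless well-separated signatures are recovered to cosine >= 0.95."""
        # one group per signature: every signature dominates some samples,
        # which is what makes the factorization identifiable
        config = StudyConfig(
            n_metabolites=120, n_per_group={"A": 4, "B": 4, "C": 4},
            n_signatures=3, noise_cv=0.0, signature_sparsity=0.2, seed=8,
        )
        X, truth = generate_study(config)
        res = best_of_restarts(X, k=3, rel_tol=1e-10, max_iter=5000)
        Wt = truth.true_signatures.to_numpy()
        Wf = res.signatures.weights.to_numpy()
        sims = Wt.T @ Wf / (
            np.linalg.norm(Wt, axis=0)[:, None] * np.linalg.norm(Wf, axis=0)
        )
        matched = []
        taken = set()
        # greedy maximum-similarity matching
        for _ in range(3):
            i, j = np.unravel_index(
                np.argmax(np.where(
                    np.isin(np.arange(3), list(taken))[None, :], -np.inf, sims
                )), sims.shape)
            matched.append(sims[i, j])
            sims[i, :] = -np.inf
            taken.add(j)
        assert min(matched) >= 0.95

    def test_matches_reference_nmf_fit_quality(self, rng):
        """Reconstruction error is on par with an independent NMF solver."""
        from sklearn.decomposition import NMF

        X = random_matrix(rng, 30, 10)
        ours = best_of_restarts(X, k=4, rel_tol=1e-9, max_iter=4000)
        err_ours = reconstruction_error(X, ours)
        ref = NMF(n_components=4, init="random", random_state=0,
                  max_iter=4000, tol=1e-9, solver="mu").fit(X.values)
        err_ref = np.linalg.norm(
            X.values - ref.transform(X.values) @ ref.components_
        ) / np.linalg.norm(X.values)
        assert err_ours <= err_ref * 1.1 + 1e-9


class TestHypothesisProperties:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        k=st.integers(1, 4),
        objective=st.sampled_from(["frobenius", "kl"]),
    )
    def test_factors_nonnegative_and_trace_monotone(self, seed, k, objective):
        X = random_matrix(None, 12, 6, seed=seed)
        res = factorize(X, k=k, objective=objective, seed=seed, max_iter=300)
        assert np.all(res.signatures.weights.to_numpy() >= 0)
        assert np.all(res.loadings.loadings.to_numpy() >= 0)
        trace = res.objective_trace
        assert np.all(np.diff(trace) <= 1e-10 * max(abs(trace[0]), 1.0))


class TestNormalizeSignatures:
    def test_already_normalized_unchanged(self):
        W = np.array([[0.2], [0.3], [0.5]])
        H = np.array([[1.0, 4.0]])
        W2, H2 = normalize_signatures(W, H)
        np.testing.assert_allclose(W2, W)
        np.testing.assert_allclose(H2, H)

    def test_scaling_identity(self):
        W = np.array([[2.0], [3.0], [5.0]])
        H = np.array([[1.0, 4.0]])
        W2, H2 = normalize_signatures(W, H)
        np.testing.assert_allclose(W2[:, 0], [0.2, 0.3, 0.5])
        np.testing.assert_allclose(H2[0], [10.0, 40.0])
        np.testing.assert_allclose(W @ H, W2 @ H2)

    def test_zero_column_raises(self):
        with pytest.raises(DegenerateSignatureError):
            normalize_signatures(np.zeros((3, 1)), np.ones((1, 2)))


class TestReconstructionError:
    def test_exact_product_gives_zero(self):
        W = np.array([[1.0], [2.0]])
        H = np.array([[3.0, 1.0]])
        assert reconstruction_error(W @ H, (W, H)) == 0.0

    def test_one_by_one_case(self):
        assert reconstruction_error(
            np.array([[1.0]]), (np.array([[2.0]]), np.array([[1.0]]))
        ) == pytest.approx(1.0)

    def test_matches_elementwise_oracle(self, rng):
        X = random_matrix(rng, 10, 6)
        res = factorize(X, k=3, seed=0, max_iter=100)
        W = res.signatures.weights.to_numpy()
        H = res.loadings.loadings.to_numpy()
        # brute-force elementwise computation
        prod = np.zeros_like(X.values)
        for i in range(10):
            for j in range(6):
                prod[i, j] = sum(W[i, r] * H[r, j] for r in range(3))
        expected = np.sqrt(((X.values - prod) ** 2).sum()) / np.sqrt(
            (X.values ** 2).sum()
        )
        assert reconstruction_error(X, res) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        X = random_matrix(rng, 10, 6)
        with pytest.raises(ValidationError):
            reconstruction_error(X, (np.ones((9, 2)), np.ones((2, 6))))
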