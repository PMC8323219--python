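import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fundusgcn.label_graph import (GraphConfig, binarize, build_adjacency,
                                   conditional_probabilities,
                                   cooccurrence_counts, load_matrix,
                                   normalize, reweight, save_matrix)
from fundusgcn.synthetic_data import (default_mixture, sample_labels,
                                      true_conditional_probabilities)


def brute_cooccurrence(Y):
    """Per-sample loop oracle for the vectorized count."""
    n, k = Y.shape
    M = np.zeros((k, k), dtype=int)
    for s in range(n):
        for i in range(k):
            for j in range(k):
                if Y[s, i] and Y[s, j]:
                    M[i, j] += 1
    return M


class TestCooccurrence:
    def test_hand_counted_toy(self, toy_labels):
        M = cooccurrence_counts(toy_labels)
        np.testing.assert_array_equal(np.diag(M), [3, 3, 1])
        assert M[0, 1] == 2 and M[0, 2] == 0 and M[1, 2] == 1
        np.testing.assert_array_equal(M, M.T)

    def test_all_zero_matrix(self):
        np.testing.assert_array_equal(
            cooccurrence_counts(np.zeros((2, 3), dtype=int)), np.zeros((3, 3)))

    def test_single_sample_all_ones(self):
        np.testing.assert_array_equal(cooccurrence_counts([[1, 1]]),
                                      np.ones((2, 2)))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            cooccurrence_counts([[0, 2]])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(1, 50), st.integers(2, 10), st.integers(0, 10_000))
    def test_matches_bruteforce(self, n, k, seed):
        Y = np.random.default_rng(seed).integers(0, 2, size=(n, k))
        np.testing.assert_array_equal(cooccurrence_counts(Y),
                                      brute_cooccurrence(Y))


class TestConditionalProbabilities:
    def test_hand_derived_toy(self, toy_labels):
        P = conditional_probabilities(cooccurrence_counts(toy_labels))
        # 0-indexed: labels (1,2,3) in the hand derivation are (0,1,2) here
        assert P[0, 1] == pytest.approx(2 / 3)
        assert P[1, 0] == pytest.approx(2 / 3)
        assert P[2, 1] == pytest.approx(1 / 3)
        assert P[1, 2] == pytest.approx(1.0)
        assert P[0, 2] == pytest.approx(0.0)
        np.testing.assert_array_equal(np.diag(P), np.ones(3))

    def test_diag_only_gives_identity(self):
        np.testing.assert_array_equal(
            conditional_probabilities(np.diag([4, 2, 7])), np.eye(3))

    def test_unseen_label_errors(self):
        M = np.diag([3, 0, 2])
        with pytest.raises(ValueError, match=r"\[1\]"):
            conditional_probabilities(M)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(2, 8), st.integers(0, 10_000))
    def test_entries_in_unit_interval(self, k, seed):
        rng = np.random.default_rng(seed)
        Y = rng.integers(0, 2, size=(30, k))
        Y[0] = 1  # ensure every label occurs
        P = conditional_probabilities(cooccurrence_counts(Y))
        assert np.all((P >= 0) & (P <= 1))
        np.testing.assert_array_equal(np.diag(P), np.ones(k))


class TestBinarize:
    def test_toy_edges_at_default_tau(self, toy_labels):
        P = conditional_probabilities(cooccurrence_counts(toy_labels))
        A = binarize(P, 0.3)
        assert A[0, 1] == 1 and A[1, 0] == 1
        assert A[2, 1] == 1 and A[1, 2] == 1
        assert A[0, 2] == 0 and A[2, 0] == 0

    def test_tau_above_max_kills_all_offdiagonal(self):
        P = np.array([[1.0, 0.4], [0.2, 1.0]])
        off_mask = ~np.eye(2, dtype=bool)
        A = binarize(P, P[off_mask].max() + 1e-9)
        assert A[off_mask].sum() == 0

    def test_tie_at_threshold_is_edge(self):
        assert binarize(np.array([[0.3]]), 0.3)[0, 0] == 1

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(arrays(float, (5, 5), elements=st.floats(0, 1)),
           st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    def test_monotone_in_tau(self, P, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2)
        assert np.all(binarize(P, hi) <= binarize(P, lo))


class TestReweight:
    def test_row_arithmetic(self):
        A_bin = np.array([[1., 1, 1, 0],
                          [1, 1, 0, 0],
                          [0, 0, 1, 0],
                          [1, 1, 1, 1]])
        A = reweight(A_bin, 0.25)
        np.testing.assert_allclose(A[0], [0.75, 0.125, 0.125, 0.0])
        np.testing.assert_allclose(np.diag(A), 0.75)

    def test_isolated_row_keeps_diagonal_only(self):
        A = reweight(np.eye(3), 0.25)
        np.testing.assert_allclose(A, 0.75 * np.eye(3))

    def test_connected_rows_sum_to_one(self, toy_labels):
        P = conditional_probabilities(cooccurrence_counts(toy_labels))
        A = reweight(binarize(P, 0.3), 0.25)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(2, 9), st.integers(0, 10_000), st.floats(0.05, 0.95))
    def test_conservation_property(self, k, seed, p):
        A_bin = np.random.default_rng(seed).integers(0, 2, size=(k, k))
        A = reweight(A_bin.astype(float), p)
        off = A_bin.copy()
        np.fill_diagonal(off, 0)
        connected = off.sum(axis=1) > 0
        np.testing.assert_allclose(A[connected].sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(A[~connected].sum(axis=1), 1.0 - p)
        # sparsity preserved: binarization zeros stay zero off the diagonal
        offdiag = ~np.eye(k, dtype=bool)
        assert np.all(A[offdiag][off[offdiag] == 0] == 0)


class TestNormalize:
    def test_row_sums_one_is_fixed_point(self, toy_labels):
        P = conditional_probabilities(cooccurrence_counts(toy_labels))
        A = reweight(binarize(P, 0.3), 0.25)
        assert np.allclose(A.sum(axis=1), 1.0)
        np.testing.assert_allclose(normalize(A), A)

    def test_direct_arithmetic(self):
        A = np.array([[0.75, 0.25], [0.5, 0.75]])
        A_hat = normalize(A)
        assert A_hat[1, 0] == pytest.approx(0.5 / np.sqrt(1.25))
        assert A_hat[1, 1] == pytest.approx(0.75 / 1.25)
        # cross-check against the matrix-form oracle
        D = np.diag(A.sum(axis=1))
        oracle = np.linalg.inv(np.sqrt(D)) @ A @ np.linalg.inv(np.sqrt(D))
        np.testing.assert_allclose(A_hat, oracle, atol=1e-12)

    def test_symmetry_preserved(self):
        A = np.array([[0.75, 0.25, 0.0],
                      [0.25, 0.75, 0.5],
                      [0.0, 0.5, 0.75]])
        A_hat = normalize(A)
        np.testing.assert_allclose(A_hat, A_hat.T)

    def test_nonpositive_row_sum_errors(self):
        with pytest.raises(ValueError, match="row sum"):
            normalize(np.zeros((2, 2)))


class TestPipelineAndSerialization:
    def test_asymmetry_is_preserved_end_to_end(self, toy_labels):
        # P(2|3)=1 but P(3|2)=1/3: the graph is directed and stays so
        g = build_adjacency(toy_labels, GraphConfig(tau=0.5, p=0.25))
        assert g["A_binary"][1, 2] != g["A_binary"][2, 1]
        assert not np.allclose(g["A_normalized"], g["A_normalized"].T)

    def test_recovery_converges_with_sample_size(self):
        """Empirical conditionals approach the mixture's closed form."""
        mix = default_mixture()
        P_true = true_conditional_probabilities(mix)
        errs = {}
        for n in (2000, 20000):
            Y = sample_labels(n, mix, seed=11)
            P_hat = conditional_probabilities(cooccurrence_counts(Y))
            errs[n] = np.abs(P_hat - P_true).max()
        assert errs[20000] < errs[2000]
        assert errs[20000] < 0.05

    def test_matrix_roundtrip(self, tmp_path, toy_labels):
        g = build_adjacency(toy_labels)
        path = tmp_path / "a.tsv"
        save_matrix(path, g["A_normalized"], ["a", "b", "c"])
        loaded, labels = load_matrix(path)
        assert labels == ["a", "b", "c"]
        np.testing.assert_array_equal(loaded, g["A_normalized"])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GraphConfig(tau=0.0)
        with pytest.raises(ValueError):
            GraphConfig(p=1.0)
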