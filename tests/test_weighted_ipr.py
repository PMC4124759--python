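import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ipr2go import group_weights, phi_correlation_matrix, weighted_transform
from tests._oracle import brute_force_weighted
from tests.conftest import DEMO_CORR, DEMO_WEIGHTED


class TestPhiCorrelationMatrix:
    def test_demo_matrix_reproduces_reference_at_4dp(self, demo_matrix):
        C = phi_correlation_matrix(demo_matrix)
        np.testing.assert_allclose(np.round(C.values, 4), DEMO_CORR, atol=1e-12)

    def test_named_pairs(self, demo_matrix):
        C = phi_correlation_matrix(demo_matrix).values
        assert round(C[0, 4], 4) == 0.6124  # IPR1 vs IPR5
        assert round(C[1, 5], 4) == -0.6124  # IPR2 vs IPR6

    def test_diagonal_is_one(self, demo_matrix):
        C = phi_correlation_matrix(demo_matrix).values
        np.testing.assert_array_equal(np.diag(C), np.ones(6))

    def test_symmetry(self, demo_matrix):
        C = phi_correlation_matrix(demo_matrix).values
        np.testing.assert_allclose(C, C.T, atol=1e-12)

    def test_zero_variance_column_correlates_zero(self):
        X = np.array([[1, 0, 1], [1, 1, 0], [1, 0, 0], [1, 1, 1]])
        C = phi_correlation_matrix(X).values
        np.testing.assert_array_equal(C[0, 1:], [0.0, 0.0])
        assert C[0, 0] == 1.0

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            phi_correlation_matrix(np.array([[0, 1]]))

    def test_matches_numpy_corrcoef_on_nondegenerate_columns(self):
        rng = np.random.default_rng(0)
        X = (rng.random((25, 8)) < 0.4).astype(float)
        X = X[:, (X.sum(0) > 0) & (X.sum(0) < 25)]
        np.testing.assert_allclose(
            phi_correlation_matrix(X).values, np.corrcoef(X, rowvar=False), atol=1e-12
        )


class TestWeightedTransform:
    def test_worked_intermediates_from_rounded_correlations(self, demo_matrix):
        """The published derivation sums the 4-d.p. correlation table:
        weight 0.7791, group total 0.7418, final 0.5*0.7791/0.7418=0.5251."""
        members, w, total = group_weights(demo_matrix.values[0].astype(float), DEMO_CORR, 0)
        np.testing.assert_array_equal(members, [0, 4, 5])
        assert round(w[0], 4) == 0.7791
        assert round(total, 4) == 0.7418
        assert round(0.5 * w[0] / total, 4) == 0.5251

    def test_full_precision_intermediates(self, demo_matrix):
        C = phi_correlation_matrix(demo_matrix)
        _, w, total = group_weights(demo_matrix.values[0].astype(float), C.values, 0)
        assert w[0] == pytest.approx(0.7790, abs=5e-5)
        assert total == pytest.approx(0.7416, abs=5e-5)

    def test_demo_matrix_entrywise_against_reference(self, demo_matrix):
        """The printed reference table rounds intermediates inconsistently
        (its rows disagree by up to 2e-4 with any single convention); the
        full-precision transform must agree within that rounding slack."""
        C = phi_correlation_matrix(demo_matrix)
        W = weighted_transform(demo_matrix, C)
        np.testing.assert_allclose(np.round(W.values, 4), DEMO_WEIGHTED, atol=2.5e-4)

    def test_singleton_group_gets_half(self, demo_matrix):
        # protein 3 carries only IPR6: a one-member group takes the whole mass
        C = phi_correlation_matrix(demo_matrix)
        W = weighted_transform(demo_matrix, C)
        assert W.values[2, 5] == pytest.approx(0.5)

    def test_negative_denominator_cell(self, demo_matrix):
        # protein 2's absent-group weights total -2/3; the ratio is taken as-is
        C = phi_correlation_matrix(demo_matrix)
        W = weighted_transform(demo_matrix, C)
        assert W.values[1, 3] == pytest.approx(0.3750, abs=5e-5)
        _, _, total = group_weights(demo_matrix.values[1].astype(float), C.values, 0)
        assert total == pytest.approx(-2 / 3)

    def test_full_precision_cell_that_rounded_inputs_miss(self, demo_matrix):
        # (protein 5, IPR1): rounded correlation inputs give 0.7985
        C = phi_correlation_matrix(demo_matrix)
        W = weighted_transform(demo_matrix, C)
        assert W.values[4, 0] == pytest.approx(0.7990, abs=1.5e-4)
        W_rounded = weighted_transform(demo_matrix.values.astype(float),
                                       type(C)(C.feature_ids, np.round(C.values, 4)))
        assert round(W_rounded.values[4, 0], 4) == 0.7985

    def test_all_ones_protein_is_single_group_summing_to_half(self):
        X = np.array([[1, 1, 1], [1, 0, 1], [0, 1, 0], [1, 1, 0]])
        W = weighted_transform(X, phi_correlation_matrix(X))
        assert W.values[0].sum() == pytest.approx(0.5, abs=1e-9)

    def test_group_conservation_on_demo(self, demo_matrix):
        C = phi_correlation_matrix(demo_matrix)
        W = weighted_transform(demo_matrix, C)
        for p in range(5):
            for v in (0, 1):
                members = np.flatnonzero(demo_matrix.values[p] == v)
                if len(members) >= 1:
                    assert W.values[p, members].sum() == pytest.approx(0.5, abs=1e-9)

    def test_zero_denominator_falls_back_to_equal_shares(self):
        # two all-zero (zero-variance) columns in one group: all correlations 0
        X = np.array([[1, 0, 0], [1, 0, 0], [0, 0, 0]])
        W = weighted_transform(X, phi_correlation_matrix(X))
        assert W.values[0, 1] == W.values[0, 2] == pytest.approx(0.25)
        assert (0, 0) in W.degenerate_groups

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        X = (rng.random((12, 7)) < 0.4).astype(float)
        perm = rng.permutation(7)
        W = weighted_transform(X, phi_correlation_matrix(X)).values
        W_perm = weighted_transform(X[:, perm], phi_correlation_matrix(X[:, perm])).values
        np.testing.assert_allclose(W_perm, W[:, perm], atol=1e-12)

    def test_duplicating_a_row_changes_its_transform(self):
        """Correlations are data-dependent: the encoding of a protein is not
        invariant to enlarging the matrix (documented non-invariance)."""
        rng = np.random.default_rng(4)
        X = (rng.random((10, 6)) < 0.4).astype(float)
        W = weighted_transform(X, phi_correlation_matrix(X)).values
        X2 = np.vstack([X, X[0]])
        W2 = weighted_transform(X2, phi_correlation_matrix(X2)).values
        assert not np.allclose(W2[0], W[0])

    def test_mismatched_correlation_shape_rejected(self, demo_matrix):
        C = phi_correlation_matrix(demo_matrix.values[:, :3].astype(float))
        with pytest.raises(ValueError):
            weighted_transform(demo_matrix, C)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.integers(2, 20).flatmap(
            lambda n: st.integers(1, 15).flatmap(
                lambda m: arrays(np.int8, (n, m), elements=st.integers(0, 1))
            )
        )
    )
    def test_agrees_with_brute_force_oracle(self, X):
        W = weighted_transform(X.astype(float), phi_correlation_matrix(X.astype(float)))
        np.testing.assert_allclose(W.values, brute_force_weighted(X), atol=1e-9)
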