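"""AHP weight derivation, consistency diagnostics and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caaprio.ahp import (
    CR_THRESHOLD,
    RANDOM_INDEX,
    ComparisonMatrix,
    MatrixValidationError,
    WeightVector,
    aggregate_experts,
    consistency_ratio,
    consistent_matrix_from_weights,
    derive_weights,
    validate_matrix,
)


def random_reciprocal(n: int, rng: np.random.Generator) -> ComparisonMatrix:
    """Random reciprocal matrix with Saaty-range upper-triangle entries."""
    a = np.ones((n, n))
    iu = np.triu_indices(n, 1)
    a[iu] = np.exp(rng.uniform(-np.log(9), np.log(9), size=len(iu[0])))
    a[(iu[1], iu[0])] = 1.0 / a[iu]
    return validate_matrix(a, [f"f{i}" for i in range(n)])


def eig_oracle(m: ComparisonMatrix) -> tuple[np.ndarray, float]:
    """Dense eigendecomposition: independent route to the principal vector."""
    vals, vecs = np.linalg.eig(m.values)
    k = int(np.argmax(vals.real))
    v = np.abs(vecs[:, k].real)
    return v / v.sum(), float(vals[k].real)


class TestValidation:
    def test_indifference_matrix_is_valid(self):
        m = validate_matrix(np.ones((3, 3)), ["a", "b", "c"])
        assert m.n == 3

    def test_reciprocal_pair_is_valid(self):
        m = validate_matrix([[1, 2], [0.5, 1]], ["a", "b"])
        assert m.values[0, 1] == 2

    @pytest.mark.parametrize(
        "raw, fragment",
        [
            ([[1, 2], [0.4, 1]], "(1, 0)"),          # 0.4 is not 1/2
            ([[1, 2, 3], [0.5, 1, 1]], "shape"),     # not square
            ([[1, -2], [-0.5, 1]], "non-positive"),
            ([[2, 1], [1, 2]], "diagonal"),
        ],
    )
    def test_structural_errors_name_the_problem(self, raw, fragment):
        with pytest.raises(MatrixValidationError, match=None) as exc:
            validate_matrix(raw, [f"f{i}" for i in range(len(raw))])
        assert fragment in str(exc.value)

    def test_duplicate_factor_ids_rejected(self):
        with pytest.raises(MatrixValidationError):
            validate_matrix(np.ones((2, 2)), ["a", "a"])


class TestDeriveWeights:
    def test_indifference_gives_uniform_weights(self):
        m = validate_matrix(np.ones((3, 3)), list("abc"))
        w, rep = derive_weights(m)
        np.testing.assert_allclose(w.weights, 1 / 3, atol=1e-12)
        assert rep.consistency_ratio == 0

    def test_recovers_published_panel_weights(self, panel_weights):
        """A perfectly consistent ratio matrix round-trips the seven
        consensus weights (0.22 ... 0.08) through the eigenvector method."""
        m = consistent_matrix_from_weights(panel_weights)
        w, rep = derive_weights(m)
        np.testing.assert_allclose(w.weights, panel_weights.weights, atol=1e-6)
        assert rep.consistency_ratio <= 1e-9
        assert rep.acceptable

    def test_inconsistent_3x3_matches_dense_eigensolver(self):
        m = validate_matrix([[1, 2, 0.5], [0.5, 1, 4], [2, 0.25, 1]], list("abc"))
        w, rep = derive_weights(m)
        w_ref, lam_ref = eig_oracle(m)
        np.testing.assert_allclose(w.weights, w_ref, atol=1e-8)
        ci_ref = (lam_ref - 3) / 2
        assert rep.consistency_ratio == pytest.approx(ci_ref / RANDOM_INDEX[3], abs=1e-8)
        assert rep.consistency_ratio > 0

    def test_oracle_equivalence_random_matrices(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 10))
            m = random_reciprocal(n, rng)
            w, rep = derive_weights(m)
            w_ref, lam_ref = eig_oracle(m)
            np.testing.assert_allclose(w.weights, w_ref, atol=1e-8)
            assert rep.lambda_max >= n - 1e-9
            assert rep.consistency_index >= 0
            assert rep.consistency_ratio >= 0

    def test_permutation_equivariance(self, rng):
        m = random_reciprocal(6, rng)
        w, rep = derive_weights(m)
        perm = rng.permutation(6)
        wp, repp = derive_weights(m.permuted(perm))
        np.testing.assert_allclose(wp.weights, w.weights[perm], atol=1e-10)
        assert repp.consistency_ratio == pytest.approx(rep.consistency_ratio, abs=1e-10)


class TestConsistencyRatio:
    def test_consistent_matrix_cr_zero(self, rng):
        w = rng.dirichlet(np.ones(5))
        m = consistent_matrix_from_weights(WeightVector(tuple("abcde"), w))
        assert consistency_ratio(m).consistency_ratio <= 1e-9

    def test_2x2_always_consistent(self):
        m = validate_matrix([[1, 7], [1 / 7, 1]], ["a", "b"])
        rep = consistency_ratio(m)
        assert rep.consistency_ratio == 0
        assert rep.acceptable

    def test_acceptability_threshold(self, rng):
        # a wildly intransitive matrix must be flagged
        m = validate_matrix([[1, 9, 1 / 9], [1 / 9, 1, 9], [9, 1 / 9, 1]], list("abc"))
        rep = consistency_ratio(m)
        assert rep.consistency_ratio > CR_THRESHOLD
        assert not rep.acceptable


class TestAggregation:
    def test_single_matrix_unchanged(self, rng):
        m = random_reciprocal(4, rng)
        agg = aggregate_experts([m])
        np.testing.assert_allclose(agg.values, m.values, rtol=1e-12)

    def test_geometric_mean_of_two_judgments(self):
        m1 = validate_matrix([[1, 2], [0.5, 1]], ["a", "b"])
        m2 = validate_matrix([[1, 8], [0.125, 1]], ["a", "b"])
        agg = aggregate_experts([m1, m2])
        assert agg.values[0, 1] == pytest.approx(4.0)
        assert agg.values[1, 0] == pytest.approx(0.25)

    def test_mismatched_factors_rejected(self, rng):
        m1 = random_reciprocal(3, rng)
        m2 = ComparisonMatrix(("x", "y", "z"), m1.values)
        with pytest.raises(ValueError, match="factors"):
            aggregate_experts([m1, m2])

    def test_panel_aggregate_beats_worst_expert(self, panel_weights, rng):
        """Geometric-mean aggregation of ten jittered expert matrices lands
        closer (L1) to the generating weights than the worst single expert."""
        from caaprio.fixtures import jittered_comparison_matrices

        mats = jittered_comparison_matrices(panel_weights, n_experts=10, sigma=0.3, rng=rng)
        errs = [
            np.abs(derive_weights(m)[0].weights - panel_weights.weights).sum() for m in mats
        ]
        agg_err = np.abs(
            derive_weights(aggregate_experts(mats))[0].weights - panel_weights.weights
        ).sum()
        assert agg_err < max(errs)


class TestConsistentConstruction:
    def test_equal_weights_give_all_ones(self):
        m = consistent_matrix_from_weights(WeightVector(("a", "b"), np.array([0.5, 0.5])))
        np.testing.assert_allclose(m.values, 1.0)

    def test_extreme_ratio_of_panel_weights(self, panel_weights):
        m = consistent_matrix_from_weights(panel_weights)
        assert m.values[0, 6] == pytest.approx(0.22 / 0.08)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            consistent_matrix_from_weights(
                WeightVector(("a", "b", "c"), np.array([1.0, 0.0, 0.0]))
            )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8), st.integers(0, 2**31 - 1))
    def test_round_trip_recovers_any_positive_weights(self, raw, _seed):
        w = np.asarray(raw) / np.sum(raw)
        wv = WeightVector(tuple(f"f{i}" for i in range(len(w))), w)
        back, rep = derive_weights(consistent_matrix_from_weights(wv))
        np.testing.assert_allclose(back.weights, w, atol=1e-9)
        assert rep.consistency_ratio <= 1e-9
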