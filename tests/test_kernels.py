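"""Kernel module: distances, local scales, CNN counts, both kernels."""

import numpy as np
import pytest

from spectrumclust import (
    ExpressionMatrix,
    InputError,
    KernelParams,
    ParameterError,
    adaptive_kernel,
    cnn_counts,
    local_scale,
    pairwise_distances,
    zelnik_manor_kernel,
)
from spectrumclust.kernels import _kernel_matrix

from oracles import cnn_loop, distance_loop, kernel_scalar


class TestPairwiseDistances:
    def test_identical_samples_have_zero_distance(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]])
        D = pairwise_distances(X)
        assert D[0, 1] == 0.0

    def test_three_four_five_triangle(self):
        D = pairwise_distances(np.array([[0.0, 0.0], [3.0, 4.0], [1.0, 1.0]]))
        assert D[0, 1] == pytest.approx(5.0)

    def test_matches_per_pair_loop(self, rng):
        X = rng.normal(size=(5, 3))
        np.testing.assert_allclose(pairwise_distances(X), distance_loop(X), atol=1e-12)

    def test_symmetric_zero_diagonal(self, rng):
        D = pairwise_distances(rng.normal(size=(10, 4)))
        np.testing.assert_array_equal(D, D.T)
        np.testing.assert_array_equal(np.diag(D), np.zeros(10))

    def test_missing_values_rejected_with_coordinates(self):
        vals = np.array([[1.0, np.nan, 2.0], [0.0, 1.0, 2.0]])
        with pytest.raises(InputError, match="f1.*s2"):
            ExpressionMatrix(vals, ["s1", "s2", "s3"], ["f1", "f2"])


class TestLocalScale:
    # 1-D points 0,1,2,10
    D = distance_loop(np.array([[0.0], [1.0], [2.0], [10.0]]))

    def test_first_neighbour_distances(self):
        np.testing.assert_allclose(local_scale(self.D, P=1), [1, 1, 1, 8])

    def test_second_neighbour_distances(self):
        np.testing.assert_allclose(local_scale(self.D, P=2), [2, 1, 2, 9])

    def test_duplicate_point_falls_back_to_positive_distance(self):
        D = distance_loop(np.array([[0.0], [0.0], [5.0]]))
        sigma = local_scale(D, P=1)
        assert sigma[0] == 5.0  # 1st NN is the duplicate at distance 0

    def test_all_identical_points_scale_one(self):
        D = np.zeros((4, 4))
        np.testing.assert_allclose(local_scale(D, P=2), np.ones(4))

    def test_p_out_of_range(self):
        with pytest.raises(ParameterError):
            local_scale(self.D, P=4)


class TestCnnCounts:
    def test_disjoint_blobs_share_no_neighbours(self):
        a = np.arange(10, dtype=float).reshape(-1, 1) * 0.01
        b = a + 1000.0
        D = distance_loop(np.vstack([a, b]))
        cnn = cnn_counts(D, S=3)
        assert cnn[:10, 10:].max() == 0

    def test_bounded_by_set_size(self, points8):
        D = pairwise_distances(points8)
        assert cnn_counts(D, S=4).max() <= 4

    def test_matches_set_intersection_loop(self, points8):
        D = pairwise_distances(points8)
        np.testing.assert_array_equal(cnn_counts(D, S=3), cnn_loop(D, 3))

    def test_scale_invariance(self, points8):
        D1 = pairwise_distances(points8)
        D2 = pairwise_distances(points8 * 37.5)
        np.testing.assert_array_equal(cnn_counts(D1, S=3), cnn_counts(D2, S=3))


class TestKernels:
    def test_unit_diagonal_regardless_of_cnn(self, points8):
        A = adaptive_kernel(pairwise_distances(points8), KernelParams(P=3, S=7))
        np.testing.assert_array_equal(np.diag(A.values), np.ones(8))

    def test_zero_cnn_reduces_to_zelnik_manor(self, points8):
        D = pairwise_distances(points8)
        sigma = local_scale(D, 3)
        reduced = _kernel_matrix(D, sigma, np.zeros((8, 8)))
        zm = zelnik_manor_kernel(D, P=3).values
        np.testing.assert_allclose(reduced, zm, atol=1e-15)

    def test_adaptive_matches_scalar_formula(self, points8):
        D = pairwise_distances(points8)
        A = adaptive_kernel(D, KernelParams(P=3, S=7)).values
        expected = kernel_scalar(D, local_scale(D, 3), cnn_loop(D, 7))
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(A, expected, atol=1e-12)

    def test_zelnik_manor_matches_scalar_formula(self, points8):
        D = pairwise_distances(points8)
        A = zelnik_manor_kernel(D, P=3).values
        expected = kernel_scalar(D, local_scale(D, 3), np.zeros((8, 8), dtype=int))
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(A, expected, atol=1e-12)

    def test_unit_distance_unit_scales(self):
        # two points at distance 1 with sigma_i = sigma_j = 1
        D = distance_loop(np.array([[0.0], [1.0], [2.0]]))
        A = zelnik_manor_kernel(D, P=1).values
        assert A[0, 1] == pytest.approx(np.exp(-1.0))

    def test_zelnik_never_exceeds_adaptive(self, points8):
        D = pairwise_distances(points8)
        A_ad = adaptive_kernel(D, KernelParams(P=3, S=7)).values
        A_zm = zelnik_manor_kernel(D, P=3).values
        assert np.all(A_zm <= A_ad + 1e-15)

    @pytest.mark.parametrize("builder", ["adaptive", "zelnik"])
    def test_symmetry_and_bounds(self, rng, builder):
        D = pairwise_distances(rng.normal(size=(20, 3)))
        if builder == "adaptive":
            A = adaptive_kernel(D, KernelParams(P=3, S=7)).values
        else:
            A = zelnik_manor_kernel(D, P=3).values
        np.testing.assert_array_equal(A, A.T)
        assert A.min() > 0 and A.max() <= 1.0

    def test_density_effect_monotone_in_shared_neighbours(self, points8):
        # same distances/scales, more common neighbours => similarity
        # can only grow
        D = pairwise_distances(points8)
        sigma = local_scale(D, 3)
        cnn = cnn_loop(D, 7)
        A_lo = kernel_scalar(D, sigma, cnn)
        A_hi = kernel_scalar(D, sigma, cnn + 1)
        assert np.all(A_hi >= A_lo)
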