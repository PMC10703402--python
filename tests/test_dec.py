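"""Deep embedded clustering: soft assignment, target distribution, KL, init."""

import numpy as np
import pytest

from fuseclust._autograd import Tensor
from fuseclust.dec import (hard_labels_and_change, init_centers, kl_loss,
                           kl_loss_tensor, soft_assign, soft_assign_tensor,
                           target_distribution)

from conftest import numerical_grad


class TestSoftAssign:
    def test_equidistant_is_half_half(self):
        z = np.array([[0.0, 0.0]])
        centers = np.array([[1.0, 0.0], [-1.0, 0.0]])
        np.testing.assert_allclose(soft_assign(z, centers), [[0.5, 0.5]])

    def test_on_center_two_thirds(self):
        z = np.array([[0.0]])
        centers = np.array([[0.0], [1.0]])
        np.testing.assert_allclose(soft_assign(z, centers),
                                   [[2.0 / 3.0, 1.0 / 3.0]], atol=1e-9)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(5, 4))
        centers = rng.normal(size=(3, 4))
        q = soft_assign(z, centers)
        for i in range(5):
            nums = [1.0 / (1.0 + np.sum((z[i] - centers[j]) ** 2))
                    for j in range(3)]
            np.testing.assert_allclose(q[i], np.array(nums) / sum(nums),
                                       atol=1e-10)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        q = soft_assign(rng.normal(size=(20, 6)), rng.normal(size=(4, 6)))
        np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-12)

    def test_tensor_version_matches_numpy(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(6, 3))
        c = rng.normal(size=(2, 3))
        q_t = soft_assign_tensor(Tensor(z), Tensor(c))
        np.testing.assert_allclose(q_t.data, soft_assign(z, c), atol=1e-12)


class TestTargetDistribution:
    def test_one_hot_fixed_point(self):
        q = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(target_distribution(q), q)

    def test_symmetric_single_cell_invariant(self):
        np.testing.assert_allclose(target_distribution(np.array([[0.5, 0.5]])),
                                   [[0.5, 0.5]])

    def test_hand_formula_oracle(self):
        q = np.array([[0.8, 0.2], [0.4, 0.6]])
        f = q.sum(axis=0)
        w = q**2 / f
        expected = w / w.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(target_distribution(q), expected, atol=1e-10)

    def test_sharpening_increases_max(self):
        rng = np.random.default_rng(3)
        q = rng.dirichlet(np.ones(5), size=1000)
        p = target_distribution(q)
        assert np.all(p.max(axis=1) >= q.max(axis=1) - 1e-12)

    def test_empty_cluster_column_dropped(self):
        q = np.array([[0.7, 0.3, 0.0], [0.6, 0.4, 0.0]])
        p = target_distribution(q)
        np.testing.assert_array_equal(p[:, 2], 0.0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)


class TestKLLoss:
    def test_identity_zero(self):
        q = np.array([[0.3, 0.7], [0.5, 0.5]])
        assert kl_loss(q, q) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_log2(self):
        assert kl_loss(np.array([[1.0, 0.0]]), np.array([[0.5, 0.5]])) == \
            pytest.approx(np.log(2), abs=1e-9)

    def test_nonnegative_and_matches_loop(self):
        rng = np.random.default_rng(4)
        p = rng.dirichlet(np.ones(4), size=6)
        q = rng.dirichlet(np.ones(4), size=6)
        expected = sum(p[i, j] * np.log(p[i, j] / q[i, j])
                       for i in range(6) for j in range(4))
        val = kl_loss(p, q)
        assert val == pytest.approx(expected, abs=1e-10)
        assert val >= 0

    def test_gradient_through_q_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        z0 = rng.normal(size=(4, 3))
        centers = rng.normal(size=(2, 3))
        p = target_distribution(soft_assign(z0, centers))

        def loss_of_z(z_arr):
            q = soft_assign_tensor(Tensor(z_arr), Tensor(centers))
            return float(kl_loss_tensor(p, q).data)

        z_t = Tensor(z0, requires_grad=True)
        kl_loss_tensor(p, soft_assign_tensor(z_t, Tensor(centers))).backward()
        num = numerical_grad(loss_of_z, z0)
        np.testing.assert_allclose(z_t.grad, num, rtol=1e-4, atol=1e-8)


class TestDistributionProperties:
    """Invariants of Q/P for arbitrary valid soft assignments."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @given(arrays(np.float64, (7, 4),
                  elements=st.floats(1e-3, 1.0)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_target_rows_sum_to_one_and_sharpen(self, raw_q):
        q = raw_q / raw_q.sum(axis=1, keepdims=True)
        p = target_distribution(q)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(p.max(axis=1) >= q.max(axis=1) - 1e-12)
        assert kl_loss(p, q) >= -1e-12

    @given(arrays(np.float64, (6, 3), elements=st.floats(-50.0, 50.0)),
           arrays(np.float64, (2, 3), elements=st.floats(-50.0, 50.0)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_soft_assign_always_a_distribution(self, z, centers):
        q = soft_assign(z, centers)
        assert np.all(q > 0)
        np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-9)


class TestHardLabels:
    def test_no_change(self):
        q = np.array([[0.9, 0.1], [0.2, 0.8]])
        labels, changed = hard_labels_and_change(q, np.array([0, 1]))
        np.testing.assert_array_equal(labels, [0, 1])
        assert changed == 0.0

    def test_tie_takes_lowest_index(self):
        labels, _ = hard_labels_and_change(np.array([[0.5, 0.5]]), np.array([1]))
        assert labels[0] == 0

    def test_fraction_matches_counting_oracle(self):
        rng = np.random.default_rng(6)
        q = rng.dirichlet(np.ones(3), size=50)
        prev = rng.integers(0, 3, 50)
        labels, changed = hard_labels_and_change(q, prev)
        assert changed == pytest.approx(np.sum(labels != prev) / 50)


class TestInitCenters:
    def test_two_separated_blobs_recovered_at_coarse_resolution(self):
        rng = np.random.default_rng(0)
        sigma = 1.0
        blob1 = rng.normal(0.0, sigma, size=(60, 5))
        blob2 = rng.normal(0.0, sigma, size=(60, 5)) + 20.0 * sigma
        z = np.vstack([blob1, blob2])
        state = init_centers(z, resolution=0.5, seed=0, k=10)
        assert state.n_clusters == 2
        # each center close to its blob mean
        means = np.array([blob1.mean(axis=0), blob2.mean(axis=0)])
        tol = 3 * sigma / np.sqrt(60)
        for c in state.centers:
            assert min(np.linalg.norm(c - m) for m in means) < tol * np.sqrt(5)

    def test_resolution_one_never_mixes_separated_blobs(self):
        # resolution 1 may over-partition (the clustering stage later merges
        # redundant centers) but every community stays inside one blob
        rng = np.random.default_rng(1)
        z = np.vstack([rng.normal(size=(40, 3)),
                       rng.normal(size=(40, 3)) + 25.0])
        state = init_centers(z, resolution=1.0, seed=0, k=8)
        blob_of = np.array([0] * 40 + [1] * 40)
        for comm in range(state.n_clusters):
            members = blob_of[state.labels == comm]
            assert len(set(members)) == 1

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(80, 4))
        s1 = init_centers(z, seed=5, k=10)
        s2 = init_centers(z, seed=5, k=10)
        np.testing.assert_array_equal(s1.labels, s2.labels)
        np.testing.assert_array_equal(s1.centers, s2.centers)
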