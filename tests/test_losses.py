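"""Loss terms checked against hand computations and brute-force
double-loop oracles."""

import numpy as np
import pytest

from ccan import (ClusterAlignConfig, loss_class, loss_cluster_align,
                  loss_diff, loss_mmd, loss_recons, total_loss)


class TestRecons:
    def test_perfect_reconstruction_is_zero(self):
        X = np.random.default_rng(0).normal(size=(3, 4))
        assert loss_recons(X, X, X, X) == 0.0

    def test_hand_value(self):
        # (1² + 2²) / 1 cell = 5, target perfectly reconstructed
        v = loss_recons(np.array([[1.0, 2.0]]), np.array([[0.0, 0.0]]),
                        np.ones((2, 2)), np.ones((2, 2)))
        assert np.isclose(v, 5.0)

    def test_per_cell_normalisation(self):
        rng = np.random.default_rng(1)
        X, Xh = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        T = rng.normal(size=(2, 3))
        v1 = loss_recons(X, Xh, T, T)
        v2 = loss_recons(np.vstack([X, X]), np.vstack([Xh, Xh]), T, T)
        assert np.isclose(v1, v2)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            loss_recons(np.ones((2, 3)), np.ones((2, 2)), np.ones((1, 3)),
                        np.ones((1, 3)))


class TestDiff:
    def test_orthogonal_codes_zero(self):
        v = loss_diff(np.array([[1.0], [0.0]]), np.array([[0.0], [1.0]]),
                      np.zeros((1, 1)), np.zeros((1, 1)))
        assert v == 0.0

    def test_hand_value(self):
        v = loss_diff(np.array([[1.0], [1.0]]), np.array([[1.0], [1.0]]),
                      np.zeros((1, 1)), np.zeros((1, 1)))
        assert np.isclose(v, 4.0)  # (1·1 + 1·1)² = 4

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        zss, zsp = rng.normal(size=(10, 3)), rng.normal(size=(10, 1))
        zts, ztp = rng.normal(size=(7, 3)), rng.normal(size=(7, 2))

        def gram_sq(a, b):
            total = 0.0
            for i in range(a.shape[1]):
                for j in range(b.shape[1]):
                    total += (a[:, i] @ b[:, j]) ** 2
            return total

        expected = gram_sq(zss, zsp) + gram_sq(zts, ztp)
        assert np.isclose(loss_diff(zss, zsp, zts, ztp), expected, atol=1e-8)

    def test_invariant_to_simultaneous_row_permutation(self):
        rng = np.random.default_rng(3)
        zss, zsp = rng.normal(size=(8, 3)), rng.normal(size=(8, 1))
        z0 = np.zeros((2, 3)), np.zeros((2, 1))
        perm = rng.permutation(8)
        assert np.isclose(loss_diff(zss, zsp, *z0),
                          loss_diff(zss[perm], zsp[perm], *z0))


class TestMMD:
    def test_identical_samples_zero(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(9, 4))
        assert abs(loss_mmd(z, z[::-1])) < 1e-10

    def test_linear_kernel_equal_means(self):
        v = loss_mmd(np.array([[0.0], [2.0]]), np.array([[1.0], [1.0]]),
                     kernel="linear")
        assert abs(v) < 1e-12

    def test_linear_kernel_unit_gap(self):
        assert np.isclose(loss_mmd(np.array([[0.0]]), np.array([[1.0]]),
                                   kernel="linear"), 1.0)

    def test_symmetric_and_permutation_invariant(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(6, 3)), rng.normal(size=(8, 3))
        v = loss_mmd(a, b)
        assert np.isclose(v, loss_mmd(b, a), atol=1e-12)
        assert np.isclose(v, loss_mmd(a[rng.permutation(6)],
                                      b[rng.permutation(8)]), atol=1e-12)

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError):
            loss_mmd(np.zeros((0, 2)), np.ones((3, 2)))


class TestClassLoss:
    def test_confident_correct_is_zero(self):
        assert loss_class(np.array([[1.0, 0.0]]), np.array([[1.0, 0.0]])) == 0.0

    def test_fifty_fifty_is_log_two(self):
        v = loss_class(np.array([[1.0, 0.0]]), np.array([[0.5, 0.5]]))
        assert np.isclose(v, np.log(2.0))

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(6)
        p = rng.dirichlet(np.ones(3), size=10)
        y = np.eye(3)[rng.integers(3, size=10)]
        perm = rng.permutation(10)
        assert np.isclose(loss_class(y, p), loss_class(y[perm], p[perm]))


class TestClusterAlign:
    CFG = ClusterAlignConfig(margin_m=1.0)

    def test_same_class_identical_codes_zero(self):
        v = loss_cluster_align(np.array([[1.0, 0.0]]), ["a"],
                               np.array([[1.0, 0.0]]), ["a"], self.CFG)
        assert v == 0.0

    def test_saturated_hinge_leaves_centroid_term(self):
        # single source/target pair, different classes would need both classes
        # in both domains; use one cell per class per domain, far apart
        zs = np.array([[0.0], [5.0]])
        zt = np.array([[0.0], [5.0]])
        v = loss_cluster_align(zs, ["a", "b"], zt, ["a", "b"], self.CFG)
        # same-class pairs identical (0), cross pairs at d=25 ≥ m → hinge 0,
        # centroids coincide → total 0
        assert np.isclose(v, 0.0)

    def test_matches_double_loop_oracle(self):
        zs = np.array([[0.0], [0.5], [2.0], [2.5]])
        ls = ["a", "a", "b", "b"]
        zt = np.array([[0.2], [2.2], [0.1]])
        lt = ["a", "b", "a"]
        m = 1.0
        pair_sum = 0.0
        for i in range(4):
            for j in range(3):
                d = (zs[i, 0] - zt[j, 0]) ** 2
                if ls[i] == lt[j]:
                    pair_sum += d
                else:
                    pair_sum += max(0.0, m - d)
        cen = 0.0
        for c in ("a", "b"):
            ms = zs[[i for i in range(4) if ls[i] == c]].mean()
            mt = zt[[j for j in range(3) if lt[j] == c]].mean()
            cen += (ms - mt) ** 2
        expected = pair_sum / 12 + cen / 2
        got = loss_cluster_align(zs, ls, zt, lt, ClusterAlignConfig(margin_m=m))
        assert np.isclose(got, expected, atol=1e-8)

    def test_small_margin_reduces_to_within_class_distances(self):
        rng = np.random.default_rng(7)
        zs, zt = rng.normal(size=(6, 2)), rng.normal(size=(5, 2))
        ls = ["a", "b", "a", "b", "a", "b"]
        lt = ["b", "a", "b", "a", "a"]
        got = loss_cluster_align(zs, ls, zt, lt,
                                 ClusterAlignConfig(margin_m=1e-12))
        within = sum((np.linalg.norm(zs[i] - zt[j]) ** 2)
                     for i in range(6) for j in range(5) if ls[i] == lt[j])
        cen = sum(np.linalg.norm(
            zs[[i for i in range(6) if ls[i] == c]].mean(0)
            - zt[[j for j in range(5) if lt[j] == c]].mean(0)) ** 2
            for c in ("a", "b"))
        assert np.isclose(got, within / 30 + cen / 2, atol=1e-8)

    def test_missing_class_named_in_error(self):
        with pytest.raises(ValueError, match="'b'"):
            loss_cluster_align(np.zeros((2, 1)), ["a", "b"],
                               np.zeros((1, 1)), ["a"], self.CFG)


class TestTotalLoss:
    W = {"recons": 1.0, "diff": 1.0, "mmd": 1.0, "class": 1.0, "ca": 1.0}

    def test_all_zero_terms(self):
        br = total_loss(0.0, 0.0, 0.0, 0.0, 0.0, self.W, "pretrain")
        assert br.total == 0.0

    def test_pretrain_excludes_cluster_alignment(self):
        br = total_loss(1.0, 1.0, 1.0, 1.0, 99.0, self.W, "pretrain")
        assert br.total == 4.0
        assert br.weights["ca"] == 0.0
        assert br.align_ca == 99.0  # still recorded

    def test_refine_includes_cluster_alignment(self):
        br = total_loss(1.0, 1.0, 1.0, 1.0, 99.0, self.W, "refine")
        assert br.total == 103.0

    def test_weighted_hand_sum(self):
        w = dict(self.W, **{"class": 2.0})
        br = total_loss(0.5, 0.25, 0.125, 3.0, 0.0, w, "pretrain")
        assert np.isclose(br.total, 0.5 + 0.25 + 0.125 + 6.0)
        # breakdown identity: total == Σ weight·value
        back = sum(br.weights[k] * v for k, v in
                   [("recons", br.recons), ("diff", br.diff),
                    ("mmd", br.align_mmd), ("class", br.classify),
                    ("ca", br.align_ca)])
        assert np.isclose(br.total, back, atol=1e-8)

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            total_loss(0, 0, 0, 0, 0, self.W, "warmup")


def test_all_losses_nonnegative_on_random_inputs():
    rng = np.random.default_rng(8)
    for _ in range(5):
        zss, zsp = rng.normal(size=(6, 3)), rng.normal(size=(6, 1))
        zts, ztp = rng.normal(size=(5, 3)), rng.normal(size=(5, 1))
        X, Xh = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        T, Th = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        assert loss_recons(X, Xh, T, Th) >= 0
        assert loss_diff(zss, zsp, zts, ztp) >= 0
        assert loss_mmd(zss, zts) >= -1e-12
        probs = rng.dirichlet(np.ones(3), size=6)
        y = np.eye(3)[rng.integers(3, size=6)]
        assert loss_class(y, probs) >= 0
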