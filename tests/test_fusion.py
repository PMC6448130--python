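import numpy as np
import pytest

from conftest import random_knn_instance

from hopes.fusion import (
    FusionConfig,
    direct_solve_oracle,
    hopes_energy,
    hopes_energy_gradient,
    hopes_fuse,
    postprocess_similarity,
    snf_fuse,
    snf_update_step,
    _snf_normalize,
)


def naive_energy(W, S_list, masks, alpha, beta):
    """Term-by-term loop evaluation of the path energy, kept deliberately
    dumb and independent of the vectorised implementation."""
    n = W.shape[0]
    e = 0.0
    for S in S_list:
        for i in range(n):
            for j in range(n):
                e += (W[i, j] - S[i, j]) ** 2
        R1 = W - S @ W
        e += alpha * np.sum(R1**2)
        for Sj in S_list:
            R2 = W - S @ W @ Sj.T
            e += beta * np.sum(R2**2)
    return e


class TestEnergy:
    def test_zero_at_exact_fit_single_layer(self):
        _, S_list, masks = random_knn_instance(8, 1, 0)
        assert hopes_energy(S_list[0], S_list, masks, 0.0, 0.0) == pytest.approx(0.0)

    def test_nonnegative(self, rng):
        _, S_list, masks = random_knn_instance(7, 2, 1)
        for _ in range(5):
            W = rng.normal(size=(7, 7))
            assert hopes_energy(W, S_list, masks, 0.7, 0.3) >= 0.0

    def test_matches_naive_loop(self, rng):
        _, S_list, masks = random_knn_instance(5, 2, 2)
        W = rng.normal(size=(5, 5))
        expected = naive_energy(W, S_list, masks, 1.3, 0.4)
        assert hopes_energy(W, S_list, masks, 1.3, 0.4) == pytest.approx(expected, rel=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        _, S_list, masks = random_knn_instance(5, 2, 3)
        W = rng.normal(size=(5, 5))
        g = hopes_energy_gradient(W, S_list, masks, 0.8, 0.5, ridge=0.1)
        h = 1e-6
        for idx in [(0, 0), (1, 3), (4, 2)]:
            Wp, Wm = W.copy(), W.copy()
            Wp[idx] += h
            Wm[idx] -= h
            fd = (
                hopes_energy(Wp, S_list, masks, 0.8, 0.5)
                + 0.1 * np.sum(Wp**2)
                - hopes_energy(Wm, S_list, masks, 0.8, 0.5)
                - 0.1 * np.sum(Wm**2)
            ) / (2 * h)
            assert g[idx] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_dimension_mismatch_rejected(self):
        _, S_list, masks = random_knn_instance(6, 1, 4)
        with pytest.raises(ValueError):
            hopes_energy(np.zeros((5, 5)), S_list, masks, 1.0, 1.0)


class TestDirectOracle:
    def test_first_order_optimality(self):
        _, S_list, masks = random_knn_instance(10, 2, 5)
        cfg = FusionConfig(alpha=1.0, beta=1.0)
        W = direct_solve_oracle(S_list, masks, cfg)
        g = hopes_energy_gradient(W, S_list, masks, 1.0, 1.0, cfg.ridge)
        assert np.linalg.norm(g) <= 1e-8 * 10

    def test_alpha_beta_zero_closed_form(self):
        _, S_list, masks = random_knn_instance(9, 1, 6)
        cfg = FusionConfig(alpha=0.0, beta=0.0, ridge=1e-8)
        W = direct_solve_oracle(S_list, masks, cfg)
        # single layer, no paths: W = S / (1 + ridge)
        np.testing.assert_allclose(W, S_list[0] / (1 + 1e-8), atol=1e-9)

    def test_refuses_large_n(self):
        _, S_list, masks = random_knn_instance(12, 1, 7)
        big = [np.eye(65)] * 1
        with pytest.raises(ValueError, match="64"):
            direct_solve_oracle(big, big, FusionConfig())


class TestHopesFuse:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_oracle(self, seed):
        C = 2 + seed % 2
        _, S_list, masks = random_knn_instance(12, C, seed)
        cfg = FusionConfig(alpha=1.0, beta=1.0)
        fused, diag = hopes_fuse(S_list, masks, cfg)
        Wo = direct_solve_oracle(S_list, masks, cfg)
        rel = np.linalg.norm(fused.matrix_raw - Wo) / np.linalg.norm(Wo)
        assert fused.converged
        assert rel <= 1e-5

    def test_degenerate_single_layer_closed_form(self):
        _, S_list, masks = random_knn_instance(10, 1, 42)
        cfg = FusionConfig(alpha=0.0, beta=0.0, ridge=1e-8)
        fused, _ = hopes_fuse(S_list, masks, cfg)
        W, S, M = fused.matrix_raw, S_list[0], masks[0]
        assert np.abs(W - S)[M == 1].max() < 1e-6
        assert np.abs(W)[M == 0].max() < 1e-6

    def test_energy_no_worse_than_mean_s_init(self):
        _, S_list, masks = random_knn_instance(12, 3, 8)
        cfg = FusionConfig()
        fused, _ = hopes_fuse(S_list, masks, cfg)
        e0 = fused.energy_trace[0]  # energy at W0 = mean of S_i
        assert fused.energy_trace[-1] <= e0 + 1e-12

    def test_initialization_independence(self, rng):
        # strictly convex objective: two starts agree to ~solver tolerance
        _, S_list, masks = random_knn_instance(12, 2, 9)
        cfg = FusionConfig()
        f1, _ = hopes_fuse(S_list, masks, cfg)
        f2, _ = hopes_fuse(S_list, masks, cfg, W0=rng.normal(size=(12, 12)))
        rel = np.linalg.norm(f1.matrix_raw - f2.matrix_raw) / np.linalg.norm(f1.matrix_raw)
        assert rel <= 1e-4

    def test_permutation_equivariance(self, rng):
        _, S_list, masks = random_knn_instance(12, 2, 10)
        perm = rng.permutation(12)
        cfg = FusionConfig()
        f1, _ = hopes_fuse(S_list, masks, cfg)
        f2, _ = hopes_fuse(
            [S[np.ix_(perm, perm)] for S in S_list],
            [M[np.ix_(perm, perm)] for M in masks],
            cfg,
        )
        np.testing.assert_allclose(
            f2.matrix, f1.matrix[np.ix_(perm, perm)], atol=1e-5
        )

    def test_postprocessed_matrix_is_valid_similarity(self):
        _, S_list, masks = random_knn_instance(12, 2, 11)
        fused, _ = hopes_fuse(S_list, masks, FusionConfig())
        W = fused.matrix
        np.testing.assert_allclose(W, W.T, atol=1e-10)
        assert W.min() >= 0.0
        off = W - np.diag(np.diag(W))
        np.testing.assert_allclose(np.diag(W), off.max(axis=1), atol=1e-12)

    def test_beta_suppresses_single_layer_edges(self):
        # edges backed by one layer only lose mass as the cross-layer
        # filtration weight grows (checked as a trend over seeds)
        counts = {0.0: [], 1.0: [], 3.0: []}
        for seed in range(10):
            _, S_list, masks = random_knn_instance(16, 2, 100 + seed)
            support_count = sum(masks)
            single = (support_count == 1) & ~np.eye(16, dtype=bool)
            for beta in counts:
                fused, _ = hopes_fuse(
                    S_list, masks, FusionConfig(alpha=1.0, beta=beta)
                )
                counts[beta].append(fused.matrix[single].sum())
        means = {b: np.mean(v) for b, v in counts.items()}
        assert means[1.0] <= means[0.0] + 1e-9
        assert means[3.0] <= means[1.0] + 1e-9

    def test_nonconvergence_warns(self):
        _, S_list, masks = random_knn_instance(12, 2, 12)
        cfg = FusionConfig(max_iter=3, tol=1e-12)
        with pytest.warns(RuntimeWarning, match="ADMM"):
            fused, diag = hopes_fuse(S_list, masks, cfg)
        assert not fused.converged
        assert diag.iterations_used == 3


class TestSNF:
    def test_one_step_hand_product(self):
        # 3x3 toy: one raw update step is S (avg of other P) S^T
        S = np.array([[0.0, 0.7, 0.3], [0.5, 0.0, 0.5], [0.2, 0.8, 0.0]])
        P_other = np.array([[0.5, 0.3, 0.2], [0.3, 0.5, 0.2], [0.2, 0.2, 0.6]])
        expected = S @ P_other @ S.T
        np.testing.assert_allclose(snf_update_step(S, P_other), expected, atol=1e-12)

    def test_output_symmetric(self):
        P_list, S_list, _ = random_knn_instance(10, 3, 13)
        fused = snf_fuse(P_list, S_list, iterations=5)
        np.testing.assert_allclose(fused.matrix, fused.matrix.T, atol=1e-12)

    def test_identical_layers_preserve_blocks(self):
        # two identical layers with exact 2-block structure: the fused
        # matrix keeps blocks (within-block mass strictly dominates)
        n = 10
        labels = np.array([0] * 5 + [1] * 5)
        P = np.where(labels[:, None] == labels[None, :], 0.9, 0.05)
        np.fill_diagonal(P, 1.0)
        S = P.copy()
        np.fill_diagonal(S, 0.0)
        S = S / S.sum(axis=1, keepdims=True)
        fused = snf_fuse([P, P], [S, S], iterations=10)
        W = fused.matrix
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(n, dtype=bool)
        assert W[same & off].mean() > 2 * W[~same].mean()

    def test_single_layer_rejected(self):
        P_list, S_list, _ = random_knn_instance(8, 1, 14)
        with pytest.raises(ValueError, match="two layers"):
            snf_fuse(P_list, S_list)

    def test_normalization_row_stochastic_half_diagonal(self):
        P_list, _, _ = random_knn_instance(9, 1, 15)
        Pn = _snf_normalize(P_list[0])
        np.testing.assert_allclose(Pn.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(np.diag(Pn), 0.5, atol=1e-15)


class TestPostprocess:
    def test_idempotent_on_valid_similarity(self, rng):
        W = np.abs(rng.normal(size=(8, 8)))
        W = (W + W.T) / 2
        once = postprocess_similarity(W)
        np.testing.assert_allclose(postprocess_similarity(once), once, atol=1e-14)

    def test_clamps_and_symmetrises(self):
        W = np.array([[1.0, -0.5], [0.3, 1.0]])
        out = postprocess_similarity(W)
        assert out.min() >= 0
        np.testing.assert_allclose(out, out.T)
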