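"""Twin SVM: kernels, dual solutions vs an independent QP oracle, voting."""

import numpy as np
import pytest

from lmdcsp.twsvm import (
    KernelConfig,
    decision_values,
    kernel_matrix,
    ovo_predict,
    predict_binary,
    train_binary,
    train_ovo,
)


from qp_oracle import oracle_box_qp as oracle_dual_solve


def dual_matrices(A, B, kernel, eps_scale=1e-7):
    """Rebuild the two dual QPs exactly as stated, for oracle comparison."""
    C = np.vstack([A, B])
    m1, m2 = len(A), len(B)
    H = np.hstack([kernel_matrix(A, C, kernel), np.ones((m1, 1))])
    G = np.hstack([kernel_matrix(B, C, kernel), np.ones((m2, 1))])
    dim = m1 + m2 + 1
    out = []
    for Hm, Gm in ((H, G), (G, H)):
        HtH = Hm.T @ Hm
        eps = eps_scale * np.trace(HtH) / dim
        Md = Gm @ np.linalg.solve(HtH + eps * np.eye(dim), Gm.T)
        out.append(0.5 * (Md + Md.T))
    return out


class TestKernel:
    def test_gaussian_diagonal_is_one(self, rng):
        X = rng.standard_normal((5, 3))
        K = kernel_matrix(X, X, KernelConfig("gaussian", 1.3))
        assert np.allclose(np.diag(K), 1.0)

    def test_linear_orthonormal_rows(self):
        K = kernel_matrix(np.eye(3), np.eye(3), KernelConfig("linear"))
        assert np.allclose(K, np.eye(3))

    def test_gaussian_hand_computed_points(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        K = kernel_matrix(pts, pts, KernelConfig("gaussian", 1.0))
        d2 = (pts - pts.T) ** 2
        assert np.allclose(K, np.exp(-d2 / 2.0), atol=1e-15)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            KernelConfig("gaussian", 0.0)


class TestTrainBinary:
    def test_separable_toy_perfect_training_accuracy(self, rng):
        A = rng.standard_normal((10, 2))
        B = rng.standard_normal((10, 2)) + 10.0
        model = train_binary(A, B, 1.0, 1.0, KernelConfig("linear"), labels=("a", "b"))
        pred = predict_binary(model, np.vstack([A, B]))
        assert np.array_equal(pred, ["a"] * 10 + ["b"] * 10)

    def test_collinear_class_objective_term_vanishes(self, rng):
        # class A on an exact line: hyperplane 1 can pass through every
        # point, so ||K(A,C')w1 + e b1|| ~ 0 at the optimum
        t = np.linspace(0, 1, 8)
        A = np.column_stack([t, 2 * t + 1])
        B = rng.standard_normal((8, 2)) + np.array([5.0, -5.0])
        model = train_binary(A, B, 1.0, 1.0, KernelConfig("linear"))
        C = model.support_data
        vals = kernel_matrix(A, C, model.kernel) @ model.w1 + model.b1
        norm = np.linalg.norm(model.w1)
        assert np.linalg.norm(vals) < 1e-4 * max(norm, 1.0)

    @pytest.mark.parametrize("kind,lam", [("linear", 1.0), ("gaussian", 1.5)])
    def test_duals_match_interior_point_oracle(self, rng, kind, lam):
        A = rng.standard_normal((3, 2))
        B = rng.standard_normal((3, 2)) + 1.5
        kern = KernelConfig(kind, lam)
        c1 = c2 = 0.8
        model = train_binary(A, B, c1, c2, kern)
        M1, M2 = dual_matrices(A, B, kern)
        for Md, ub, obj in zip((M1, M2), (c1, c2), model.dual_objectives):
            x, fun = oracle_dual_solve(Md, -np.ones(Md.shape[0]), ub)
            assert obj == pytest.approx(-fun, abs=1e-6)

    def test_dual_variables_feasible(self, rng):
        A = rng.standard_normal((6, 3))
        B = rng.standard_normal((5, 3)) + 1.0
        kern = KernelConfig("gaussian", 1.0)
        M1, M2 = dual_matrices(A, B, kern)
        from lmdcsp.twsvm import _box_qp

        for Md, ub in ((M1, 0.5), (M2, 0.5)):
            x = _box_qp(Md, -np.ones(Md.shape[0]), ub)
            assert np.all(x >= -1e-12) and np.all(x <= ub + 1e-12)
            g = Md @ x - 1.0
            # complementary slackness: interior points have ~zero gradient
            interior = (x > 1e-8) & (x < ub - 1e-8)
            if interior.any():
                assert np.max(np.abs(g[interior])) < 1e-6 * max(1.0, np.abs(Md).max())

    def test_class_swap_symmetry(self, rng):
        A = rng.standard_normal((5, 2))
        B = rng.standard_normal((6, 2)) + 2.0
        kern = KernelConfig("linear")
        m_ab = train_binary(A, B, 0.7, 1.3, kern)
        m_ba = train_binary(B, A, 1.3, 0.7, kern)
        # hyperplane 1 of (A,B) plays the role of hyperplane 2 of (B,A);
        # kernel expansions differ by the row permutation of C
        perm = np.concatenate([np.arange(5, 11), np.arange(0, 5)])
        assert np.allclose(m_ab.w1, m_ba.w2[np.argsort(perm)], atol=1e-6)
        assert m_ab.b1 == pytest.approx(m_ba.b2, abs=1e-6)

    def test_monotone_regularization_path(self, rng):
        A = rng.standard_normal((12, 2))
        B = rng.standard_normal((12, 2)) + 1.0  # heavy overlap
        kern = KernelConfig("linear")
        violations = []
        for c1 in (0.01, 0.1, 1.0, 8.0):
            model = train_binary(A, B, c1, 1.0, kern)
            C = model.support_data
            margins = -(kernel_matrix(B, C, kern) @ model.w1 + model.b1)
            violations.append(int(np.sum(margins < 1 - 1e-9)))
        assert all(b >= a for a, b in zip(violations[1:], violations[:-1]))


class TestPrediction:
    def test_training_point_is_nearer_its_own_hyperplane(self, rng):
        A = rng.standard_normal((10, 2))
        B = rng.standard_normal((10, 2)) + 10.0
        model = train_binary(A, B, 1.0, 1.0, KernelConfig("linear"))
        d = decision_values(model, A[0])
        assert d[0, 0] < d[0, 1]

    def test_identical_hyperplanes_tie(self, rng):
        A = rng.standard_normal((4, 2))
        B = rng.standard_normal((4, 2)) + 5.0
        model = train_binary(A, B, 1.0, 1.0, KernelConfig("linear"))
        from dataclasses import replace

        tied = replace(model, w2=model.w1.copy(), b2=model.b1)
        d = decision_values(tied, rng.standard_normal((20, 2)))
        assert np.allclose(d[:, 0], d[:, 1])

    def test_agreement_with_oracle_trained_model(self, rng):
        """Predictions from the package's dual solver match a model whose
        duals were solved by the independent interior-point oracle."""
        A = rng.standard_normal((3, 2))
        B = rng.standard_normal((3, 2)) + 2.0
        kern = KernelConfig("gaussian", 1.2)
        c1 = c2 = 1.0
        model = train_binary(A, B, c1, c2, kern)

        C = np.vstack([A, B])
        m1, m2 = len(A), len(B)
        H = np.hstack([kernel_matrix(A, C, kern), np.ones((m1, 1))])
        G = np.hstack([kernel_matrix(B, C, kern), np.ones((m2, 1))])
        dim = m1 + m2 + 1
        M1, M2 = dual_matrices(A, B, kern)
        a_or, _ = oracle_dual_solve(M1, -np.ones(m2), c1)
        g_or, _ = oracle_dual_solve(M2, -np.ones(m1), c2)
        HtH = H.T @ H
        u1 = -np.linalg.solve(HtH + 1e-7 * np.trace(HtH) / dim * np.eye(dim), G.T @ a_or)
        GtG = G.T @ G
        u2 = np.linalg.solve(GtG + 1e-7 * np.trace(GtG) / dim * np.eye(dim), H.T @ g_or)

        X = rng.standard_normal((100, 2)) * 2
        k = kernel_matrix(X, C, kern)
        d1 = np.abs(k @ u1[:-1] + u1[-1]) / np.linalg.norm(u1[:-1])
        d2 = np.abs(k @ u2[:-1] + u2[-1]) / np.linalg.norm(u2[:-1])
        d_model = decision_values(model, X)
        # the signed margins of both routes must agree, hence the labels too
        assert np.allclose(d_model[:, 0] - d_model[:, 1], d1 - d2, atol=1e-8)
        oracle_pred = np.where(d1 <= d2, "1", "2")
        assert np.array_equal(predict_binary(model, X), oracle_pred)


class TestOVO:
    def _blob_models(self, rng, centers, spread=0.5):
        feats = {
            name: rng.standard_normal((12, 2)) * spread + np.asarray(c)
            for name, c in centers.items()
        }
        return feats, train_ovo(feats, 1.0, 1.0, KernelConfig("gaussian", 2.0))

    def test_majority_vote_wins(self, rng):
        feats, models = self._blob_models(
            rng, {"A": (0, 0), "E": (6, 0), "F": (0, 6)}
        )
        x = np.array([0.1, -0.1])  # clearly class A
        assert ovo_predict(models, x)[0] == "A"

    def test_separated_blobs_fully_recovered(self, rng):
        feats, models = self._blob_models(
            rng, {"A": (0, 0), "E": (8, 0), "F": (0, 8)}, spread=0.4
        )
        test = {name: rng.standard_normal((20, 2)) * 0.4 + np.array(c)
                for name, c in {"A": (0, 0), "E": (8, 0), "F": (0, 8)}.items()}
        for name, X in test.items():
            assert np.all(ovo_predict(models, X) == name)

    def test_circular_tie_resolved_deterministically(self, rng):
        feats, models = self._blob_models(rng, {"A": (0, 0), "E": (4, 0), "F": (2, 3)})
        # centroid region: whatever the votes, output must be deterministic
        x = np.array([[2.0, 1.0]])
        first = ovo_predict(models, x)[0]
        for _ in range(3):
            assert ovo_predict(models, x)[0] == first
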