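import numpy as np
import pytest

from bilat.preprocess import ContextMatrix
from bilat.subspace import (
    alignment_index,
    alignment_null,
    context_pca,
    joint_orthogonal_subspaces,
    relative_difference,
    weight_balance_index,
)


def _cm(matrix, context="contra"):
    matrix = np.asarray(matrix, float)
    matrix = matrix - matrix.mean(axis=1, keepdims=True)
    n, m = matrix.shape
    return ContextMatrix(
        context=context, matrix=matrix, neuron_ids=list(range(n)),
        divisors=np.ones(n), condition_mean=np.zeros((n, m)),
        n_conditions=1, n_time=m,
    )


class TestAlignmentIndex:
    def test_explicit_trace_arithmetic_toy(self):
        cov = np.diag([4.0, 1.0, 0.0])
        basis = np.eye(3)[:, 1:]  # axes 2 and 3
        assert alignment_index(basis, cov, k=2) == pytest.approx(0.2, abs=1e-12)

    def test_self_alignment_is_one_and_orthogonal_is_zero(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((6, 6))
        cov = A @ A.T
        w, V = np.linalg.eigh(cov)
        top = V[:, ::-1][:, :3]
        assert alignment_index(top, cov, 3) == pytest.approx(1.0, abs=1e-10)
        # rank-2 covariance, basis in its null space
        low = np.diag([3.0, 2.0, 0.0, 0.0, 0.0, 0.0])
        assert alignment_index(np.eye(6)[:, 2:5], low, 3) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_under_rotation_away_from_eigenspace(self):
        cov = np.diag([5.0, 2.0, 0.5])
        vals = []
        for theta in np.linspace(0, np.pi / 2, 10):
            # rotate the top-1 eigenvector toward the smallest axis
            b = np.array([[np.cos(theta)], [0.0], [np.sin(theta)]])
            vals.append(alignment_index(b, cov, 1))
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_input_validation(self):
        with pytest.raises(ValueError, match="orthonormal"):
            alignment_index(2 * np.eye(3)[:, :1], np.eye(3))
        with pytest.raises(ValueError, match="semidefinite"):
            alignment_index(np.eye(3)[:, :1], np.diag([1.0, -1.0, 0.0]))


class TestContextPCA:
    def test_rank_one_matrix_fully_captured_by_first_component(self):
        u = np.array([1.0, 2.0, -1.0, 0.5])
        v = np.linspace(-1, 1, 12)
        cm = _cm(np.outer(u, v))
        res = context_pca(cm, k=2)
        assert res.var_captured_own[0] == pytest.approx(1.0, abs=1e-10)

    def test_cumulative_own_variance_matches_eigenvalue_ratio(self):
        rng = np.random.default_rng(1)
        cm = _cm(rng.standard_normal((8, 40)))
        res = context_pca(cm, k=4)
        eig = np.sort(np.linalg.eigvalsh(cm.covariance()))[::-1]
        expect = eig[:4].sum() / eig.sum()
        assert res.cumulative_own[-1] == pytest.approx(expect, abs=1e-10)

    def test_k_larger_than_rank_bound_rejected(self):
        cm = _cm(np.random.default_rng(2).standard_normal((4, 20)))
        with pytest.raises(ValueError, match="k="):
            context_pca(cm, k=5)


class TestAlignmentNull:
    def test_identical_contexts_give_observed_one_and_p_one(self):
        rng = np.random.default_rng(3)
        m = rng.standard_normal((10, 4)) @ rng.standard_normal((4, 60))
        res = alignment_null(_cm(m, "contra"), _cm(m, "ipsi"), k=2, n_boot=200, seed=0)
        assert res.a_contra_on_ipsi == pytest.approx(1.0, abs=1e-8)
        assert res.a_ipsi_on_contra == pytest.approx(1.0, abs=1e-8)
        assert res.p_mean == 1.0

    def test_seeded_null_reproducible(self, default_bundle):
        C, I = default_bundle["C"], default_bundle["I"]
        r1 = alignment_null(C, I, k=10, n_boot=50, seed=9)
        r2 = alignment_null(C, I, k=10, n_boot=50, seed=9)
        assert np.array_equal(r1.null_samples, r2.null_samples)

    def test_rotation_variant_agrees_on_orthogonality_call(self, default_bundle):
        C, I = default_bundle["C"], default_bundle["I"]
        res = alignment_null(C, I, k=10, n_boot=100, seed=1, method="rotation")
        assert res.p_mean < 0.01
        assert res.null_mean > res.mean_index

    def test_too_few_components_for_disjoint_draws_rejected(self):
        # rank 8 supports the PCA at k=8 but not two disjoint 8-sets
        m = np.random.default_rng(4).standard_normal((8, 30))
        with pytest.raises(ValueError, match="components"):
            alignment_null(
                _cm(m, "contra"), _cm(m, "ipsi"), k=8, n_boot=10, seed=0,
                disjoint=True,
            )


class TestJointOrthogonalization:
    def test_disjoint_supports_reach_objective_one_with_exact_bases(self):
        cov_c = np.diag([5.0, 3.0, 2.0, 0, 0, 0])
        cov_i = np.diag([0, 0, 0, 4.0, 2.0, 1.0])
        pair = joint_orthogonal_subspaces(cov_c, cov_i, d=3, seed=0)
        assert pair.objective == pytest.approx(1.0, abs=1e-9)
        s = np.linalg.svd(pair.Q_contra.T @ np.eye(6)[:, :3], compute_uv=False)
        angles = np.degrees(np.arccos(np.clip(s, 0, 1)))
        assert np.all(angles < 1e-4)

    def test_flat_identity_objective_constant_across_restarts(self):
        objs = [
            joint_orthogonal_subspaces(np.eye(8), np.eye(8), d=3, seed=s).objective
            for s in range(10)
        ]
        assert max(objs) - min(objs) < 1e-8

    def test_joint_orthonormality_residual(self, default_bundle):
        pair = joint_orthogonal_subspaces(
            default_bundle["C"].covariance(), default_bundle["I"].covariance(),
            d=3, seed=0,
        )
        assert np.abs(pair.Q_contra.T @ pair.Q_ipsi).max() < 1e-8
        Q = np.concatenate([pair.Q_contra, pair.Q_ipsi], axis=1)
        assert np.allclose(Q.T @ Q, np.eye(6), atol=1e-8)

    def test_never_worse_than_pca_feasible_start(self, default_bundle):
        cov_c = default_bundle["C"].covariance()
        cov_i = default_bundle["I"].covariance()
        wc, Vc = np.linalg.eigh(cov_c)
        wi, Vi = np.linalg.eigh(cov_i)
        start = np.linalg.qr(
            np.concatenate([Vc[:, ::-1][:, :3], Vi[:, ::-1][:, :3]], axis=1)
        )[0]
        sa = np.sort(np.linalg.eigvalsh(cov_c))[::-1][:3].sum()
        sb = np.sort(np.linalg.eigvalsh(cov_i))[::-1][:3].sum()
        f_start = 0.5 * (
            np.trace(start[:, :3].T @ cov_c @ start[:, :3]) / sa
            + np.trace(start[:, 3:].T @ cov_i @ start[:, 3:]) / sb
        )
        pair = joint_orthogonal_subspaces(cov_c, cov_i, d=3, seed=0)
        assert pair.objective >= f_start - 1e-10

    def test_dimension_bound_enforced(self):
        with pytest.raises(ValueError, match="2\\*d"):
            joint_orthogonal_subspaces(np.eye(4), np.eye(4), d=3)


class TestRelativeDifference:
    def test_limits(self):
        ref = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert relative_difference(ref, np.zeros_like(ref)) == pytest.approx(100.0)
        assert relative_difference(ref, ref) == pytest.approx(0.0)
        assert relative_difference(ref, -ref) == pytest.approx(200.0)
        with pytest.raises(ValueError, match="zero norm"):
            relative_difference(np.zeros_like(ref), ref)


class TestWeightBalance:
    def test_extreme_and_balanced_indices(self):
        pcs_c = np.array([[0.0, 0.0], [0.3, 0.4], [0.5, 0.5]])
        pcs_i = np.array([[0.6, 0.2], [0.3, 0.4], [0.0, 0.0]])
        res = weight_balance_index(pcs_c, pcs_i)
        assert res.index[0] == pytest.approx(1.0)  # ipsi-only neuron
        assert res.index[1] == pytest.approx(0.0)  # symmetric loadings
        assert res.index[2] == pytest.approx(-1.0)  # contra-only neuron

    def test_zero_weight_neuron_excluded_with_warning(self):
        pcs = np.array([[0.5, 0.5], [0.0, 0.0]])
        with pytest.warns(UserWarning, match="zero total weight"):
            res = weight_balance_index(pcs, pcs)
        assert res.neuron_ids == [0] and res.excluded == [1]

    def test_two_disjoint_groups_detected_as_non_normal(self):
        rng = np.random.default_rng(5)
        n = 100
        pcs_c = np.abs(rng.normal(0.5, 0.05, (n, 10)))
        pcs_i = np.abs(rng.normal(0.5, 0.05, (n, 10)))
        pcs_c[n // 2 :] *= 0.02  # half the neurons load almost only on ipsi
        pcs_i[: n // 2] *= 0.02
        res = weight_balance_index(pcs_c, pcs_i)
        assert res.ks_p < 0.05

    def test_mixed_population_looks_normal(self, default_bundle):
        pca_c = context_pca(default_bundle["C"], k=10)
        pca_i = context_pca(default_bundle["I"], k=10)
        res = weight_balance_index(pca_c.components, pca_i.components)
        assert res.ks_p > 0.05
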