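import numpy as np
import pytest

from cellfactor.data_io import GeneExpressionMatrix
from cellfactor.decomposition import (
    compute_sigma,
    compute_W,
    compute_W_sampled,
    reconstruct,
    reconstruction_mse,
)
from cellfactor.errors import (
    DegenerateOperatorError,
    ParameterError,
    RankDeficiencyWarning,
    ShapeError,
)
from cellfactor.grn import GRNMatrix

from conftest import random_expr


def expr_from(vals):
    vals = np.asarray(vals, dtype=float)
    return GeneExpressionMatrix(
        [f"g{i}" for i in range(vals.shape[0])],
        [f"c{j}" for j in range(vals.shape[1])],
        vals,
    )


def orthogonal_grn(expr):
    """R whose leading columns are the left singular vectors of A."""
    m = expr.n_genes
    u, *_ = np.linalg.svd(expr.values, full_matrices=True)
    return GRNMatrix(list(expr.gene_ids), u)


class TestComputeSigma:
    def test_identity_matrix(self):
        sigma = compute_sigma(expr_from(np.eye(2)))
        np.testing.assert_allclose(sigma.sigma_values, [1.0, 1.0])

    def test_diagonal_matrix(self):
        sigma = compute_sigma(expr_from(np.diag([3.0, 2.0])))
        np.testing.assert_allclose(sigma.sigma_values, [3.0, 2.0])

    def test_matches_symmetric_eigensolver_oracle(self):
        rng = np.random.default_rng(11)
        A = rng.random((6, 4))
        sigma = compute_sigma(expr_from(A))
        eigvals = np.linalg.eigvalsh(A.T @ A)[::-1]
        np.testing.assert_allclose(sigma.sigma_values, np.sqrt(eigvals), atol=1e-8)

    def test_reconstructs_input(self, rng):
        expr = random_expr(rng, 7, 5)
        s = compute_sigma(expr)
        recon = s.u_matrix @ np.diag(s.sigma_values) @ s.v_matrix.T
        rel = np.linalg.norm(recon - expr.values) / np.linalg.norm(expr.values)
        assert rel < 1e-8

    def test_materialize_shape_and_diagonal(self, rng):
        expr = random_expr(rng, 3, 5)
        s = compute_sigma(expr)
        S = s.materialize()
        assert S.shape == (3, 5)
        np.testing.assert_allclose(np.diag(S[:3, :3]), s.sigma_values)


class TestComputeW:
    def test_scalar_case(self):
        w = compute_W(expr_from([[2.0]]), GRNMatrix(["g0"], np.array([[1.0]])))
        np.testing.assert_allclose(w.w_values, [[1.0]])

    def test_zero_expression_gives_zero_w(self, rng):
        expr = expr_from(np.zeros((3, 3)))
        # Sigma of a zero matrix is zero, so build the operator from a
        # nonzero reference spectrum to keep it well-posed
        ref = random_expr(rng, 3, 3)
        sigma = compute_sigma(ref)
        w = compute_W(
            expr_from(np.zeros((3, 3))),
            GRNMatrix(expr.gene_ids, np.eye(3)),
            sigma=sigma,
        )
        np.testing.assert_allclose(w.w_values, 0.0)

    def test_zero_operator_is_degenerate(self, rng):
        expr = random_expr(rng, 3, 3)
        with pytest.raises(DegenerateOperatorError):
            compute_W(expr, GRNMatrix(expr.gene_ids, np.zeros((3, 3))))

    def test_orthogonal_grn_recovers_right_singular_vectors(self, rng):
        expr = random_expr(rng, 8, 5)
        grn = orthogonal_grn(expr)
        sigma = compute_sigma(expr)
        w = compute_W(expr, grn)
        np.testing.assert_allclose(w.w_values[:5], sigma.v_matrix.T, atol=1e-8)

    def test_matches_dense_pseudoinverse_oracle(self, rng):
        for _ in range(10):
            m, n = rng.integers(2, 21, size=2)
            expr = random_expr(rng, m, n)
            R = rng.normal(size=(m, m))
            grn = GRNMatrix(list(expr.gene_ids), R)
            sigma = compute_sigma(expr)
            RS = R @ sigma.materialize()
            expected = np.linalg.pinv(RS) @ expr.values
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RankDeficiencyWarning)
                w = compute_W(expr, grn)
            rel = np.linalg.norm(w.w_values - expected) / max(np.linalg.norm(expected), 1e-30)
            assert rel < 1e-8

    def test_scale_equivariance(self, rng):
        expr = random_expr(rng, 6, 4)
        grn = GRNMatrix(list(expr.gene_ids), rng.normal(size=(6, 6)))
        sigma = compute_sigma(expr)
        w1 = compute_W(expr, grn, sigma=sigma)
        scaled = GeneExpressionMatrix(expr.gene_ids, expr.cell_ids, 3.0 * expr.values)
        w2 = compute_W(scaled, grn, sigma=sigma)
        np.testing.assert_allclose(w2.w_values, 3.0 * w1.w_values, atol=1e-8)

    def test_rank_cap(self, rng):
        expr = random_expr(rng, 5, 8)
        R = np.outer(rng.random(5), rng.random(5))  # rank-1 GRN
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RankDeficiencyWarning)
            w = compute_W(expr, GRNMatrix(list(expr.gene_ids), R))
        assert np.linalg.matrix_rank(w.w_values, tol=1e-10) <= 1


class TestReconstruction:
    def test_zero_w_reconstructs_zero(self, rng):
        expr = random_expr(rng, 4, 3)
        grn = GRNMatrix(list(expr.gene_ids), rng.normal(size=(4, 4)))
        sigma = compute_sigma(expr)
        from cellfactor.decomposition import CommunicationMatrix

        w = CommunicationMatrix(list(expr.cell_ids), np.zeros((3, 3)))
        np.testing.assert_allclose(reconstruct(grn, sigma, w), 0.0)

    def test_full_rank_orthogonal_grn_reconstructs_exactly(self, rng):
        expr = random_expr(rng, 6, 4)
        grn = orthogonal_grn(expr)
        sigma = compute_sigma(expr)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RankDeficiencyWarning)
            w = compute_W(expr, grn, sigma=sigma)
        recon = reconstruct(grn, sigma, w)
        assert reconstruction_mse(expr, recon) < 1e-8

    def test_residual_orthogonal_to_operator_columns(self, rng):
        expr = random_expr(rng, 8, 6)
        grn = GRNMatrix(list(expr.gene_ids), rng.normal(size=(8, 8)))
        sigma = compute_sigma(expr)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RankDeficiencyWarning)
            w = compute_W(expr, grn, sigma=sigma)
        RS = grn.weights @ sigma.materialize()
        residual = expr.values - reconstruct(grn, sigma, w)
        assert np.abs(RS.T @ residual).max() < 1e-6

    def test_mse_examples_and_oracle(self, rng):
        a = random_expr(rng, 5, 4)
        assert reconstruction_mse(a, a.values) == 0.0
        assert reconstruction_mse(expr_from([[1.0]]), np.array([[0.0]])) == 1.0
        recon = rng.random((5, 4))
        total = 0.0
        for i in range(5):
            for j in range(4):
                total += (a.values[i, j] - recon[i, j]) ** 2
        assert reconstruction_mse(a, recon) == pytest.approx(total / 20, abs=1e-12)
        with pytest.raises(ShapeError):
            reconstruction_mse(a, np.zeros((2, 2)))


class TestSampledW:
    def test_delegates_when_cells_do_not_exceed_genes(self, rng):
        expr = random_expr(rng, 6, 5)
        grn = GRNMatrix(list(expr.gene_ids), rng.normal(size=(6, 6)))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RankDeficiencyWarning)
            w1 = compute_W_sampled(expr, grn, seed=0)
            w2 = compute_W(expr, grn)
        np.testing.assert_array_equal(w1.w_values, w2.w_values)

    def test_deterministic_under_seed(self, rng):
        expr = random_expr(rng, 5, 9)
        grn = GRNMatrix(list(expr.gene_ids), rng.normal(size=(5, 5)))
        w1 = compute_W_sampled(expr, grn, seed=7)
        w2 = compute_W_sampled(expr, grn, seed=7)
        np.testing.assert_array_equal(w1.w_values, w2.w_values)

    def test_batch_size_bounds(self, rng):
        expr = random_expr(rng, 5, 9)
        grn = GRNMatrix(list(expr.gene_ids), rng.normal(size=(5, 5)))
        with pytest.raises(ParameterError):
            compute_W_sampled(expr, grn, batch_size=6, seed=0)
        with pytest.raises(ParameterError):
            compute_W_sampled(expr, grn, batch_size=1, seed=0)

    def test_every_pair_covered(self, rng):
        expr = random_expr(rng, 5, 12)
        grn = GRNMatrix(list(expr.gene_ids), rng.normal(size=(5, 5)))
        w = compute_W_sampled(expr, grn, batch_size=4, seed=3)
        assert np.all(np.isfinite(w.w_values))  # a NaN would mark an uncovered pair

    def test_agrees_with_square_padded_configuration(self):
        # gene-padding the matrix to square and solving exactly is an
        # independent route to the same type-level network
        import scipy.stats

        from cellfactor.grn import infer_grn
        from cellfactor.network import aggregate_to_types, resolve_directions
        from cellfactor.simulate import make_planted_dataset

        rhos = []
        for seed in range(1, 6):
            expr, labels, _ = make_planted_dataset(seed, 40, 60, 2, 1, 0.3)
            grn = infer_grn(expr, seed=seed)
            ws = compute_W_sampled(expr, grn, seed=seed, ridge=0.1)
            ts = aggregate_to_types(resolve_directions(ws), labels)
            pad = 20
            padded = GeneExpressionMatrix(
                expr.gene_ids + [f"pad{i}" for i in range(pad)],
                expr.cell_ids,
                np.vstack([expr.values, np.zeros((pad, 60))]),
            )
            pw = np.zeros((60, 60))
            pw[:40, :40] = grn.weights
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RankDeficiencyWarning)
                wf = compute_W(padded, GRNMatrix(padded.gene_ids, pw), ridge=0.1)
            tf = aggregate_to_types(resolve_directions(wf), labels)
            rhos.append(
                scipy.stats.spearmanr(ts.strengths.ravel(), tf.strengths.ravel()).statistic
            )
        assert np.median(rhos) >= 0.8
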