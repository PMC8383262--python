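import numpy as np
import pytest

from funfanova import (
    MFPCA,
    FunctionalSample,
    assemble_multivariate,
    make_bspline_basis,
    reconstruct,
    select_num_components,
)
from funfanova.basis import BSplineBasis

from .conftest import random_functional_sample
from .oracles import mfpca_scores_by_integration


def orthonormal_basis(p):
    """Synthetic basis whose Gram matrix is the identity (W = I)."""
    return BSplineBasis(
        domain=(0.0, 1.0), order=1, n_basis=p,
        knots=np.linspace(0.0, 1.0, p + 1), gram=np.eye(p),
    )


def bivariate_sample(rng, n=12, p1=6, p2=9, groups=None):
    b1 = make_bspline_basis((0, 1), p1, 4)
    b2 = make_bspline_basis((0, 1), p2, 4)
    ids = [f"u{i}" for i in range(n)]
    v1 = FunctionalSample(basis=b1, coefficients=rng.standard_normal((n, p1)),
                          unit_ids=ids, variable_name="A")
    v2 = FunctionalSample(basis=b2, coefficients=rng.standard_normal((n, p2)),
                          unit_ids=ids, variable_name="B")
    return assemble_multivariate([v1, v2], group_labels=groups)


class TestAssembly:
    def test_single_variable_reduces_to_its_own_blocks(self, cubic7, rng):
        v = random_functional_sample(cubic7, 5, rng)
        mv = assemble_multivariate([v])
        assert np.array_equal(mv.stacked_coefficients, v.coefficients)
        assert np.array_equal(mv.block_gram, cubic7.gram)

    def test_block_diagonal_structure(self, rng):
        mv = bivariate_sample(rng, n=6, p1=5, p2=4)
        W = mv.block_gram
        assert W.shape == (9, 9)
        assert np.all(W[:5, 5:] == 0) and np.all(W[5:, :5] == 0)
        assert np.any(W[:5, :5] != 0) and np.any(W[5:, 5:] != 0)

    def test_unit_permutation_leaves_eigenvalues_unchanged(self, rng):
        mv = bivariate_sample(rng, n=8)
        perm = rng.permutation(8)
        permuted = assemble_multivariate(
            [
                FunctionalSample(
                    basis=v.basis,
                    coefficients=v.coefficients[perm],
                    unit_ids=[v.unit_ids[i] for i in perm],
                    variable_name=v.variable_name,
                )
                for v in mv.variables
            ]
        )
        ev1 = MFPCA(mv).fit().eigenvalues
        ev2 = MFPCA(permuted).fit().eigenvalues
        assert np.allclose(ev1, ev2)

    def test_mismatched_units_rejected(self, cubic7, rng):
        v1 = random_functional_sample(cubic7, 5, rng)
        v2 = random_functional_sample(cubic7, 6, rng)
        with pytest.raises(ValueError):
            assemble_multivariate([v1, v2])


class TestFit:
    def test_identity_gram_equals_ordinary_pca(self, rng):
        p, n = 6, 15
        basis = orthonormal_basis(p)
        A = rng.standard_normal((n, p))
        v = FunctionalSample(basis=basis, coefficients=A,
                             unit_ids=[f"u{i}" for i in range(n)])
        res = MFPCA(assemble_multivariate([v])).fit()
        # ordinary PCA oracle via SVD of the centered matrix
        Ac = A - A.mean(axis=0)
        U, s, Vt = np.linalg.svd(Ac, full_matrices=False)
        lam = s ** 2 / (n - 1)
        assert np.allclose(res.eigenvalues, lam[: res.n_components], atol=1e-10)
        pc_scores = Ac @ Vt.T
        for m in range(res.n_components):
            a, b = res.scores[:, m], pc_scores[:, m]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_rank_one_variation(self, cubic7):
        direction = np.linspace(-1, 1, 7)
        t = np.linspace(-2, 2, 9)
        A = 1.5 + t[:, None] * direction[None, :]
        v = FunctionalSample(basis=cubic7, coefficients=A,
                             unit_ids=[f"u{i}" for i in range(9)])
        res = MFPCA(assemble_multivariate([v])).fit()
        assert res.eigenvalues[0] > 0
        assert np.allclose(res.eigenvalues[1:], 0, atol=1e-10)
        assert res.cumulative_explained[0] == pytest.approx(1.0)
        assert select_num_components(res, 0.99) == 1

    def test_score_covariance_is_diagonal_eigenvalues(self, rng):
        res = MFPCA(bivariate_sample(rng)).fit()
        S = np.cov(res.scores, rowvar=False, ddof=1)
        assert np.abs(S - np.diag(res.eigenvalues)).max() < 1e-8
        assert np.abs(res.scores.mean(axis=0)).max() < 1e-10

    def test_weight_functions_orthonormal(self, rng):
        mv = bivariate_sample(rng)
        res = MFPCA(mv).fit()
        G = res.loadings_b @ mv.block_gram @ res.loadings_b.T
        assert np.abs(G - np.eye(res.n_components)).max() < 1e-8

    def test_eigenvalue_sum_matches_total_variance(self, rng):
        mv = bivariate_sample(rng)
        res = MFPCA(mv).fit()
        A = mv.stacked_coefficients
        Ac = A - A.mean(axis=0)
        Sigma = Ac.T @ Ac / (A.shape[0] - 1)
        W = mv.block_gram
        sqrtW = _sym_sqrt(W)
        assert res.eigenvalues.sum() == pytest.approx(
            np.trace(sqrtW @ Sigma @ sqrtW), abs=1e-8
        )

    def test_scores_match_integral_definition(self, rng):
        res = MFPCA(bivariate_sample(rng)).fit()
        ref = mfpca_scores_by_integration(res, grid_size=10_001)
        assert np.abs(res.scores - ref).max() < 1e-6

    def test_orthogonal_invariance_of_eigenvalues(self, rng):
        p, n = 5, 10
        basis = orthonormal_basis(p)
        A = rng.standard_normal((n, p))
        Q, _ = np.linalg.qr(rng.standard_normal((p, p)))
        ids = [f"u{i}" for i in range(n)]
        ev1 = MFPCA(assemble_multivariate([
            FunctionalSample(basis=basis, coefficients=A, unit_ids=ids)
        ])).fit().eigenvalues
        ev2 = MFPCA(assemble_multivariate([
            FunctionalSample(basis=basis, coefficients=A @ Q, unit_ids=ids)
        ])).fit().eigenvalues
        assert np.allclose(ev1, ev2, atol=1e-9)

    def test_standardization_balances_variables(self, rng):
        mv = bivariate_sample(rng, n=20)
        # inflate the first variable by a large factor
        scaled = assemble_multivariate(
            [
                FunctionalSample(
                    basis=mv.variables[0].basis,
                    coefficients=mv.variables[0].coefficients * 100.0,
                    unit_ids=mv.variables[0].unit_ids,
                    variable_name="A",
                ),
                mv.variables[1],
            ]
        )
        raw = MFPCA(scaled, standardize=False).fit()
        std = MFPCA(scaled, standardize=True).fit()
        # without standardization the inflated variable dominates PC1
        assert raw.explained[0] > std.explained[0]

    def test_too_few_units_rejected(self, cubic7, rng):
        v = random_functional_sample(cubic7, 1, rng)
        with pytest.raises(ValueError):
            MFPCA(assemble_multivariate([v])).fit()


def _sym_sqrt(W):
    w, V = np.linalg.eigh(W)
    return (V * np.sqrt(np.clip(w, 0, None))) @ V.T


class TestSelectionAndReconstruction:
    @pytest.mark.parametrize(
        "threshold,expected", [(0.99, 4), (0.9, 3), (0.7, 2), (0.4, 1)]
    )
    def test_component_selection_rule(self, threshold, expected, rng):
        # engineer a spectrum proportional to (4, 3, 2, 1)
        res = _result_with_spectrum(rng, np.array([4.0, 3.0, 2.0, 1.0]))
        assert select_num_components(res, threshold) == expected

    def test_threshold_validation(self, rng):
        res = _result_with_spectrum(rng, np.array([2.0, 1.0]))
        with pytest.raises(ValueError):
            select_num_components(res, 0.0)

    def test_full_rank_reconstruction_is_exact(self, rng):
        mv = bivariate_sample(rng, n=20, p1=5, p2=4)
        res = MFPCA(mv).fit()
        rec = reconstruct(res, res.n_components)
        assert np.abs(rec - mv.stacked_coefficients).max() < 1e-8

    def test_rank_one_data_reconstructed_by_first_component(self, cubic7):
        direction = np.sin(np.linspace(0, 3, 7))
        t = np.linspace(-1, 1, 6)
        A = 0.5 + t[:, None] * direction[None, :]
        v = FunctionalSample(basis=cubic7, coefficients=A,
                             unit_ids=[f"u{i}" for i in range(6)])
        res = MFPCA(assemble_multivariate([v])).fit()
        assert np.abs(reconstruct(res, 1) - A).max() < 1e-8

    def test_reconstruction_energy_identity(self, rng):
        mv = bivariate_sample(rng, n=10)
        res = MFPCA(mv).fit()
        W = mv.block_gram
        n = mv.n_units
        for q in (1, 2, 4):
            resid = mv.stacked_coefficients - reconstruct(res, q)
            # integrated squared error summed over units, in the W metric
            ise = np.einsum("ij,jk,ik->", resid, W, resid)
            assert ise == pytest.approx(
                (n - 1) * res.eigenvalues[q:].sum(), rel=1e-6, abs=1e-10
            )

    def test_q_out_of_range(self, rng):
        res = MFPCA(bivariate_sample(rng)).fit()
        with pytest.raises(ValueError):
            reconstruct(res, 0)
        with pytest.raises(ValueError):
            reconstruct(res, res.n_components + 1)

    def test_cumulative_explained_monotone_reaching_one(self, rng):
        res = MFPCA(bivariate_sample(rng, n=8)).fit()
        cum = res.cumulative_explained
        assert np.all(np.diff(cum) >= -1e-12)
        assert cum[-1] == pytest.approx(1.0, abs=1e-8)


def _result_with_spectrum(rng, lam):
    """Fit data engineered to have eigenvalues proportional to ``lam``."""
    p = lam.size
    n = 50 * p
    basis = orthonormal_basis(p)
    Z = rng.standard_normal((n, p))
    Z = (Z - Z.mean(axis=0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(Z.T))).T
    A = Z * np.sqrt(lam)
    v = FunctionalSample(basis=basis, coefficients=A,
                         unit_ids=[f"u{i}" for i in range(n)])
    return MFPCA(assemble_multivariate([v])).fit()
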