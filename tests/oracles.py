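"""Independent reference implementations used only as test oracles.

Everything here works pointwise on evaluated curves (dense grids) or by
direct recursion/enumeration, deliberately avoiding the coefficient-space
shortcuts of the package under test.
"""

import itertools

import numpy as np
from scipy.integrate import simpson


def deboor_basis_value(knots, order, i, t):
    """Cox-de Boor recursion for one B-spline basis function value."""
    d = order - 1
    if d == 0:
        # closed right end on the last non-empty interval
        if knots[i] <= t < knots[i + 1]:
            return 1.0
        if t == knots[i + 1] and knots[i + 1] == knots[-1] and knots[i] < knots[i + 1]:
            return 1.0
        return 0.0
    left = 0.0
    if knots[i + d] > knots[i]:
        left = (t - knots[i]) / (knots[i + d] - knots[i]) * deboor_basis_value(
            knots, order - 1, i, t
        )
    right = 0.0
    if knots[i + d + 1] > knots[i + 1]:
        right = (knots[i + d + 1] - t) / (
            knots[i + d + 1] - knots[i + 1]
        ) * deboor_basis_value(knots, order - 1, i + 1, t)
    return left + right


def deboor_design_matrix(basis, t):
    return np.array(
        [
            [deboor_basis_value(basis.knots, basis.order, i, tt)
             for i in range(basis.n_basis)]
            for tt in np.atleast_1d(t)
        ]
    )


def pointwise_kernel(sample, grid):
    """K(t,t) from evaluated curves by the direct sample formula."""
    X1 = sample.coeff_cond1 @ sample.basis.design_matrix(grid).T
    X2 = sample.coeff_cond2 @ sample.basis.design_matrix(grid).T
    n = X1.shape[0]
    diff = (X1 - X1.mean(axis=0)) - (X2 - X2.mean(axis=0))
    return (diff ** 2).sum(axis=0) / (n - 1)


def cn_trapezoid(sample, grid_size=10001):
    grid = np.linspace(*sample.basis.domain, grid_size)
    Phi = sample.basis.design_matrix(grid)
    X1 = sample.coeff_cond1 @ Phi.T
    X2 = sample.coeff_cond2 @ Phi.T
    n = X1.shape[0]
    sq = (X1.mean(axis=0) - X2.mean(axis=0)) ** 2
    return n * np.trapezoid(sq, grid)


def dn_en_pointwise(sample, grid_size=1001):
    """D_n and E_n computed from scratch on evaluated curves."""
    grid = np.linspace(*sample.basis.domain, grid_size)
    Phi = sample.basis.design_matrix(grid)
    X1 = sample.coeff_cond1 @ Phi.T
    X2 = sample.coeff_cond2 @ Phi.T
    n = X1.shape[0]
    num = n * (X1.mean(axis=0) - X2.mean(axis=0)) ** 2
    diff = (X1 - X1.mean(axis=0)) - (X2 - X2.mean(axis=0))
    K = (diff ** 2).sum(axis=0) / (n - 1)
    K = np.maximum(K, 1e-12 * K.max())
    ratio = num / K
    return simpson(ratio, x=grid), ratio.max()


def naive_permutation_distribution(sample, statistic_fn, patterns=None):
    """Recompute a statistic for explicit row swaps of the two conditions."""
    from funfanova import PairedFunctionalSample

    n = sample.n_units
    if patterns is None:
        patterns = list(itertools.product([0, 1], repeat=n))
    values = []
    for pat in patterns:
        A1 = sample.coeff_cond1.copy()
        A2 = sample.coeff_cond2.copy()
        for j, swap in enumerate(pat):
            if swap:
                A1[j], A2[j] = sample.coeff_cond2[j].copy(), sample.coeff_cond1[j].copy()
        swapped = PairedFunctionalSample(
            basis=sample.basis, coeff_cond1=A1, coeff_cond2=A2,
            unit_ids=sample.unit_ids,
        )
        values.append(statistic_fn(swapped))
    return np.array(values)


def mfpca_scores_by_integration(result, grid_size=10001):
    """Scores via direct quadrature of the integral definition."""
    mv = result.model.sample
    grid = np.linspace(0.0, 1.0, grid_size)
    n = mv.n_units
    M = result.n_components
    scores = np.zeros((n, M))
    for h, sl in enumerate(mv.block_slices()):
        Phi = mv.variables[h].basis.design_matrix(grid)
        Xc = (mv.stacked_coefficients[:, sl] - result.mean_coefficients[sl]) @ Phi.T
        if result.model.standardize:
            Xc = Xc / result.standardize_scales[h]
        F = result.loadings_b[:, sl] @ Phi.T  # (M, grid)
        for m in range(M):
            scores[:, m] += simpson(Xc * F[m][None, :], x=grid, axis=1)
    return scores
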