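"""Multivariate functional principal component analysis (MFPCA).

For an H-variate functional sample expanded in per-variable bases, the
covariance eigen-problem ``C f_m = lambda_m f_m`` reduces to matrix algebra
on the stacked coefficient matrix ``A`` (``n x sum_h p_h``) and the
block-diagonal Gram matrix ``W`` of basis inner products:

    Sigma_A W b_m' = lambda_m b_m',

where ``b_m`` carries the basis coefficients of the weight functions
``f_m(t) = Phi(t) b_m'``.  Substituting ``u_m = b_m W^{1/2}`` turns this
into the symmetric eigen-problem of ``W^{1/2} Sigma_A W^{1/2}`` — i.e. the
MFPCA is the ordinary PCA of ``A W^{1/2}``.  Component scores are
``xi_ijm = a_ij' W b_m`` and the curves admit the truncated Karhunen-Loeve
reconstruction ``X^q = mu + sum_{m<=q} xi_m f_m``.

The number of retained components ``q`` is chosen so the cumulative
explained variability reaches a threshold (0.99 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import block_diag

from .basis import FunctionalSample

__all__ = [
    "MultivariateFunctionalSample",
    "assemble_multivariate",
    "MFPCA",
    "MFPCAResults",
    "select_num_components",
    "reconstruct",
]

_EIG_CLIP_REL = 1e-12


@dataclass
class MultivariateFunctionalSample:
    """H functional variables observed on the same ``n`` units.

    ``stacked_coefficients`` is the row-wise concatenation ``A`` of the
    per-variable coefficient matrices (block order = variable order) and
    ``block_gram`` the matching block-diagonal inner-product matrix ``W``.
    """

    variables: list[FunctionalSample]
    group_labels: np.ndarray | None = None
    stacked_coefficients: np.ndarray = field(init=False, repr=False)
    block_gram: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("at least one functional variable is required")
        first = self.variables[0]
        for v in self.variables[1:]:
            if v.n_units != first.n_units:
                raise ValueError("all variables must share the number of units")
            if v.unit_ids != first.unit_ids:
                raise ValueError("all variables must share the unit ordering")
        self.stacked_coefficients = np.hstack(
            [v.coefficients for v in self.variables]
        )
        self.block_gram = block_diag(*[v.basis.gram for v in self.variables])
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels)
            if self.group_labels.shape[0] != first.n_units:
                raise ValueError("one group label per unit is required")

    @property
    def n_units(self) -> int:
        return self.variables[0].n_units

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def block_dims(self) -> list[int]:
        return [v.basis.n_basis for v in self.variables]

    @property
    def unit_ids(self) -> list[str]:
        return list(self.variables[0].unit_ids)

    def block_slices(self) -> list[slice]:
        edges = np.concatenate([[0], np.cumsum(self.block_dims)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def assemble_multivariate(
    samples: list[FunctionalSample], group_labels=None
) -> MultivariateFunctionalSample:
    """Stack per-variable samples into one multivariate sample."""
    return MultivariateFunctionalSample(
        variables=list(samples),
        group_labels=None if group_labels is None else np.asarray(group_labels),
    )


def _symmetric_sqrt(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric square root and pseudo-inverse square root of a PSD matrix."""
    w, V = np.linalg.eigh(0.5 * (W + W.T))
    tol = _EIG_CLIP_REL * max(w.max(initial=0.0), 0.0)
    w = np.where(w > tol, w, 0.0)
    if np.any(w == 0.0):
        warnings.warn(
            "Gram matrix numerically singular; pseudo-inverse used for the "
            "weight-function coefficients",
            RuntimeWarning,
            stacklevel=3,
        )
    sqrt_w = np.sqrt(w)
    inv_sqrt = np.where(sqrt_w > 0, 1.0 / np.where(sqrt_w > 0, sqrt_w, 1.0), 0.0)
    return (V * sqrt_w) @ V.T, (V * inv_sqrt) @ V.T


class MFPCA:
    """Multivariate functional PCA model.

    Parameters
    ----------
    sample : MultivariateFunctionalSample
        Stacked coefficient representation of the H-variate curves.
    standardize : bool, optional
        If True, each variable's centered coefficients are divided by the
        square root of its integrated total variance before the joint PCA
        (useful when variables live on very different scales).  Off by
        default.
    """

    def __init__(self, sample: MultivariateFunctionalSample, standardize: bool = False):
        self.sample = sample
        self.standardize = standardize

    def fit(self, n_components: int | None = None) -> "MFPCAResults":
        mv = self.sample
        A = mv.stacked_coefficients
        n, P = A.shape
        if n < 2:
            raise ValueError(f"need at least 2 units, got {n}")
        mean = A.mean(axis=0)
        Ac = A - mean

        scales = np.ones(mv.n_variables)
        if self.standardize:
            for h, sl in enumerate(mv.block_slices()):
                Wh = mv.variables[h].basis.gram
                Sh = Ac[:, sl].T @ Ac[:, sl] / (n - 1)
                total_var = float(np.trace(Sh @ Wh))
                if total_var > 0:
                    scales[h] = np.sqrt(total_var)
                    Ac[:, sl] = Ac[:, sl] / scales[h]

        W = mv.block_gram
        sqrtW, inv_sqrtW = _symmetric_sqrt(W)
        Sigma_A = Ac.T @ Ac / (n - 1)
        S = sqrtW @ Sigma_A @ sqrtW
        S = 0.5 * (S + S.T)
        evals, evecs = np.linalg.eigh(S)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        total_variance = float(np.clip(evals, 0.0, None).sum())
        M = min(n - 1, P) if n_components is None else min(n_components, P)
        evals = np.clip(evals[:M], 0.0, None)
        U = evecs[:, :M].T  # rows u_m, orthonormal

        # sign convention: largest-magnitude entry of each u_m positive
        flip = np.sign(U[np.arange(M), np.abs(U).argmax(axis=1)])
        flip[flip == 0] = 1.0
        U = U * flip[:, None]

        B = U @ inv_sqrtW           # rows b_m: f_m(t) = Phi(t) b_m'
        scores = Ac @ sqrtW @ U.T   # = Ac @ W @ B.T on the retained spectrum
        explained = evals / total_variance if total_variance > 0 else evals
        return MFPCAResults(
            model=self,
            mean_coefficients=mean,
            eigenvalues=evals,
            loadings_u=U,
            loadings_b=B,
            scores=scores,
            explained=explained,
            total_variance=total_variance,
            standardize_scales=scales,
        )


@dataclass
class MFPCAResults:
    """Eigenvalues, weight functions, scores of a fitted multivariate FPCA.

    ``loadings_b`` rows are the basis coefficients of the weight functions
    ``f_m``; ``scores[i, m]`` is the m-th principal component score of unit
    ``i``; ``explained`` holds per-component variance fractions.
    """

    model: MFPCA
    mean_coefficients: np.ndarray
    eigenvalues: np.ndarray
    loadings_u: np.ndarray
    loadings_b: np.ndarray
    scores: np.ndarray
    explained: np.ndarray
    total_variance: float
    standardize_scales: np.ndarray

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    @property
    def cumulative_explained(self) -> np.ndarray:
        return np.cumsum(self.explained)

    def select_num_components(self, threshold: float = 0.99) -> int:
        return select_num_components(self, threshold)

    def reconstruct(self, q: int) -> np.ndarray:
        return reconstruct(self, q)

    def weight_function_values(self, grid: np.ndarray) -> np.ndarray:
        """Evaluate weight functions -> (M, H, len(grid)) array."""
        mv = self.model.sample
        out = np.zeros((self.n_components, mv.n_variables, len(grid)))
        for h, sl in enumerate(mv.block_slices()):
            Phi = mv.variables[h].basis.design_matrix(grid)
            out[:, h, :] = self.loadings_b[:, sl] @ Phi.T
        return out

    def summary(self) -> str:
        lines = [
            "Multivariate functional PCA",
            f"  variables  : H = {self.model.sample.n_variables} "
            f"({', '.join(v.variable_name or '?' for v in self.model.sample.variables)})",
            f"  units      : n = {self.model.sample.n_units}",
            f"  components : {self.n_components} retained",
            "",
            f"  {'m':>3}  {'eigenvalue':>12}  {'explained':>9}  {'cumulative':>10}",
        ]
        cum = self.cumulative_explained
        for m in range(self.n_components):
            lines.append(
                f"  {m + 1:>3}  {self.eigenvalues[m]:12.5g}"
                f"  {self.explained[m]:9.4f}  {cum[m]:10.4f}"
            )
        return "\n".join(lines)


def select_num_components(result: MFPCAResults, threshold: float = 0.99) -> int:
    """Smallest q whose cumulative explained variability reaches threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    cum = result.cumulative_explained
    idx = np.nonzero(cum >= threshold - 1e-12)[0]
    return int(idx[0]) + 1 if idx.size else result.n_components


def reconstruct(result: MFPCAResults, q: int) -> np.ndarray:
    """Truncated Karhunen-Loeve reconstruction as stacked coefficients."""
    if not 1 <= q <= result.n_components:
        raise ValueError(f"q must lie in [1, {result.n_components}], got {q}")
    Ac = result.scores[:, :q] @ result.loadings_b[:q]
    mv = result.model.sample
    if result.model.standardize:
        for h, sl in enumerate(mv.block_slices()):
            Ac[:, sl] = Ac[:, sl] * result.standardize_scales[h]
    return result.mean_coefficients + Ac
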