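"""Homogeneity tests on principal component scores (independent groups).

The multivariate FANOVA hypothesis H0: mu_1(t) = ... = mu_g(t) for an
H-variate functional sample is reduced, via MFPCA, to a homogeneity test on
the vectors of the leading ``q`` principal component scores.  Two test
families are provided:

* per-component one-way ANOVA with a Bonferroni-corrected level ``alpha/q``
  (suited to Gaussian scores, where uncorrelatedness implies independence);
* a multivariate Kruskal-Wallis extension built on spatial ranks
  ``R_i = n^{-1} sum_j (x_i - x_j) / ||x_i - x_j||`` with the statistic
  ``Q = sum_i n_i Rbar_i' B^{-1} Rbar_i``, ``B = n^{-1} sum_i R_i R_i'``,
  asymptotically chi-square with q(g-1) degrees of freedom under H0.

For the small samples typical of monitoring networks the permutation
version of the tests is the default decision rule; when the number of
distinct group-label arrangements does not exceed the requested replicate
count they are enumerated exhaustively and the permutation p-value is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import factorial

import numpy as np
from scipy import stats

from .mfpca import MFPCA, MFPCAResults, MultivariateFunctionalSample

__all__ = [
    "ComponentANOVA",
    "ScoreHomogeneityResult",
    "anova_per_component",
    "spatial_rank_kw_statistic",
    "permutation_homogeneity_test",
    "mfanova_pipeline",
    "MultivariateFANOVA",
]


class DegenerateVarianceError(ValueError):
    """Zero within-group variance makes the ANOVA F statistic undefined."""


class RankDeficiencyError(ValueError):
    """Spatial-rank scatter matrix is singular; reduce the number of scores."""


@dataclass
class ComponentANOVA:
    """One-way ANOVA result for a single score component."""

    component: int
    f_statistic: float
    p_value: float
    significant: bool


@dataclass
class ScoreHomogeneityResult:
    """Joint outcome of the score-based homogeneity tests."""

    q: int
    per_component: list[ComponentANOVA]
    corrected_alpha: float
    multivariate_p: float | None
    multivariate_statistic: float | None
    n_perm: int
    seed: int | None
    group_sizes: dict
    exhaustive: bool = False
    test: str = "both"
    anova_family_p: float | None = None
    explained: float | None = None

    @property
    def anova_rejects(self) -> bool:
        return any(c.significant for c in self.per_component)


def _group_indices(groups) -> tuple[np.ndarray, list, list[np.ndarray]]:
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))  # first-appearance order
    idx = [np.nonzero(groups == lab)[0] for lab in labels]
    return groups, labels, idx


def anova_per_component(
    scores: np.ndarray, groups, alpha: float = 0.05
) -> list[ComponentANOVA]:
    """Classical one-way ANOVA per score column, Bonferroni level alpha/q."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.ndim == 2 and scores.shape[0] == 1 and len(np.asarray(groups)) > 1:
        scores = scores.T
    _, labels, idx = _group_indices(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab, ii in zip(labels, idx):
        if ii.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 members")
    q = scores.shape[1]
    corrected = alpha / q
    out = []
    for m in range(q):
        cols = [scores[ii, m] for ii in idx]
        ssw = sum(np.sum((c - c.mean()) ** 2) for c in cols)
        grand = scores[:, m].mean()
        ssb = sum(len(c) * (c.mean() - grand) ** 2 for c in cols)
        df1, df2 = len(labels) - 1, scores.shape[0] - len(labels)
        if ssw <= 0.0:
            if ssb <= 0.0:
                F, p = 0.0, 1.0
            else:
                raise DegenerateVarianceError(
                    f"component {m + 1}: zero within-group variance"
                )
        else:
            F = (ssb / df1) / (ssw / df2)
            p = float(stats.f.sf(F, df1, df2))
        out.append(
            ComponentANOVA(
                component=m + 1,
                f_statistic=float(F),
                p_value=float(p),
                significant=bool(p < corrected),
            )
        )
    return out


def spatial_ranks(x: np.ndarray) -> np.ndarray:
    """Spatial ranks R_i = n^{-1} sum_j u(x_i - x_j), u(x) = x / ||x||."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    diff = x[:, None, :] - x[None, :, :]
    norms = np.linalg.norm(diff, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = diff / norms[:, :, None]
    unit[norms == 0] = 0.0
    return unit.mean(axis=1)


def spatial_rank_kw_statistic(scores: np.ndarray, groups) -> float:
    """Multivariate Kruskal-Wallis statistic on spatial ranks."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    _, labels, idx = _group_indices(groups)
    n, q = scores.shape
    if n <= len(labels):
        raise ValueError("need more observations than groups")
    R = spatial_ranks(scores)
    B = R.T @ R / n
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError as exc:
        raise RankDeficiencyError(
            "spatial-rank scatter matrix is singular; use fewer components"
        ) from exc
    cond = np.linalg.cond(B)
    if not np.isfinite(cond) or cond > 1e12:
        raise RankDeficiencyError(
            "spatial-rank scatter matrix is numerically singular; "
            "use fewer components"
        )
    Q = 0.0
    for ii in idx:
        rbar = R[ii].mean(axis=0)
        Q += ii.size * rbar @ Binv @ rbar
    return float(Q)


def _distinct_arrangements(counts: list[int]) -> int:
    total = factorial(sum(counts))
    for c in counts:
        total //= factorial(c)
    return total


def _multiset_permutations(items: list):
    """Yield distinct permutations of a label multiset (lexicographic)."""
    items = sorted(items, key=repr)
    n = len(items)
    perm = list(items)
    while True:
        yield tuple(perm)
        i = n - 2
        while i >= 0 and not repr(perm[i]) < repr(perm[i + 1]):
            i -= 1
        if i < 0:
            return
        j = n - 1
        while not repr(perm[i]) < repr(perm[j]):
            j -= 1
        perm[i], perm[j] = perm[j], perm[i]
        perm[i + 1:] = reversed(perm[i + 1:])


def _label_permutations(groups: np.ndarray, n_perm: int, rng: np.random.Generator):
    """All distinct arrangements if few enough, else sampled permutations.

    Returns an ``(n_rep, n)`` matrix of label arrangements and the
    exhaustive flag.
    """
    _, labels, idx = _group_indices(groups)
    counts = [ii.size for ii in idx]
    n_distinct = _distinct_arrangements(counts)
    if n_distinct <= n_perm:
        perms = np.array([list(p) for p in _multiset_permutations(list(groups))])
        return perms, True
    perms = np.array([rng.permutation(groups) for _ in range(n_perm)])
    return perms, False


def _group_means_per_perm(
    values: np.ndarray, perms: np.ndarray, labels: list
) -> tuple[np.ndarray, np.ndarray]:
    """Group means of ``values`` (n x q) for each label arrangement.

    Returns ``means`` of shape (n_rep, g, q) and the group sizes (g,).
    """
    n_rep = perms.shape[0]
    g = len(labels)
    q = values.shape[1]
    means = np.empty((n_rep, g, q))
    sizes = np.empty(g)
    for gi, lab in enumerate(labels):
        mask = (perms == lab).astype(float)  # (n_rep, n)
        sizes[gi] = mask[0].sum()
        means[:, gi, :] = (mask @ values) / sizes[gi]
    return means, sizes


def permutation_homogeneity_test(
    scores: np.ndarray,
    groups,
    test: str = "both",
    n_perm: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> ScoreHomogeneityResult:
    """Permutation homogeneity test on a matrix of component scores.

    ``test``:

    * ``"rank"``  — multivariate p-value from the spatial-rank Kruskal-Wallis
      statistic under label permutation; per-component ANOVA reported with
      classical F p-values.
    * ``"anova"`` — per-component p-values from the permutation distribution
      of each F statistic; the family-level p-value is the Bonferroni
      combination ``min(1, q * min_m p_m)``.
    * ``"both"``  — rank multivariate p-value plus permutation ANOVA
      per-component p-values.

    Ties count as exceedances.  When the number of distinct group-label
    arrangements does not exceed ``n_perm`` they are enumerated and the
    permutation p-values are exact.
    """
    if test not in ("anova", "rank", "both"):
        raise ValueError(f"unknown test {test!r}")
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    groups = np.asarray(groups)
    n, q = scores.shape
    if groups.shape[0] != n:
        raise ValueError("one group label per score row is required")
    _, labels, idx = _group_indices(groups)
    group_sizes = {lab: int(ii.size) for lab, ii in zip(labels, idx)}
    corrected = alpha / q

    per_component = anova_per_component(scores, groups, alpha=alpha)

    rng = np.random.default_rng(seed)
    perms, exhaustive = _label_permutations(groups, n_perm, rng)
    n_rep = perms.shape[0]

    multivariate_p = None
    multivariate_statistic = None
    if test in ("rank", "both"):
        if n <= q + 1:
            warnings.warn(
                f"spatial-rank test with q = {q} components on n = {n} "
                "observations is degenerate (the statistic is invariant "
                "under relabelling when n <= q + 1); cap q at n - 2 or use "
                "the ANOVA family",
                RuntimeWarning,
                stacklevel=2,
            )
        # spatial ranks do not depend on labels: precompute once
        R = spatial_ranks(scores)
        B = R.T @ R / n
        if np.linalg.cond(B) > 1e12:
            raise RankDeficiencyError(
                "spatial-rank scatter matrix is numerically singular; "
                "use fewer components"
            )
        Binv = np.linalg.inv(B)
        observed = spatial_rank_kw_statistic(scores, groups)
        rbar, sizes = _group_means_per_perm(R, perms, labels)
        perm_stats = np.einsum("rgq,qk,rgk,g->r", rbar, Binv, rbar, sizes)
        multivariate_statistic = observed
        multivariate_p = float(np.mean(perm_stats >= observed - 1e-12))

    anova_family_p = None
    if test in ("anova", "both"):
        obs_F = np.array([c.f_statistic for c in per_component])
        df1 = len(labels) - 1
        df2 = n - len(labels)
        grand = scores.mean(axis=0)
        sst = np.sum((scores - grand) ** 2, axis=0)  # (q,)
        means, sizes = _group_means_per_perm(scores, perms, labels)
        ssb = np.einsum("g,rgq->rq", sizes, (means - grand[None, None, :]) ** 2)
        ssw = np.maximum(sst[None, :] - ssb, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            perm_F = (ssb / df1) / (ssw / df2)
        perm_F[~np.isfinite(perm_F)] = np.inf
        perm_p = (perm_F >= obs_F[None, :] - 1e-12).mean(axis=0)
        per_component = [
            ComponentANOVA(
                component=c.component,
                f_statistic=c.f_statistic,
                p_value=float(perm_p[m]),
                significant=bool(perm_p[m] < corrected),
            )
            for m, c in enumerate(per_component)
        ]
        anova_family_p = float(min(1.0, q * perm_p.min()))

    return ScoreHomogeneityResult(
        q=q,
        per_component=per_component,
        corrected_alpha=corrected,
        multivariate_p=multivariate_p,
        multivariate_statistic=multivariate_statistic,
        n_perm=n_rep,
        seed=seed,
        group_sizes=group_sizes,
        exhaustive=exhaustive,
        test=test,
        anova_family_p=anova_family_p,
    )


def mfanova_pipeline(
    mv: MultivariateFunctionalSample,
    threshold: float = 0.99,
    test: str = "both",
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int | None = None,
    q: int | None = None,
    standardize: bool = False,
) -> ScoreHomogeneityResult:
    """Full chain: MFPCA -> select q -> score homogeneity tests."""
    if mv.group_labels is None:
        raise ValueError("multivariate sample carries no group labels")
    pca = MFPCA(mv, standardize=standardize).fit()
    q_used = pca.select_num_components(threshold) if q is None else q
    q_used = min(q_used, pca.n_components)
    res = permutation_homogeneity_test(
        pca.scores[:, :q_used],
        mv.group_labels,
        test=test,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
    )
    res.explained = float(pca.cumulative_explained[q_used - 1])
    return res


class MultivariateFANOVA:
    """Model object for the independent-groups multivariate functional ANOVA.

    Wraps the MFPCA reduction and score homogeneity tests; ``fit`` returns a
    :class:`MultivariateFANOVAResults` with the fitted PCA, the selected
    number of components and both test families.
    """

    def __init__(self, sample: MultivariateFunctionalSample, standardize: bool = False):
        if sample.group_labels is None:
            raise ValueError("multivariate sample carries no group labels")
        self.sample = sample
        self.standardize = standardize

    def fit(
        self,
        threshold: float = 0.99,
        test: str = "both",
        alpha: float = 0.05,
        n_perm: int = 2000,
        seed: int | None = None,
        q: int | None = None,
    ) -> "MultivariateFANOVAResults":
        pca = MFPCA(self.sample, standardize=self.standardize).fit()
        q_used = pca.select_num_components(threshold) if q is None else q
        q_used = min(q_used, pca.n_components)
        homo = permutation_homogeneity_test(
            pca.scores[:, :q_used],
            self.sample.group_labels,
            test=test,
            n_perm=n_perm,
            seed=seed,
            alpha=alpha,
        )
        homo.explained = float(pca.cumulative_explained[q_used - 1])
        return MultivariateFANOVAResults(self, pca, homo)


class MultivariateFANOVAResults:
    """Fitted MFPCA reduction plus score homogeneity test outcomes."""

    def __init__(
        self, model: MultivariateFANOVA, pca: MFPCAResults, homogeneity: ScoreHomogeneityResult
    ):
        self.model = model
        self.pca = pca
        self.homogeneity = homogeneity

    @property
    def q(self) -> int:
        return self.homogeneity.q

    @property
    def multivariate_p(self) -> float | None:
        return self.homogeneity.multivariate_p

    def summary(self) -> str:
        h = self.homogeneity
        sizes = ", ".join(f"{k}: {v}" for k, v in h.group_sizes.items())
        lines = [
            "Multivariate functional ANOVA via MFPCA score homogeneity",
            f"  groups          : {sizes}",
            f"  components used : q = {h.q} "
            f"(cumulative explained {h.explained:.4f})" if h.explained is not None
            else f"  components used : q = {h.q}",
            f"  corrected alpha : {h.corrected_alpha:.4g} (Bonferroni)",
            f"  permutations    : {h.n_perm} ({'exhaustive' if h.exhaustive else 'sampled'})",
        ]
        if h.multivariate_p is not None:
            lines.append(
                f"  spatial-rank KW : Q = {h.multivariate_statistic:.5g}, "
                f"p = {h.multivariate_p:.4f}"
            )
        if h.anova_family_p is not None:
            lines.append(f"  ANOVA family p  : {h.anova_family_p:.4f} (Bonferroni-combined)")
        lines.append("")
        lines.append(f"  {'component':>9}  {'F':>10}  {'p-value':>8}  significant")
        for c in h.per_component:
            lines.append(
                f"  {c.component:>9}  {c.f_statistic:10.4g}  {c.p_value:8.4f}"
                f"  {'yes' if c.significant else 'no'}"
            )
        return "\n".join(lines)
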