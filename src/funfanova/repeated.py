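"""Repeated-measures functional ANOVA for paired curve samples.

Tests H0: mu_1(t) = mu_2(t) for all t, where the same n units are observed
under two conditions (e.g. the same monitoring stations before and during a
lockdown window).  Three statistics are available:

* ``C_n = n * int (Xbar_1 - Xbar_2)^2 dt`` — integrated squared mean
  difference (between-condition variability only, no homoscedasticity
  assumption);
* ``D_n = n * int (Xbar_1 - Xbar_2)^2 / K(t,t) dt`` — the same integral
  standardized by the pointwise variance of the within-unit condition
  differences;
* ``E_n = sup_t n (Xbar_1 - Xbar_2)^2 / K(t,t)`` — the supremum of the
  standardized ratio.

Here ``K(t,t)`` is the sample variance function of the paired differences
``(X_j1 - Xbar_1) - (X_j2 - Xbar_2)``.  Under the basis expansion these
quantities reduce to coefficient-space algebra: with mean coefficient
difference ``dbar`` and Gram matrix ``W``, ``C_n = n dbar' W dbar``, and
``K(t,t) = phi(t)' (S1 - S12 - S12' + S2) phi(t)`` with per-condition
coefficient covariances ``S1, S2`` and cross-covariance ``S12``.

The null distribution is approximated by the per-unit permutation scheme:
each replicate independently swaps (or not) the two condition curves within
every unit, and the p-value is the proportion of replicate statistics that
meet or exceed the observed one.  When ``2^n`` does not exceed the requested
number of replicates the full set of swap patterns is enumerated, giving
the exact permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson

from .basis import BSplineBasis, FunctionalSample

__all__ = [
    "PairedFunctionalSample",
    "PairedCoefficientSummary",
    "TestResult",
    "DegenerateKernelError",
    "paired_summary",
    "statistic_cn",
    "statistic_dn",
    "statistic_en",
    "permutation_test",
    "RepeatedMeasuresFANOVA",
    "RepeatedMeasuresFANOVAResults",
]

STATISTIC_NAMES = ("cn", "dn", "en")


class DegenerateKernelError(ValueError):
    """The variance kernel K(t,t) vanishes on the whole integration grid."""


@dataclass
class PairedFunctionalSample:
    """Two aligned coefficient matrices for the same ``n`` units (R = 2)."""

    basis: BSplineBasis
    coeff_cond1: np.ndarray
    coeff_cond2: np.ndarray
    unit_ids: list[str]
    condition_labels: tuple[str, str] = ("condition 1", "condition 2")

    def __post_init__(self) -> None:
        self.coeff_cond1 = np.atleast_2d(np.asarray(self.coeff_cond1, dtype=float))
        self.coeff_cond2 = np.atleast_2d(np.asarray(self.coeff_cond2, dtype=float))
        if self.coeff_cond1.shape != self.coeff_cond2.shape:
            raise ValueError("condition coefficient matrices must have equal shape")
        if self.coeff_cond1.shape[0] != len(self.unit_ids):
            raise ValueError("coefficient rows must match number of unit ids")
        if len(self.condition_labels) != 2:
            raise ValueError("exactly two conditions are supported (R = 2)")

    @property
    def n_units(self) -> int:
        return self.coeff_cond1.shape[0]

    @classmethod
    def from_samples(
        cls, sample1: FunctionalSample, sample2: FunctionalSample,
        condition_labels: tuple[str, str] = ("condition 1", "condition 2"),
    ) -> "PairedFunctionalSample":
        if sample1.unit_ids != sample2.unit_ids:
            raise ValueError("unit ids of the two conditions must align")
        if sample1.basis.n_basis != sample2.basis.n_basis:
            raise ValueError("both conditions must share one basis")
        return cls(
            basis=sample1.basis,
            coeff_cond1=sample1.coefficients,
            coeff_cond2=sample2.coefficients,
            unit_ids=list(sample1.unit_ids),
            condition_labels=condition_labels,
        )


@dataclass
class PairedCoefficientSummary:
    """Coefficient-space summary: mean difference and (cross-)covariances."""

    mean_diff: np.ndarray
    cov1: np.ndarray
    cov2: np.ndarray
    crosscov: np.ndarray
    n: int

    def kernel_coefficient_matrix(self) -> np.ndarray:
        """Matrix M with K(t,t) = phi(t)' M phi(t).

        Uses the symmetrized cross term ``S12 + S12'`` (identical value to
        ``2 S12`` inside the quadratic form, numerically symmetric).
        """
        return self.cov1 + self.cov2 - (self.crosscov + self.crosscov.T)


def paired_summary(sample: PairedFunctionalSample) -> PairedCoefficientSummary:
    """Mean coefficient difference and covariance matrices (denominator n-1)."""
    A1, A2 = sample.coeff_cond1, sample.coeff_cond2
    n = A1.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 paired units, got {n}")
    m1, m2 = A1.mean(axis=0), A2.mean(axis=0)
    C1 = (A1 - m1).T @ (A1 - m1) / (n - 1)
    C2 = (A2 - m2).T @ (A2 - m2) / (n - 1)
    C12 = (A1 - m1).T @ (A2 - m2) / (n - 1)
    return PairedCoefficientSummary(
        mean_diff=m1 - m2, cov1=C1, cov2=C2, crosscov=C12, n=n
    )


def statistic_cn(summary: PairedCoefficientSummary, gram: np.ndarray) -> float:
    """Integrated squared mean difference, ``n dbar' W dbar``."""
    d = summary.mean_diff
    gram = np.asarray(gram)
    if gram.shape != (d.size, d.size):
        raise ValueError(
            f"gram shape {gram.shape} does not match coefficient length {d.size}"
        )
    return float(summary.n * d @ gram @ d)

_KERNEL_FLOOR_REL = 1e-12


def _pointwise_ratio(
    summary: PairedCoefficientSummary, basis: BSplineBasis, grid: np.ndarray
) -> np.ndarray:
    """n (Xbar1 - Xbar2)^2 / K(t,t) on a grid, with the relative floor on K."""
    Phi = basis.design_matrix(grid)
    num = summary.n * (Phi @ summary.mean_diff) ** 2
    M = summary.kernel_coefficient_matrix()
    K = np.einsum("gp,pq,gq->g", Phi, M, Phi)
    kmax = K.max(initial=0.0)
    floor = _KERNEL_FLOOR_REL * kmax
    if kmax <= 0.0 or np.all(K <= floor):
        raise DegenerateKernelError(
            "variance kernel K(t,t) vanishes on the whole grid "
            "(deterministic identical paired differences?)"
        )
    return num / np.maximum(K, floor)


def _grid(basis: BSplineBasis, grid_size: int) -> np.ndarray:
    a, b = basis.domain
    if grid_size < 3:
        raise ValueError("grid_size must be >= 3")
    return np.linspace(a, b, grid_size)


def statistic_dn(
    summary: PairedCoefficientSummary, basis: BSplineBasis, grid_size: int = 1001
) -> float:
    """Variance-standardized integral, composite Simpson on a uniform grid."""
    grid = _grid(basis, grid_size)
    return float(simpson(_pointwise_ratio(summary, basis, grid), x=grid))


def statistic_en(
    summary: PairedCoefficientSummary, basis: BSplineBasis, grid_size: int = 1001
) -> float:
    """Supremum of the standardized ratio over the same uniform grid."""
    grid = _grid(basis, grid_size)
    return float(_pointwise_ratio(summary, basis, grid).max())


@dataclass
class TestResult:
    """Outcome of one permutation test."""

    statistic_name: str
    observed: float
    p_value: float
    n_perm: int
    exhaustive: bool
    seed: int | None = None
    grid_size: int | None = None
    n_degenerate: int = 0
    reference_quantiles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _swap_patterns(n: int, n_perm: int, rng: np.random.Generator):
    """Replicate sign matrix (+1 keep / -1 swap per unit), and exhaustive flag."""
    if n <= 62 and 2 ** n <= n_perm:
        codes = np.arange(2 ** n, dtype=np.uint64)
        bits = (codes[:, None] >> np.arange(n, dtype=np.uint64)) & np.uint64(1)
        return 1.0 - 2.0 * bits.astype(float), True
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2.0 - 1.0
    return signs, False


def _statistics_from_signed_means(
    dbar: np.ndarray,
    gram_diag_quad: np.ndarray | None,
    Phi: np.ndarray | None,
    grid: np.ndarray | None,
    gram: np.ndarray | None,
    n: int,
    which: tuple[str, ...],
) -> dict[str, np.ndarray]:
    """Evaluate the requested statistics for a batch of signed mean differences.

    ``dbar`` is ``(batch, p)``.  Sign flips leave the Gram of the difference
    rows ``D'D`` unchanged, so the paired-difference covariance for a signed
    replicate is ``(D'D - n dbar dbar') / (n - 1)``; only ``dbar`` varies.
    ``gram_diag_quad`` holds the precomputed grid values of
    ``phi(t)' D'D phi(t)``.
    """
    out: dict[str, np.ndarray] = {}
    if "cn" in which:
        out["cn"] = n * np.einsum("bp,pq,bq->b", dbar, gram, dbar)
    if "dn" in which or "en" in which:
        Mgrid = dbar @ Phi.T  # (batch, grid)
        num = n * Mgrid ** 2
        K = (gram_diag_quad[None, :] - num) / (n - 1)
        kmax = K.max(axis=1)
        degenerate = kmax <= 0.0
        floor = _KERNEL_FLOOR_REL * np.maximum(kmax, 0.0)
        ratio = num / np.maximum(K, np.maximum(floor[:, None], np.finfo(float).tiny))
        if "dn" in which:
            dn = simpson(ratio, x=grid, axis=1)
            dn[degenerate] = np.inf
            out["dn"] = dn
        if "en" in which:
            en = ratio.max(axis=1)
            en[degenerate] = np.inf
            out["en"] = en
        out["_degenerate"] = degenerate
    return out


def permutation_test(
    sample: PairedFunctionalSample,
    statistic: str = "dn",
    n_perm: int = 2000,
    seed: int | None = None,
    grid_size: int = 1001,
    add_one: bool = False,
) -> TestResult:
    """Per-unit swap permutation test for one statistic.

    ``statistic`` is one of ``"cn"``, ``"dn"``, ``"en"``.  Ties count toward
    the p-value (a replicate meeting the observed value is an exceedance).
    With ``add_one=True`` the p-value is ``(1 + #exceed) / (1 + n_perm)``
    instead of the plain proportion.  Replicates with a fully degenerate
    kernel (D_n/E_n only) are counted as exceedances, conservatively.
    """
    results = _permutation_tests(sample, (statistic,), n_perm, seed, grid_size, add_one)
    return results[statistic]


def _permutation_tests(
    sample: PairedFunctionalSample,
    statistics: tuple[str, ...],
    n_perm: int,
    seed: int | None,
    grid_size: int,
    add_one: bool = False,
) -> dict[str, TestResult]:
    for s in statistics:
        if s not in STATISTIC_NAMES:
            raise ValueError(f"unknown statistic {s!r}; choose from {STATISTIC_NAMES}")
    n = sample.n_units
    if n < 2:
        raise ValueError(f"need at least 2 paired units, got {n}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    D = sample.coeff_cond1 - sample.coeff_cond2  # swap of unit j flips row j's sign
    need_grid = "dn" in statistics or "en" in statistics
    gram = sample.basis.gram if "cn" in statistics else None
    Phi = grid = gram_diag_quad = None
    if need_grid:
        grid = _grid(sample.basis, grid_size)
        Phi = sample.basis.design_matrix(grid)
        G2 = D.T @ D
        gram_diag_quad = np.einsum("gp,pq,gq->g", Phi, G2, Phi)

    obs = _statistics_from_signed_means(
        D.mean(axis=0)[None, :], gram_diag_quad, Phi, grid, gram, n, statistics
    )
    obs_degen = obs.pop("_degenerate", np.zeros(1, bool))
    if obs_degen[0]:
        raise DegenerateKernelError(
            "variance kernel K(t,t) vanishes everywhere for the observed sample"
        )

    rng = np.random.default_rng(seed)
    signs, exhaustive = _swap_patterns(n, n_perm, rng)
    dbar = (signs @ D) / n
    perm = _statistics_from_signed_means(
        dbar, gram_diag_quad, Phi, grid, gram, n, statistics
    )
    degen = perm.pop("_degenerate", np.zeros(signs.shape[0], bool))
    n_degen = int(degen.sum())
    if n_degen:
        warnings.warn(
            f"{n_degen} permutation replicates had a degenerate kernel; "
            "counted as exceedances",
            RuntimeWarning,
            stacklevel=2,
        )

    n_rep = signs.shape[0]
    out: dict[str, TestResult] = {}
    for s in statistics:
        observed = float(obs[s][0])
        # ties count as exceedances; tolerance absorbs last-ulp differences
        # between the observed and replicate computation paths
        tie_tol = 1e-9 * max(1.0, abs(observed))
        exceed = int(np.sum(perm[s] >= observed - tie_tol))
        p = (1 + exceed) / (1 + n_rep) if add_one else exceed / n_rep
        finite = perm[s][np.isfinite(perm[s])]
        quantiles = {}
        if finite.size:
            qs = np.quantile(finite, [0.5, 0.9, 0.95, 0.99])
            quantiles = dict(zip(["q50", "q90", "q95", "q99"], map(float, qs)))
        out[s] = TestResult(
            statistic_name=s,
            observed=observed,
            p_value=float(p),
            n_perm=n_rep,
            exhaustive=exhaustive,
            seed=seed,
            grid_size=grid_size if s in ("dn", "en") else None,
            n_degenerate=n_degen if s in ("dn", "en") else 0,
            reference_quantiles=quantiles,
        )
    return out


class RepeatedMeasuresFANOVA:
    """Model object for the paired two-condition functional ANOVA.

    Parameters
    ----------
    sample : PairedFunctionalSample
        Aligned coefficient matrices of the two conditions.

    Examples
    --------
    >>> model = RepeatedMeasuresFANOVA(paired)          # doctest: +SKIP
    >>> res = model.fit(n_perm=2000, seed=7)            # doctest: +SKIP
    >>> print(res.summary())                            # doctest: +SKIP
    """

    def __init__(self, sample: PairedFunctionalSample):
        self.sample = sample

    @classmethod
    def from_samples(cls, sample1, sample2, condition_labels=("condition 1", "condition 2")):
        return cls(PairedFunctionalSample.from_samples(sample1, sample2, condition_labels))

    def fit(
        self,
        statistics: tuple[str, ...] = ("cn", "dn", "en"),
        n_perm: int = 2000,
        seed: int | None = None,
        grid_size: int = 1001,
        add_one: bool = False,
    ) -> "RepeatedMeasuresFANOVAResults":
        if isinstance(statistics, str):
            statistics = (statistics,)
        tests = _permutation_tests(
            self.sample, tuple(statistics), n_perm, seed, grid_size, add_one
        )
        return RepeatedMeasuresFANOVAResults(self, tests)


class RepeatedMeasuresFANOVAResults:
    """Fitted permutation tests for a paired functional sample."""

    def __init__(self, model: RepeatedMeasuresFANOVA, tests: dict[str, TestResult]):
        self.model = model
        self.tests = tests

    @property
    def p_values(self) -> dict[str, float]:
        return {name: t.p_value for name, t in self.tests.items()}

    def summary(self) -> str:
        s = self.model.sample
        lines = [
            "Repeated-measures functional ANOVA (permutation null)",
            f"  conditions : {s.condition_labels[0]!r} vs {s.condition_labels[1]!r}",
            f"  units      : n = {s.n_units}",
            f"  basis      : B-spline order {s.basis.order}, dimension {s.basis.n_basis}",
            "",
            f"  {'statistic':>9}  {'observed':>12}  {'p-value':>8}  {'replicates':>10}  exact",
        ]
        pretty = {"cn": "C_n", "dn": "D_n", "en": "E_n"}
        for name in STATISTIC_NAMES:
            if name not in self.tests:
                continue
            t = self.tests[name]
            lines.append(
                f"  {pretty[name]:>9}  {t.observed:12.5g}  {t.p_value:8.4f}"
                f"  {t.n_perm:10d}  {'yes' if t.exhaustive else 'no'}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            name: {
                "statistic": t.statistic_name,
                "observed": t.observed,
                "p_value": t.p_value,
                "n_perm": t.n_perm,
                "exhaustive": t.exhaustive,
            }
            for name, t in self.tests.items()
        }
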