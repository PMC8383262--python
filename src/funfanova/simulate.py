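"""Synthetic functional data generation and Monte-Carlo calibration.

Curves are drawn from the model ``X_jr(t) = mu_r(t) + e_jr(t) + eps``,
where the deviations ``e`` are zero-mean Gaussian processes with a
stationary exponential kernel ``sigma^2 exp(-|s - t| / length_scale)`` and
``eps`` is iid measurement noise.  Dependence across the two repeated
conditions (and across the H variables of a multivariate design) is
separable: the joint covariance is the Kronecker product of the temporal
kernel with small condition/variable correlation matrices, which keeps it
positive semi-definite by construction.

The ``airlike`` preset mirrors a small urban monitoring network: four
pollutant-like variables (NO2, PM10, PM2.5, benzene scales), five stations
split into two urban-traffic and three urban-background sites, and two
39-day windows observed as daily values.  The defaults (exponential kernel
with length-scale 0.2 and unit-scale sigma on [0, 1]) produce trajectories
rough enough that a 20-dimensional cubic B-spline basis smooths them
imperfectly, so the calibration runs exercise the smoothing step and not
just the coefficient algebra.

``rejection_rate`` / ``rejection_rate_groups`` run the full chain
(simulate -> least-squares smoothing -> permutation test) over many
Monte-Carlo datasets and report empirical rejection fractions with their
binomial standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .basis import FunctionalSample, RawSeries, make_bspline_basis
from .homogeneity import permutation_homogeneity_test
from .mfpca import MFPCA, assemble_multivariate
from .repeated import PairedFunctionalSample, _permutation_tests

__all__ = [
    "GPConfig",
    "MonteCarloReport",
    "exponential_kernel",
    "simulate_paired",
    "simulate_groups",
    "rejection_rate",
    "rejection_rate_groups",
    "airlike_preset",
    "simulate_airlike",
]


class ConfigurationError(ValueError):
    """Assembled simulation covariance is not positive semi-definite."""


def _zero(t: np.ndarray) -> np.ndarray:
    return np.zeros_like(t)


@dataclass
class GPConfig:
    """Gaussian-process simulation settings on the normalized domain [0, 1].

    ``mean_functions`` maps a condition index (paired designs) or a
    ``(group label, variable index)`` pair (group designs) to a callable on
    [0, 1]; missing entries default to the zero function.  ``sigma`` and
    ``noise_sd`` may be scalars or one value per variable.
    """

    mean_functions: dict = field(default_factory=dict)
    sigma: float | Sequence[float] = 1.0
    length_scale: float = 0.2
    cross_condition_corr: float = 0.5
    cross_variable_corr: float | np.ndarray = 0.0
    noise_sd: float | Sequence[float] = 0.1
    n_times: int = 39
    missing_rate: float = 0.0

    def grid(self) -> np.ndarray:
        if self.n_times < 2:
            raise ConfigurationError("need at least 2 observation times")
        return np.linspace(0.0, 1.0, self.n_times)

    def mean(self, key, t: np.ndarray) -> np.ndarray:
        fn = self.mean_functions.get(key, _zero)
        return np.asarray(fn(t), dtype=float) + np.zeros_like(t)

    def sigmas(self, H: int) -> np.ndarray:
        s = np.broadcast_to(np.asarray(self.sigma, dtype=float), (H,)).copy()
        if np.any(s < 0):
            raise ConfigurationError("sigma must be non-negative")
        return s

    def noise_sds(self, H: int) -> np.ndarray:
        s = np.broadcast_to(np.asarray(self.noise_sd, dtype=float), (H,)).copy()
        if np.any(s < 0):
            raise ConfigurationError("noise_sd must be non-negative")
        return s

    def variable_corr(self, H: int) -> np.ndarray:
        c = np.asarray(self.cross_variable_corr, dtype=float)
        if c.ndim == 0:
            C = np.full((H, H), float(c))
            np.fill_diagonal(C, 1.0)
        else:
            if c.shape != (H, H):
                raise ConfigurationError(
                    f"cross_variable_corr must be {H}x{H}, got {c.shape}"
                )
            C = c
        if np.abs(C).max() > 1.0 + 1e-12:
            raise ConfigurationError("correlations must lie in [-1, 1]")
        return C


def exponential_kernel(grid: np.ndarray, sigma: float = 1.0, length_scale: float = 0.2) -> np.ndarray:
    """Stationary covariance ``sigma^2 exp(-|s - t| / length_scale)``."""
    if length_scale <= 0:
        raise ConfigurationError("length_scale must be positive")
    d = np.abs(grid[:, None] - grid[None, :])
    return sigma ** 2 * np.exp(-d / length_scale)


def _cholesky_psd(C: np.ndarray) -> np.ndarray:
    if np.abs(C).max(initial=0.0) == 0.0:
        return np.zeros_like(C)
    jitter = 1e-10 * max(np.trace(C) / len(C), 1.0)
    for _ in range(4):
        try:
            return np.linalg.cholesky(C + jitter * np.eye(len(C)))
        except np.linalg.LinAlgError:
            jitter *= 100.0
    raise ConfigurationError("assembled covariance is not positive semi-definite")


def _paired_deviation_chol(config: GPConfig) -> tuple[np.ndarray, np.ndarray]:
    grid = config.grid()
    sigma = float(config.sigmas(1)[0])
    rho = float(config.cross_condition_corr)
    if abs(rho) > 1.0 + 1e-12:
        raise ConfigurationError("cross_condition_corr must lie in [-1, 1]")
    K = exponential_kernel(grid, sigma, config.length_scale)
    cond = np.array([[1.0, rho], [rho, 1.0]])
    return grid, _cholesky_psd(np.kron(cond, K))


def _simulate_paired_values(
    n: int, config: GPConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (grid, X1, X2) with X_r of shape (n, T)."""
    grid, L = _paired_deviation_chol(config)
    T = grid.size
    z = rng.standard_normal((n, 2 * T))
    e = z @ L.T
    noise = config.noise_sds(1)[0]
    X1 = config.mean(1, grid) + e[:, :T]
    X2 = config.mean(2, grid) + e[:, T:]
    if noise > 0:
        X1 = X1 + rng.normal(0.0, noise, size=X1.shape)
        X2 = X2 + rng.normal(0.0, noise, size=X2.shape)
    return grid, X1, X2


def _inject_missing(values: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return values
    mask = rng.random(values.shape) < rate
    out = values.copy()
    out[mask] = np.nan
    return out


def simulate_paired(
    n: int,
    config: GPConfig,
    seed: int | None = None,
    condition_labels: tuple[str, str] = ("condition 1", "condition 2"),
    variable_name: str = "X",
) -> list[RawSeries]:
    """Draw ``n`` paired units (2 conditions each) as RawSeries."""
    rng = np.random.default_rng(seed)
    grid, X1, X2 = _simulate_paired_values(n, config, rng)
    out = []
    for j in range(n):
        for label, X in zip(condition_labels, (X1, X2)):
            out.append(
                RawSeries(
                    unit_id=f"u{j + 1}",
                    group_label="",
                    condition_label=label,
                    variable_name=variable_name,
                    times=grid,
                    values=_inject_missing(X[j], config.missing_rate, rng),
                    times_norm=grid,
                )
            )
    return out


def _group_deviation_chol(config: GPConfig, H: int) -> tuple[np.ndarray, np.ndarray]:
    grid = config.grid()
    sig = config.sigmas(H)
    Cvar = config.variable_corr(H) * np.outer(sig, sig)
    K = exponential_kernel(grid, 1.0, config.length_scale)
    return grid, _cholesky_psd(np.kron(Cvar, K))


def _simulate_group_values(
    group_sizes: dict, H: int, config: GPConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Return (grid, X, labels); X has shape (n, H, T)."""
    grid, L = _group_deviation_chol(config, H)
    T = grid.size
    n = sum(group_sizes.values())
    z = rng.standard_normal((n, H * T))
    e = (z @ L.T).reshape(n, H, T)
    labels: list[str] = []
    for lab, size in group_sizes.items():
        labels.extend([lab] * size)
    X = np.empty((n, H, T))
    noise = config.noise_sds(H)
    for i, lab in enumerate(labels):
        for h in range(H):
            X[i, h] = config.mean((lab, h), grid) + e[i, h]
            if noise[h] > 0:
                X[i, h] += rng.normal(0.0, noise[h], size=T)
    return grid, X, labels


def simulate_groups(
    group_sizes: dict,
    H: int,
    config: GPConfig,
    seed: int | None = None,
    condition_label: str = "period",
    variable_names: Sequence[str] | None = None,
) -> list[RawSeries]:
    """Draw independent units in ``g`` labelled groups, H variables each."""
    rng = np.random.default_rng(seed)
    grid, X, labels = _simulate_group_values(group_sizes, H, config, rng)
    if variable_names is None:
        variable_names = [f"X{h + 1}" for h in range(H)]
    out = []
    for i, lab in enumerate(labels):
        for h in range(H):
            out.append(
                RawSeries(
                    unit_id=f"u{i + 1}",
                    group_label=lab,
                    condition_label=condition_label,
                    variable_name=variable_names[h],
                    times=grid,
                    values=_inject_missing(X[i, h], config.missing_rate, rng),
                    times_norm=grid,
                )
            )
    return out


@dataclass
class MonteCarloReport:
    """Empirical rejection fractions from a Monte-Carlo study."""

    n_sim: int
    alpha: float
    rejection_rate: dict
    monte_carlo_se: dict
    n_errors: int
    config: dict

    def __str__(self) -> str:
        lines = [f"Monte-Carlo report ({self.n_sim} datasets, alpha = {self.alpha})"]
        for k, r in self.rejection_rate.items():
            lines.append(f"  {k}: rate = {r:.4f} (se {self.monte_carlo_se[k]:.4f})")
        if self.n_errors:
            lines.append(f"  {self.n_errors} datasets raised errors")
        return "\n".join(lines)


def _smoothing_operator(grid: np.ndarray, n_basis: int, order: int):
    basis = make_bspline_basis((0.0, 1.0), n_basis, order)
    Phi = basis.design_matrix(grid)
    return basis, np.linalg.pinv(Phi)


def rejection_rate(
    config: GPConfig,
    n_units: int = 20,
    statistics: tuple[str, ...] = ("cn", "dn", "en"),
    alpha: float = 0.05,
    n_sim: int = 1000,
    n_perm: int = 200,
    n_basis: int = 20,
    order: int = 4,
    grid_size: int = 201,
    seed: int | None = None,
    collect_p_values: bool = False,
) -> MonteCarloReport:
    """Monte-Carlo size/power of the paired permutation tests.

    Each dataset runs the full chain: simulate discrete curves, smooth them
    by least squares onto a cubic B-spline basis, then permutation-test.
    A dataset counts as a rejection when its p-value is strictly below
    ``alpha`` (so ``alpha = 0`` never rejects).
    """
    if isinstance(statistics, str):
        statistics = (statistics,)
    root = np.random.SeedSequence(seed)
    sim_seeds = root.spawn(n_sim)
    grid, L = _paired_deviation_chol(config)
    basis, pinv_phi = _smoothing_operator(grid, n_basis, order)
    T = grid.size
    mu1, mu2 = config.mean(1, grid), config.mean(2, grid)
    noise = config.noise_sds(1)[0]

    rejections = {s: 0 for s in statistics}
    pvals: dict[str, list[float]] = {s: [] for s in statistics}
    n_err = 0
    for ss in sim_seeds:
        rng = np.random.default_rng(ss)
        z = rng.standard_normal((n_units, 2 * T))
        e = z @ L.T
        X1 = mu1 + e[:, :T]
        X2 = mu2 + e[:, T:]
        if noise > 0:
            X1 = X1 + rng.normal(0.0, noise, size=X1.shape)
            X2 = X2 + rng.normal(0.0, noise, size=X2.shape)
        A1 = X1 @ pinv_phi.T
        A2 = X2 @ pinv_phi.T
        sample = PairedFunctionalSample(
            basis=basis, coeff_cond1=A1, coeff_cond2=A2,
            unit_ids=[f"u{j}" for j in range(n_units)],
        )
        try:
            tests = _permutation_tests(
                sample, tuple(statistics), n_perm, rng, grid_size
            )
        except Exception:
            n_err += 1
            continue
        for s in statistics:
            pvals[s].append(tests[s].p_value)
            if tests[s].p_value < alpha:
                rejections[s] += 1
    done = n_sim - n_err
    rates = {s: rejections[s] / done if done else np.nan for s in statistics}
    ses = {
        s: float(np.sqrt(r * (1 - r) / done)) if done else np.nan
        for s, r in rates.items()
    }
    report = MonteCarloReport(
        n_sim=done,
        alpha=alpha,
        rejection_rate=rates,
        monte_carlo_se=ses,
        n_errors=n_err,
        config={
            "design": "paired",
            "n_units": n_units,
            "n_perm": n_perm,
            "n_basis": n_basis,
            "length_scale": config.length_scale,
            "cross_condition_corr": config.cross_condition_corr,
            "noise_sd": float(config.noise_sds(1)[0]),
            "seed": seed,
        },
    )
    if collect_p_values:
        report.config["p_values"] = {s: np.asarray(v) for s, v in pvals.items()}
    return report


def rejection_rate_groups(
    config: GPConfig,
    group_sizes: dict,
    H: int = 1,
    test: str = "both",
    threshold: float = 0.99,
    alpha: float = 0.05,
    n_sim: int = 1000,
    n_perm: int = 200,
    n_basis: int = 20,
    order: int = 4,
    seed: int | None = None,
) -> MonteCarloReport:
    """Monte-Carlo size/power of the MFPCA score homogeneity tests."""
    root = np.random.SeedSequence(seed)
    sim_seeds = root.spawn(n_sim)
    grid, L = _group_deviation_chol(config, H)
    basis, pinv_phi = _smoothing_operator(grid, n_basis, order)
    labels = []
    for lab, size in group_sizes.items():
        labels.extend([lab] * size)
    labels = np.asarray(labels)
    n = len(labels)
    T = grid.size
    noise = config.noise_sds(H)
    means = np.stack(
        [np.stack([config.mean((lab, h), grid) for h in range(H)]) for lab in labels]
    )  # (n, H, T)

    counts = {"rank": 0, "anova": 0}
    n_err = 0
    for ss in sim_seeds:
        rng = np.random.default_rng(ss)
        z = rng.standard_normal((n, H * T))
        e = (z @ L.T).reshape(n, H, T)
        X = means + e
        for h in range(H):
            if noise[h] > 0:
                X[:, h, :] += rng.normal(0.0, noise[h], size=(n, T))
        variables = [
            FunctionalSample(
                basis=basis,
                coefficients=X[:, h, :] @ pinv_phi.T,
                unit_ids=[f"u{j}" for j in range(n)],
                variable_name=f"X{h + 1}",
            )
            for h in range(H)
        ]
        mv = assemble_multivariate(variables, group_labels=labels)
        try:
            pca = MFPCA(mv).fit()
            q = pca.select_num_components(threshold)
            res = permutation_homogeneity_test(
                pca.scores[:, :q], labels, test=test,
                n_perm=n_perm, seed=rng, alpha=alpha,
            )
        except Exception:
            n_err += 1
            continue
        if test in ("rank", "both") and res.multivariate_p is not None:
            if res.multivariate_p < alpha:
                counts["rank"] += 1
        if test in ("anova", "both"):
            if res.anova_rejects:
                counts["anova"] += 1
    done = n_sim - n_err
    wanted = [k for k in ("rank", "anova") if test in (k, "both")]
    rates = {k: counts[k] / done if done else np.nan for k in wanted}
    ses = {
        k: float(np.sqrt(r * (1 - r) / done)) if done else np.nan
        for k, r in rates.items()
    }
    return MonteCarloReport(
        n_sim=done,
        alpha=alpha,
        rejection_rate=rates,
        monte_carlo_se=ses,
        n_errors=n_err,
        config={
            "design": "groups",
            "group_sizes": dict(group_sizes),
            "H": H,
            "n_perm": n_perm,
            "n_basis": n_basis,
            "threshold": threshold,
            "seed": seed,
        },
    )


# --- the air-quality-like study preset ------------------------------------

AIRLIKE_VARIABLES = ("NO2", "PM10", "PM2.5", "benzene")
AIRLIKE_UNITS = ("fi", "mo", "th", "ch", "fr")
AIRLIKE_GROUPS = {"fi": "UT", "mo": "UT", "th": "UB", "ch": "UB", "fr": "UB"}
AIRLIKE_CONDITIONS = ("before", "during")

# smooth window-mean levels per (variable, condition), micrograms/m3 scale,
# plus an additive urban-traffic offset per variable
_AIRLIKE_MEANS: dict[tuple[str, str], Callable] = {
    ("NO2", "before"): lambda t: 26.0 + 6.0 * np.sin(2 * np.pi * t + 0.4),
    ("NO2", "during"): lambda t: 12.0 + 3.0 * np.sin(2 * np.pi * t),
    ("PM10", "before"): lambda t: 24.0 + 4.0 * np.sin(np.pi * t),
    ("PM10", "during"): lambda t: 29.0 + 5.0 * np.cos(np.pi * t),
    ("PM2.5", "before"): lambda t: 15.0 + 3.0 * np.sin(np.pi * t),
    ("PM2.5", "during"): lambda t: 18.0 + 3.0 * np.cos(np.pi * t),
    ("benzene", "before"): lambda t: 1.15 + 0.30 * np.sin(2 * np.pi * t),
    ("benzene", "during"): lambda t: 1.00 + 0.20 * np.cos(2 * np.pi * t),
}
_AIRLIKE_UT_OFFSET = {"NO2": 6.0, "PM10": 2.0, "PM2.5": 1.0, "benzene": 0.25}
_AIRLIKE_SIGMA = {"NO2": 4.0, "PM10": 4.0, "PM2.5": 3.0, "benzene": 0.25}
_AIRLIKE_NOISE = {"NO2": 1.5, "PM10": 1.5, "PM2.5": 1.0, "benzene": 0.08}


def airlike_preset() -> dict:
    """Configuration of the monitoring-network-like preset."""
    return {
        "variables": list(AIRLIKE_VARIABLES),
        "units": list(AIRLIKE_UNITS),
        "groups": dict(AIRLIKE_GROUPS),
        "conditions": list(AIRLIKE_CONDITIONS),
        "n_times": 39,
        "length_scale": 0.2,
        "cross_condition_corr": 0.5,
        "cross_variable_corr": 0.3,
        "sigma": dict(_AIRLIKE_SIGMA),
        "noise_sd": dict(_AIRLIKE_NOISE),
    }


def simulate_airlike(
    seed: int | None = None, missing_rate: float = 0.0
) -> list[RawSeries]:
    """Draw one full monitoring-network-like dataset.

    Four pollutant-scale variables observed at five stations (2 UT + 3 UB)
    in two 39-day windows of daily values; deviations are correlated across
    variables (0.3) and across the two windows within a station (0.5).
    """
    rng = np.random.default_rng(seed)
    preset = airlike_preset()
    H = len(AIRLIKE_VARIABLES)
    R = len(AIRLIKE_CONDITIONS)
    grid = np.linspace(0.0, 1.0, preset["n_times"])
    T = grid.size
    sig = np.array([_AIRLIKE_SIGMA[v] for v in AIRLIKE_VARIABLES])
    Cvar = np.full((H, H), preset["cross_variable_corr"])
    np.fill_diagonal(Cvar, 1.0)
    rho = preset["cross_condition_corr"]
    Ccond = np.array([[1.0, rho], [rho, 1.0]])
    K = exponential_kernel(grid, 1.0, preset["length_scale"])
    L = _cholesky_psd(np.kron(Ccond, np.kron(Cvar * np.outer(sig, sig), K)))

    out = []
    for unit in AIRLIKE_UNITS:
        group = AIRLIKE_GROUPS[unit]
        e = (rng.standard_normal(R * H * T) @ L.T).reshape(R, H, T)
        for r, cond in enumerate(AIRLIKE_CONDITIONS):
            for h, var in enumerate(AIRLIKE_VARIABLES):
                mu = _AIRLIKE_MEANS[(var, cond)](grid)
                if group == "UT":
                    mu = mu + _AIRLIKE_UT_OFFSET[var]
                values = mu + e[r, h] + rng.normal(0.0, _AIRLIKE_NOISE[var], size=T)
                out.append(
                    RawSeries(
                        unit_id=unit,
                        group_label=group,
                        condition_label=cond,
                        variable_name=var,
                        times=grid * 39.0,  # nominal day index within the window
                        values=_inject_missing(values, missing_rate, rng),
                        times_norm=grid,
                    )
                )
    return out
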