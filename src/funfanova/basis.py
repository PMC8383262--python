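"""B-spline basis representation of discretely observed curves.

Curves observed at a finite set of time points are reconstructed as finite
basis expansions ``X_j(t) = sum_k a_jk phi_k(t)`` against a cubic B-spline
system, the standard choice for smooth non-periodic data.  All downstream
testing machinery works on the ``n x p`` coefficient matrices together with
the Gram matrix ``W`` of basis inner products, which carries the L2 geometry
of the function space into coefficient space.

The basis coefficients are estimated by ordinary (unpenalized) least
squares; smoothness is controlled through the basis dimension ``p`` alone
(a small ``p`` such as 7 captures trend only, ``p = 20`` recovers local
behaviour of a few-week daily series).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline

__all__ = [
    "BasisError",
    "DomainError",
    "UnderdeterminedFitError",
    "BSplineBasis",
    "RawSeries",
    "FunctionalSample",
    "make_bspline_basis",
    "gram_matrix",
    "fit_coefficients",
    "evaluate_curves",
]


class BasisError(ValueError):
    """Invalid basis configuration (e.g. dimension below the spline order)."""


class DomainError(ValueError):
    """Evaluation or observation times fall outside the basis domain."""


class UnderdeterminedFitError(ValueError):
    """Fewer usable observations than basis functions."""


@dataclass(frozen=True)
class BSplineBasis:
    """A clamped B-spline basis on a closed interval.

    Parameters
    ----------
    domain : tuple of float
        Closed interval ``[a, b]`` (normalized time units).
    order : int
        Spline order (degree + 1); 4 gives cubic splines.
    n_basis : int
        Basis dimension ``p`` = number of interior knots + order.
    knots : ndarray
        Full clamped knot vector (endpoints repeated ``order`` times).
    gram : ndarray
        ``p x p`` matrix ``W`` with entries ``\\int phi_k phi_l dt``.
    """

    domain: tuple[float, float]
    order: int
    n_basis: int
    knots: np.ndarray = field(repr=False)
    gram: np.ndarray = field(repr=False)

    @property
    def degree(self) -> int:
        return self.order - 1

    def _check_times(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        a, b = self.domain
        if t.size and (t.min() < a - 1e-12 or t.max() > b + 1e-12):
            raise DomainError(
                f"times outside basis domain [{a}, {b}]: "
                f"range [{t.min()}, {t.max()}]"
            )
        return np.clip(t, a, b)

    def design_matrix(self, t: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions at ``t`` -> ``len(t) x p`` matrix."""
        t = self._check_times(np.atleast_1d(t))
        return BSpline.design_matrix(t, self.knots, self.degree).toarray()

    def to_header(self) -> dict:
        """JSON-serializable description (used by the exchange format)."""
        return {
            "domain": list(self.domain),
            "order": self.order,
            "n_basis": self.n_basis,
            "knots": self.knots.tolist(),
        }

    @classmethod
    def from_header(cls, header: dict) -> "BSplineBasis":
        basis = make_bspline_basis(
            tuple(header["domain"]), header["n_basis"], header["order"]
        )
        if not np.allclose(basis.knots, header["knots"]):
            knots = np.asarray(header["knots"], dtype=float)
            basis = _basis_from_knots(tuple(header["domain"]), header["order"], knots)
        return basis


def make_bspline_basis(
    domain: tuple[float, float] = (0.0, 1.0),
    n_basis: int = 20,
    order: int = 4,
) -> BSplineBasis:
    """Build a clamped B-spline basis with equally spaced interior knots.

    ``n_basis`` must be at least ``order``; the number of interior knots is
    ``n_basis - order``.  The Gram matrix is computed by Gauss-Legendre
    quadrature on each inter-knot interval, exact for piecewise polynomials.
    """
    a, b = float(domain[0]), float(domain[1])
    if not np.isfinite(a) or not np.isfinite(b) or b <= a:
        raise DomainError(f"degenerate domain [{a}, {b}]")
    if order < 1:
        raise BasisError(f"spline order must be >= 1, got {order}")
    if n_basis < order:
        raise BasisError(f"n_basis ({n_basis}) must be >= order ({order})")
    n_interior = n_basis - order
    interior = np.linspace(a, b, n_interior + 2)[1:-1]
    knots = np.concatenate([np.full(order, a), interior, np.full(order, b)])
    return _basis_from_knots((a, b), order, knots)


def _basis_from_knots(
    domain: tuple[float, float], order: int, knots: np.ndarray
) -> BSplineBasis:
    n_basis = len(knots) - order
    basis = BSplineBasis(
        domain=domain, order=order, n_basis=n_basis, knots=knots,
        gram=np.empty((0, 0)),
    )
    gram = gram_matrix(basis)
    object.__setattr__(basis, "gram", gram)
    return basis


def gram_matrix(basis: BSplineBasis, quadrature_order: int | None = None) -> np.ndarray:
    """Matrix of inner products ``W[k, l] = \\int phi_k phi_l dt``.

    Gauss-Legendre with ``quadrature_order`` nodes per inter-knot interval
    (default ``2 * order``); products of two splines of degree ``order - 1``
    are polynomials of degree ``2 order - 2`` on each interval, so any node
    count >= ``order`` is exact up to rounding.
    """
    m = 2 * basis.order if quadrature_order is None else int(quadrature_order)
    if m < 1:
        raise BasisError("quadrature_order must be positive")
    nodes, weights = leggauss(m)
    breaks = np.unique(basis.knots)
    W = np.zeros((basis.n_basis, basis.n_basis))
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (hi - lo)
        t = lo + half * (nodes + 1.0)
        Phi = basis.design_matrix(t)
        W += half * (Phi.T * weights) @ Phi
    return 0.5 * (W + W.T)


@dataclass
class RawSeries:
    """One discretely observed curve: a (unit, variable, condition) series.

    ``values`` may contain NaN for missing observations; ``times`` must be
    strictly increasing.  ``times_norm`` is the affine map of ``times`` onto
    [0, 1] (shared across units within a condition window so that all curves
    of one analysis live on a common normalized domain).
    """

    unit_id: str
    group_label: str
    condition_label: str
    variable_name: str
    times: np.ndarray
    values: np.ndarray
    times_norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.times_norm is None:
            lo, hi = self.times.min(), self.times.max()
            span = hi - lo if hi > lo else 1.0
            self.times_norm = (self.times - lo) / span
        else:
            self.times_norm = np.asarray(self.times_norm, dtype=float)


def fit_coefficients(series: RawSeries, basis: BSplineBasis) -> np.ndarray:
    """Ordinary least-squares basis coefficients for one observed series.

    Missing values are dropped before fitting; the fit requires at least
    ``p`` usable observations inside the basis domain.
    """
    mask = np.isfinite(series.values)
    t = series.times_norm[mask]
    y = series.values[mask]
    if t.size < basis.n_basis:
        raise UnderdeterminedFitError(
            f"{t.size} usable points < basis dimension {basis.n_basis} "
            f"(unit={series.unit_id}, variable={series.variable_name})"
        )
    Phi = basis.design_matrix(t)  # raises DomainError if outside domain
    coef, *_ = np.linalg.lstsq(Phi, y, rcond=None)
    return coef


@dataclass
class FunctionalSample:
    """``n`` curves of one functional variable as basis coefficients.

    ``coefficients`` is the ``n x p`` matrix ``A`` whose row ``j`` holds the
    basis coefficients ``a_j`` of unit ``j``'s curve.
    """

    basis: BSplineBasis
    coefficients: np.ndarray
    unit_ids: list[str]
    variable_name: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, dtype=float))
        if self.coefficients.shape[0] != len(self.unit_ids):
            raise ValueError("coefficient rows must match number of unit ids")
        if self.coefficients.shape[1] != self.basis.n_basis:
            raise ValueError("coefficient columns must match basis dimension")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    @property
    def n_units(self) -> int:
        return self.coefficients.shape[0]

    @classmethod
    def from_series(
        cls, series: list[RawSeries], basis: BSplineBasis
    ) -> "FunctionalSample":
        """Smooth a list of observed series (one per unit) into a sample."""
        if not series:
            raise ValueError("empty series list")
        names = {s.variable_name for s in series}
        if len(names) > 1:
            raise ValueError(f"mixed variables in one sample: {sorted(names)}")
        coefs = np.vstack([fit_coefficients(s, basis) for s in series])
        return cls(
            basis=basis,
            coefficients=coefs,
            unit_ids=[s.unit_id for s in series],
            variable_name=series[0].variable_name,
        )

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        return evaluate_curves(self, grid)

    def mean_curve(self, grid: np.ndarray) -> np.ndarray:
        return self.basis.design_matrix(grid) @ self.coefficients.mean(axis=0)


def evaluate_curves(sample: FunctionalSample, grid: np.ndarray) -> np.ndarray:
    """Evaluate every curve on ``grid`` -> ``n x len(grid)`` matrix."""
    Phi = sample.basis.design_matrix(grid)
    return sample.coefficients @ Phi.T


def save_coefficients(sample: FunctionalSample, path) -> None:
    """Write a sample as plain numeric text with a JSON comment header."""
    header = sample.basis.to_header()
    header["variable_name"] = sample.variable_name
    header["unit_ids"] = list(sample.unit_ids)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        np.savetxt(fh, sample.coefficients)


def load_coefficients(path) -> FunctionalSample:
    """Read a sample written by :func:`save_coefficients`."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("missing JSON header line")
        header = json.loads(first[1:].strip())
        coefs = np.loadtxt(fh, ndmin=2)
    basis = BSplineBasis.from_header(header)
    return FunctionalSample(
        basis=basis,
        coefficients=coefs,
        unit_ids=list(header.get("unit_ids", [str(i) for i in range(len(coefs))])),
        variable_name=header.get("variable_name", ""),
    )
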