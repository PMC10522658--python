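"""Distributed lag non-linear model (DLNM) machinery.

A DLNM describes how the effect of an exposure (here daily temperature or
relative humidity) varies jointly along the exposure dimension and along the
lag dimension.  Both dimensions are modelled with natural cubic splines; their
tensor product forms the *cross-basis*, a design matrix whose coefficients
encode the full exposure-lag-response surface.  Cumulative associations —
the sum over lag days of lag-specific log-rate-ratios at one temperature
versus a reference temperature — are linear functionals of the coefficients,
so delta-method variances follow from a single gradient vector.

The exposure-dimension basis is a natural cubic spline (linear beyond the
boundary knots, no intercept column); the lag-dimension basis is an intercept
column plus a natural cubic spline in ``log(lag + 1)``, the conventional
default for lag structures concentrated at short lags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineSpec",
    "CrossBasisSpec",
    "CrossBasisMatrix",
    "natural_spline_basis",
    "lag_basis",
    "build_cross_basis",
    "cumulative_contrast",
]


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout for a natural cubic spline basis with ``df`` columns.

    A natural cubic spline with ``df`` degrees of freedom (no intercept) has
    ``df - 1`` interior knots; the basis is constrained to be linear beyond
    the boundary knots.
    """

    df: int
    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")
        if len(self.interior_knots) != self.df - 1:
            raise ValueError(
                f"df={self.df} requires {self.df - 1} interior knots, "
                f"got {len(self.interior_knots)}"
            )
        lo, hi = self.boundary_knots
        if not np.isfinite([lo, hi]).all() or lo >= hi:
            raise ValueError(f"invalid boundary knots ({lo}, {hi})")
        ks = np.asarray(self.interior_knots, dtype=float)
        if ks.size and (np.any(ks <= lo) or np.any(ks >= hi)):
            raise ValueError("interior knots must lie strictly inside boundary knots")
        if ks.size != np.unique(ks).size:
            raise ValueError("duplicate interior knots")

    @classmethod
    def from_data(cls, x, df: int) -> "SplineSpec":
        """Place interior knots at equally spaced percentiles of ``x``.

        For ``df = 3`` the knots sit at the 33.3rd and 66.7th percentiles;
        boundary knots at the observed min/max.
        """
        x = np.asarray(x, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if x.size == 0:
            raise ValueError("no finite values to place knots on")
        lo, hi = float(x.min()), float(x.max())
        if lo == hi:
            raise ValueError("degenerate data: all values identical")
        probs = np.linspace(0, 100, df + 1)[1:-1]
        knots = tuple(float(k) for k in np.percentile(x, probs)) if df > 1 else ()
        return cls(df=df, interior_knots=knots, boundary_knots=(lo, hi))

    @classmethod
    def equally_spaced(cls, df: int, lo: float, hi: float) -> "SplineSpec":
        """Interior knots equally spaced between ``lo`` and ``hi``."""
        knots = tuple(np.linspace(lo, hi, df + 1)[1:-1]) if df > 1 else ()
        return cls(df=df, interior_knots=knots, boundary_knots=(lo, hi))


def _bspline_design(x: np.ndarray, t: np.ndarray, nu: int = 0) -> np.ndarray:
    """Evaluate all cubic B-spline basis functions (or a derivative) at x."""
    n_basis = len(t) - 4
    out = np.empty((x.size, n_basis))
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        out[:, j] = BSpline(t, c, 3, extrapolate=False)(x, nu=nu)
    return np.nan_to_num(out, nan=0.0)


def natural_spline_basis(x, spec: SplineSpec) -> np.ndarray:
    """Natural cubic spline basis matrix, shape ``(len(x), spec.df)``.

    Construction: the cubic B-spline basis on the augmented knot sequence,
    with the intercept column dropped and the two second-derivative-at-
    boundary constraints removed by projection onto their null space (QR).
    Beyond the boundary knots every column continues linearly with the value
    and slope it attains at the boundary, so evaluation is exact at arbitrary
    points.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in spline input")
    lo, hi = spec.boundary_knots
    t = np.concatenate([[lo] * 4, np.asarray(spec.interior_knots, float), [hi] * 4])

    boundary = np.array([lo, hi])
    # constraint rows: second derivatives at the two boundary knots
    const = _bspline_design(boundary, t, nu=2)[:, 1:]

    inside = np.clip(x, lo, hi)
    design = _bspline_design(inside, t)[:, 1:]
    below, above = x < lo, x > hi
    if below.any() or above.any():
        b_val = _bspline_design(boundary, t)[:, 1:]
        b_slope = _bspline_design(boundary, t, nu=1)[:, 1:]
        if below.any():
            design[below] = b_val[0] + np.outer(x[below] - lo, b_slope[0])
        if above.any():
            design[above] = b_val[1] + np.outer(x[above] - hi, b_slope[1])

    q, _ = np.linalg.qr(const.T, mode="complete")
    return design @ q[:, 2:]


def lag_basis(max_lag: int, lag_df: int | None) -> np.ndarray:
    """Lag-dimension basis at integer lags ``0..max_lag``.

    The first column is an intercept; the remaining ``lag_df - 1`` columns
    are a natural cubic spline in ``log(lag + 1)`` with interior knots
    equally spaced on the log-lag scale (``lag_df = 4`` gives 2 interior
    knots).  ``lag_df=None`` yields an unconstrained basis (one indicator
    column per lag), used for the short-lag secondary model.
    """
    lags = np.arange(max_lag + 1, dtype=float)
    if lag_df is None:
        return np.eye(max_lag + 1)
    ones = np.ones((lags.size, 1))
    if lag_df == 1:
        return ones
    inner = SplineSpec.equally_spaced(lag_df - 1, 0.0, float(np.log(max_lag + 1.0)))
    return np.hstack([ones, natural_spline_basis(np.log(lags + 1.0), inner)])


@dataclass(frozen=True)
class CrossBasisSpec:
    """Full specification of one exposure's cross-basis.

    ``var_spec`` governs the exposure dimension, ``lag_df`` the lag dimension
    (intercept plus natural spline in log-lag; ``None`` for an unconstrained
    per-lag basis), ``reference_value`` the exposure level all contrasts are
    taken against.
    """

    var_spec: SplineSpec
    max_lag: int
    lag_df: int | None = 4
    reference_value: float = 0.0

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        if not np.isfinite(self.reference_value):
            raise ValueError("reference_value must be finite")
        if self.lag_df is not None and self.lag_df < 1:
            raise ValueError("lag_df must be >= 1 or None")

    @property
    def n_lag_cols(self) -> int:
        return (self.max_lag + 1) if self.lag_df is None else self.lag_df

    @property
    def n_columns(self) -> int:
        return self.var_spec.df * self.n_lag_cols

    def lag_matrix(self) -> np.ndarray:
        return lag_basis(self.max_lag, self.lag_df)

    @classmethod
    def from_exposure(cls, lagged_exposure, var_df: int, max_lag: int,
                      lag_df: int | None, reference_value: float | None = None
                      ) -> "CrossBasisSpec":
        """Knots from the pooled lagged exposure distribution; reference
        defaults to the observed minimum."""
        vals = np.asarray(lagged_exposure, float).ravel()
        spec = SplineSpec.from_data(vals, var_df)
        ref = float(np.nanmin(vals)) if reference_value is None else reference_value
        return cls(var_spec=spec, max_lag=max_lag, lag_df=lag_df,
                   reference_value=ref)


@dataclass
class CrossBasisMatrix:
    """Realized cross-basis design block: rows follow the input rows,
    columns are (var basis j, lag basis k) pairs, j-major."""

    values: np.ndarray
    column_names: list[str]
    spec: CrossBasisSpec


def build_cross_basis(lagged_exposure, spec: CrossBasisSpec) -> CrossBasisMatrix:
    """Tensor-product expansion of a rows x (max_lag+1) lagged-exposure matrix.

    Entry ``(i, (j, k)) = sum_l v_j(x[i, l]) * L_k(l)`` where ``v_j`` are the
    exposure-basis functions and ``L_k`` the lag-basis functions.
    """
    x = np.asarray(lagged_exposure, dtype=float)
    if x.ndim != 2 or x.shape[1] != spec.max_lag + 1:
        raise ValueError(
            f"lagged exposure must have {spec.max_lag + 1} columns, got shape {x.shape}"
        )
    bad = ~np.isfinite(x).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite exposure at rows {np.flatnonzero(bad)[:10].tolist()}")
    n, n_lags = x.shape
    v = natural_spline_basis(x.ravel(), spec.var_spec).reshape(n, n_lags, spec.var_spec.df)
    lmat = spec.lag_matrix()
    values = np.einsum("nlj,lk->njk", v, lmat).reshape(n, -1)
    names = [f"v{j+1}.l{k+1}" for j in range(spec.var_spec.df)
             for k in range(lmat.shape[1])]
    return CrossBasisMatrix(values=values, column_names=names, spec=spec)


def contrast_gradient(spec: CrossBasisSpec, at: float,
                      lag_subset=None) -> np.ndarray:
    """Gradient of the cumulative log-rate-ratio contrast w.r.t. the
    cross-basis coefficients: ``g_(j,k) = sum_{l in subset}
    [v_j(at) - v_j(ref)] * L_k(l)``."""
    if not np.isfinite(at):
        raise ValueError("contrast temperature must be finite")
    lags = np.arange(spec.max_lag + 1)
    if lag_subset is None:
        lag_subset = set(lags.tolist())
    lag_subset = set(int(l) for l in lag_subset)
    if not lag_subset <= set(lags.tolist()):
        raise ValueError(f"lag_subset {lag_subset} outside 0..{spec.max_lag}")
    dv = (natural_spline_basis([at], spec.var_spec)
          - natural_spline_basis([spec.reference_value], spec.var_spec))[0]
    lmat = spec.lag_matrix()
    lsum = lmat[sorted(lag_subset), :].sum(axis=0)
    return np.outer(dv, lsum).ravel()


def cumulative_contrast(coefficients, covariance, spec: CrossBasisSpec,
                        at: float, lag_subset=None) -> tuple[float, float]:
    """Cumulative log-rate-ratio at ``at`` versus the reference, summed over
    ``lag_subset`` (default: all lags), with its delta-method variance.

    Returns ``(g' theta, g' Sigma g)``.
    """
    theta = np.asarray(coefficients, dtype=float).ravel()
    sigma = np.asarray(covariance, dtype=float)
    if theta.size != spec.n_columns:
        raise ValueError(
            f"coefficient length {theta.size} != cross-basis width {spec.n_columns}"
        )
    g = contrast_gradient(spec, at, lag_subset)
    eta = float(g @ theta)
    var = float(g @ sigma @ g)
    return eta, max(var, 0.0)
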