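"""Sample dynamical correlation for replicated longitudinal data.

Omics time courses are short, irregularly sampled, and come in a handful of
biological replicates.  Ordinary Pearson correlation across time points treats
the trajectory as an unordered sample; the *dynamical* correlation instead
treats each trajectory as a function of time and correlates functions through
a time-averaged inner product,

    <u, v> = 1/(t_N - t_1) * integral_{t_1}^{t_N} u(t) v(t) dt,

approximated on the sampling knots by a trapezoid-weighted sum.  Trajectories
are centered by the grand mean of per-replicate time averages, standardized by
a pooled (across replicates) variance, and the replicate-wise inner products
are pooled with a 1/(M-1) prefactor.  The resulting matrix R is symmetric,
positive semidefinite, has unit diagonal, and is invariant to positive affine
rescaling of each variable.

Irregular native grids are first lifted to a common uniform grid by cubic
spline interpolation (one spline per replicate, not-a-knot boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import CubicSpline

__all__ = [
    "ReplicatedTimeSeries",
    "DynCorrResult",
    "quadrature_weights",
    "dynamical_inner_product",
    "interpolate_to_grid",
    "dynamical_correlation",
    "detrended_normality_test",
]


@dataclass
class ReplicatedTimeSeries:
    """Trajectories of one variable over a time grid across M replicates.

    Parameters
    ----------
    variable : str
        Node identifier (peak, transcript or protein id).
    grid : ndarray, shape (N,)
        Strictly increasing sampling times in hours.
    values : ndarray, shape (M, N)
        One row per replicate.
    layer : {'a', 's', 'p'}
        Omics layer: chromatin accessibility, splice expression, protein.
    """

    variable: str
    grid: np.ndarray
    values: np.ndarray
    layer: str = "a"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError(f"{self.variable}: grid needs >= 2 time points")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError(f"{self.variable}: grid must be strictly increasing")
        if self.values.shape[1] != self.grid.size:
            raise ValueError(
                f"{self.variable}: values shape {self.values.shape} does not "
                f"match grid of length {self.grid.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.variable}: non-finite values")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.grid.size


def quadrature_weights(grid: np.ndarray) -> np.ndarray:
    """Trapezoid-on-knots weights normalized by the span.

    w_1 = (t_2 - t_1) / (2 (t_N - t_1)), w_N symmetric, interior
    w_k = (t_{k+1} - t_{k-1}) / (2 (t_N - t_1)).  The weights sum to one, so
    ``sum(w * u * v)`` approximates the span-normalized integral of u*v.
    """
    t = np.asarray(grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("grid needs >= 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("grid must be strictly increasing")
    span = t[-1] - t[0]
    w = np.empty_like(t)
    w[0] = (t[1] - t[0]) / (2 * span)
    w[-1] = (t[-1] - t[-2]) / (2 * span)
    w[1:-1] = (t[2:] - t[:-2]) / (2 * span)
    return w


def dynamical_inner_product(u: np.ndarray, v: np.ndarray, grid: np.ndarray) -> float:
    """Weighted knot product ``sum_k w_k u_k v_k`` on a common grid."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    w = quadrature_weights(grid)
    if u.shape[-1] != w.size or v.shape[-1] != w.size:
        raise ValueError("u, v and grid must have equal lengths")
    return float(np.sum(w * u * v))


def interpolate_to_grid(
    series: ReplicatedTimeSeries,
    target_step: float = 0.5,
    span: tuple[float, float] = (0.0, 24.0),
) -> ReplicatedTimeSeries:
    """Cubic-spline each replicate independently onto a uniform grid.

    For the default span [0, 24] h at 0.5 h resolution the returned grid has
    49 points.  Requires >= 4 native points (cubic order) covering the span.
    """
    if series.n_times < 4:
        raise ValueError(
            f"{series.variable}: cubic spline interpolation needs >= 4 native "
            f"time points, got {series.n_times}"
        )
    lo, hi = span
    if series.grid[0] > lo or series.grid[-1] < hi:
        raise ValueError(f"{series.variable}: native grid does not cover span {span}")
    n = int(round((hi - lo) / target_step)) + 1
    target = lo + target_step * np.arange(n)
    out = np.empty((series.n_replicates, n))
    for r in range(series.n_replicates):
        out[r] = CubicSpline(series.grid, series.values[r])(target)
    return ReplicatedTimeSeries(series.variable, target, out, series.layer)


def _centered(series: ReplicatedTimeSeries) -> np.ndarray:
    """Center by the grand mean of per-replicate time averages."""
    grand = series.values.mean(axis=1).mean()
    return series.values - grand


def _pooled_variance(xc: np.ndarray, w: np.ndarray, m: int) -> float:
    denom = m - 1 if m > 1 else 1
    return float(np.sum(w * xc * xc) / denom)


@dataclass
class DynCorrResult:
    """Sample dynamical correlation/covariance over a set of variables."""

    ids: list[str]
    R: np.ndarray
    Sigma: np.ndarray
    variances: np.ndarray
    grand_means: np.ndarray
    layers: dict[str, str] = field(default_factory=dict)
    standardized: dict[str, np.ndarray] = field(default_factory=dict)
    grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.ids)}

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown variable {name!r}") from None

    def r(self, x: str, y: str) -> float:
        return float(self.R[self.index(x), self.index(y)])

    def submatrix(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.index(n) for n in names]
        return self.R[np.ix_(idx, idx)]


def dynamical_correlation(
    series: Iterable[ReplicatedTimeSeries],
    subset: Sequence[str] | None = None,
) -> DynCorrResult:
    """Pooled-replicate dynamical correlation and covariance matrices.

    All series must share one grid and one replicate count.  Per variable the
    pooled variance is ``Var = 1/(M-1) sum_r <x_r^C, x_r^C>`` (no prefactor for
    M = 1) and ``R_ij = 1/(M-1) sum_r <x_{i,r}^S, x_{j,r}^S>`` with
    ``x^S = x^C / sqrt(Var)``.
    """
    pool = {s.variable: s for s in series}
    names = list(subset) if subset is not None else list(pool)
    if not names:
        raise ValueError("no variables given")
    missing = [n for n in names if n not in pool]
    if missing:
        raise KeyError(f"variables missing from the collection: {missing}")
    first = pool[names[0]]
    grid, m = first.grid, first.n_replicates
    for n in names:
        s = pool[n]
        if s.n_replicates != m or s.grid.shape != grid.shape or not np.allclose(s.grid, grid):
            raise ValueError(
                f"{n}: all series must share one grid and replicate count "
                "(interpolate to a common grid first)"
            )
    w = quadrature_weights(grid)
    denom = m - 1 if m > 1 else 1

    cent = np.empty((len(names), m, grid.size))
    grand_means = np.empty(len(names))
    for i, n in enumerate(names):
        cent[i] = _centered(pool[n])
        grand_means[i] = pool[n].values.mean(axis=1).mean()
    variances = np.einsum("imk,imk,k->i", cent, cent, w) / denom
    bad = [names[i] for i in np.flatnonzero(variances <= 0)]
    if bad:
        raise ValueError(f"zero pooled variance (constant series): {bad}")
    std = cent / np.sqrt(variances)[:, None, None]
    R = np.einsum("imk,jmk,k->ij", std, std, w) / denom
    Sigma = R * np.sqrt(np.outer(variances, variances))
    # symmetrize away float noise; unit diagonal is exact algebraically
    R = (R + R.T) / 2
    np.fill_diagonal(R, 1.0)
    Sigma = (Sigma + Sigma.T) / 2
    return DynCorrResult(
        ids=names,
        R=R,
        Sigma=Sigma,
        variances=variances,
        grand_means=grand_means,
        layers={n: pool[n].layer for n in names},
        standardized={n: std[i] for i, n in enumerate(names)},
        grid=grid.copy(),
    )


def standardized_values(series: ReplicatedTimeSeries) -> np.ndarray:
    """Centered, pooled-variance-standardized values (detrended data)."""
    xc = _centered(series)
    w = quadrature_weights(series.grid)
    var = _pooled_variance(xc, w, series.n_replicates)
    if var <= 0:
        raise ValueError(f"{series.variable}: constant series")
    return xc / np.sqrt(var)


def detrended_normality_test(
    series: Iterable[ReplicatedTimeSeries], alpha: float = 0.01
):
    """Kolmogorov-Smirnov screen of pooled standardized values against N(0,1).

    Returns a DataFrame with one row per variable: the KS statistic, p value
    and a reject flag at ``alpha``.  Used to check that detrending makes the
    data plausibly Gaussian before a correlation analysis.
    """
    import pandas as pd

    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    rows = []
    for s in series:
        z = standardized_values(s).ravel()
        stat, p = stats.kstest(z, "norm")
        rows.append(
            {
                "variable": s.variable,
                "layer": s.layer,
                "n": z.size,
                "ks_stat": stat,
                "p_value": p,
                "reject": bool(p < alpha) if alpha < 1 else True,
            }
        )
    return pd.DataFrame(rows)
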