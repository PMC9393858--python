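"""Classical-nucleation-theory interpretation of the dG increments.

CNT writes dG(n) = mu_diff * n + c * n^{2/3}, so the per-particle increment
deltaG(n) = dG(n) - dG(n-1) is linear in x = n^{2/3} - (n-1)^{2/3}:

    deltaG = b + s x.

The intercept b is the chemical-potential difference between the infinite
cluster (bulk phase) and the reservoir gas; the slope s relates to the
surface tension through s = (36 pi / rho^2)^{1/3} gamma with rho the bulk
density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .umbrella import DeltaGSeries


@dataclass
class FitResult:
    slope: float
    intercept: float
    slope_err: float
    intercept_err: float
    n_lo: int
    n_hi: int
    weighting: str = "weighted"

    def __post_init__(self):
        if self.slope_err < 0 or self.intercept_err < 0:
            raise ValueError("errors must be >= 0")
        if self.n_lo > self.n_hi:
            raise ValueError("empty fit range")


def fit_line(series: DeltaGSeries, n_range: tuple[int, int] | None = None,
             weighted: bool = True) -> FitResult:
    """Least-squares line deltaG = b + s*x over the requested size range.

    Weighted (1/sigma^2) when per-row errors are available and positive;
    falls back to unweighted otherwise.  Parameter errors come from the
    weighted covariance (known sigmas) or from the residual variance
    (unweighted fallback).
    """
    if n_range is None:
        n_range = (int(series.n.min()), int(series.n.max()))
    sub = series.restrict(*n_range)
    m = len(sub.n)
    if m < 3:
        raise ValueError(f"need >= 3 points in range {n_range}, got {m}")
    x, y = sub.x, sub.delta
    use_w = weighted and np.all(np.isfinite(sub.se)) and np.all(sub.se > 0)
    w = 1.0 / sub.se ** 2 if use_w else np.ones(m)
    X = np.column_stack([np.ones(m), x])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    b, s = cov @ (XtW @ y)
    if use_w:
        perr = np.sqrt(np.diag(cov))
    else:
        resid = y - (b + s * x)
        sigma2 = float(resid @ resid) / (m - 2)
        perr = np.sqrt(np.diag(cov) * sigma2)
    return FitResult(slope=float(s), intercept=float(b),
                     slope_err=float(perr[1]), intercept_err=float(perr[0]),
                     n_lo=n_range[0], n_hi=n_range[1],
                     weighting="weighted" if use_w else "unweighted")


def surface_tension(fit: FitResult, rho: float,
                    rho_err: float = 0.0) -> tuple[float, float]:
    """gamma = s / (36 pi / rho^2)^{1/3}, with propagated error."""
    if rho <= 0:
        raise ValueError("rho must be > 0")
    factor = (36.0 * math.pi / rho ** 2) ** (1.0 / 3.0)
    gamma = fit.slope / factor
    # d(gamma)/d(s) = 1/factor ; d(gamma)/d(rho) = (2/3) gamma / rho
    err = math.hypot(fit.slope_err / factor,
                     (2.0 / 3.0) * gamma / rho * rho_err)
    return gamma, err


def chemical_potential(fit: FitResult, reservoir) -> tuple[float, float]:
    """Bulk-phase chemical potential mu = b + T ln(n_v), kinetic term excluded.

    The intercept is the chemical-potential difference to the reservoir
    gas, whose own value is T ln(n_v) in the convention used here; at
    n_v = 1 the intercept is the bulk chemical potential directly.
    """
    mu = fit.intercept + reservoir.T * math.log(reservoir.n_v)
    return mu, fit.intercept_err
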