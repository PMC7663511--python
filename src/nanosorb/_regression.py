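"""Shared ordinary-least-squares helper for the linearized model fits.

Every linearized isotherm/kinetic fit in this package is a straight-line
OLS regression in some transformed space; this wrapper returns slope,
intercept, their full covariance (needed for delta-method propagation to
model parameters) and R^2 computed in the regression space.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["LineFit", "fit_line", "delta_sd"]


@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float
    slope_sd: float
    intercept_sd: float
    cov_slope_intercept: float
    r_squared: float
    sse: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_line(x, y, min_points: int = 3) -> LineFit:
    """OLS of y on x. Requires >= ``min_points`` points and non-degenerate x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"x and y lengths differ ({x.size} vs {y.size})")
    if x.size < min_points:
        raise ValueError(f"need at least {min_points} points for a line fit, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the regressor; cannot fit a line")

    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    cov = res.cov_params()
    resid = y - (slope * x + intercept)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst > 0:
        r2 = 1.0 - sse / sst
    else:
        # flat response: a perfect fit if residuals vanish, else undefined -> 0
        r2 = 1.0 if sse <= 1e-24 * max(1.0, float(np.abs(y).max()) ** 2) else 0.0
    return LineFit(
        slope=float(slope),
        intercept=float(intercept),
        slope_sd=float(np.sqrt(max(cov[1, 1], 0.0))),
        intercept_sd=float(np.sqrt(max(cov[0, 0], 0.0))),
        cov_slope_intercept=float(cov[0, 1]),
        r_squared=float(min(r2, 1.0)),
        sse=sse,
        n=int(x.size),
    )


def delta_sd(line: LineFit, d_dslope: float, d_dintercept: float) -> float:
    """First-order SD of g(slope, intercept) given its partial derivatives."""
    var = (
        d_dslope**2 * line.slope_sd**2
        + d_dintercept**2 * line.intercept_sd**2
        + 2.0 * d_dslope * d_dintercept * line.cov_slope_intercept
    )
    return float(np.sqrt(max(var, 0.0)))
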