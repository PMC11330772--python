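"""Small shared statistical helpers (AICc, weighted OLS)."""

from __future__ import annotations

import math

import numpy as np

from .errors import InputError


def aicc(rss: float, n_obs: int, n_params: int) -> float:
    """Corrected Akaike information criterion for a Gaussian LS fit.

    Uses the residual-sum-of-squares form AIC = n·ln(RSS/n) + 2k with the
    small-sample correction 2k(k+1)/(n−k−1).  Returns +inf when the
    correction denominator is non-positive (model too rich for the data).
    """
    if n_obs <= 0:
        raise InputError("AICc requires at least one observation")
    rss = max(float(rss), 1e-300)  # guard log(0) on exact fits
    aic = n_obs * math.log(rss / n_obs) + 2 * n_params
    denom = n_obs - n_params - 1
    if denom <= 0:
        return math.inf
    return aic + 2 * n_params * (n_params + 1) / denom


def weighted_line_fit(
    x: np.ndarray,
    y: np.ndarray,
    se: np.ndarray | None = None,
) -> tuple[float, float, float, float]:
    """Weighted least-squares straight line y = slope·x + intercept.

    Weights are 1/se² when per-point standard errors are supplied,
    otherwise unweighted.  Returns (slope, intercept, slope_se,
    intercept_se); parameter standard errors are scaled by the reduced
    chi-square so the unweighted case matches ordinary OLS errors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    if x.size < 2:
        raise InputError("need at least two points for a line fit")
    if se is not None:
        se = np.asarray(se, dtype=float)
        if np.any(se <= 0):
            raise InputError("standard errors must be strictly positive")
        w = 1.0 / se**2
    else:
        w = np.ones_like(x)

    W = np.sum(w)
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * y) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx <= 0:
        raise InputError("x values are all identical; slope is unidentifiable")
    slope = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar

    resid = y - (slope * x + intercept)
    dof = x.size - 2
    if dof > 0:
        s2 = np.sum(w * resid**2) / dof
    else:
        s2 = 0.0
    slope_se = math.sqrt(s2 / sxx)
    intercept_se = math.sqrt(s2 * (1.0 / W + xbar**2 / sxx))
    return float(slope), float(intercept), slope_se, intercept_se
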