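"""Two-lines test for U-shaped predictor-outcome relationships.

Instead of testing a quadratic term, the two-lines approach fits an
interrupted regression with separate slopes on each side of a breakpoint c:

    y ~ b0 + b_low * min(x - c, 0) + b_high * max(x - c, 0)  (+ covariates)

and declares a U (or inverted U) only when the two slopes have opposite
signs and each is individually significant at p < 0.10.  The breakpoint is
either the sample median or the flat point of a local-averaging (lowess)
smooth of y on x, where the smoothed curve's slope changes sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

SLOPE_ALPHA = 0.10  # per-slope significance gate of the two-lines criterion


@dataclass
class TwoLinesResult:
    breakpoint: float
    b_low: float
    p_low: float
    b_high: float
    p_high: float
    u_shaped: bool
    breakpoint_method: str = "given"

    def as_dict(self) -> dict:
        return {
            "breakpoint": self.breakpoint, "b_low": self.b_low, "p_low": self.p_low,
            "b_high": self.b_high, "p_high": self.p_high,
            "u_shaped": self.u_shaped, "breakpoint_method": self.breakpoint_method,
        }


def select_breakpoint(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "smooth_flat_region",
    lowess_frac: float = 0.5,
) -> tuple[float, str]:
    """Breakpoint for the two-lines fit; returns (value, method actually used).

    ``median`` uses the sample median of x.  ``smooth_flat_region`` lowess-
    smooths y on x and returns the x where the smoothed slope changes sign
    (the curve's flat point); if the smooth is monotone it falls back to
    the median (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 30:
        raise ValueError("breakpoint selection needs at least 30 points")
    if method == "median":
        return float(np.median(x)), "median"
    if method != "smooth_flat_region":
        raise ValueError(f"unknown breakpoint method {method!r}")

    smooth = sm.nonparametric.lowess(y, x, frac=lowess_frac)
    xs, ys = smooth[:, 0], smooth[:, 1]
    ds = np.diff(ys)
    sign_change = np.flatnonzero(np.sign(ds[:-1]) * np.sign(ds[1:]) < 0) + 1
    if sign_change.size == 0:
        log.warning("smoothed curve is monotone; falling back to median breakpoint")
        return float(np.median(x)), "median_fallback"
    # among slope sign changes, take the one at the curve's extremum
    mid = 0.5 * (ys[0] + ys[-1])
    best = sign_change[np.argmax(np.abs(ys[sign_change] - mid))]
    return float(xs[best]), "smooth_flat_region"


def two_lines_test(
    x: np.ndarray,
    y: np.ndarray,
    breakpoint: float | None = None,
    covariates: pd.DataFrame | np.ndarray | None = None,
    breakpoint_method: str = "smooth_flat_region",
    min_side: int = 10,
) -> TwoLinesResult:
    """Fit the interrupted regression and apply the two-lines U criterion.

    ``u_shaped`` is True iff the slopes left and right of the breakpoint
    have opposite signs and both are significant at p < 0.10.  Covariate
    adjustment is optional (the default is the bivariate test).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    method = "given"
    if breakpoint is None:
        breakpoint, method = select_breakpoint(x, y, breakpoint_method)
        if min(np.sum(x < breakpoint), np.sum(x > breakpoint)) < min_side:
            # selected flat point too close to the data edge for stable
            # slopes on both sides; retreat to the median
            log.warning("selected breakpoint %g leaves too few points on one "
                        "side; falling back to median", breakpoint)
            breakpoint, method = float(np.median(x)), "median_fallback"
    n_low = int(np.sum(x < breakpoint))
    n_high = int(np.sum(x > breakpoint))
    if min(n_low, n_high) < min_side:
        raise ValueError(
            f"too few points on one side of breakpoint {breakpoint:g} "
            f"(low={n_low}, high={n_high}, need >= {min_side})"
        )
    X = pd.DataFrame({
        "const": np.ones_like(x),
        "xlow": np.minimum(x - breakpoint, 0.0),
        "xhigh": np.maximum(x - breakpoint, 0.0),
    })
    if covariates is not None:
        C = pd.DataFrame(covariates).reset_index(drop=True)
        X = pd.concat([X, C], axis=1)
    res = sm.OLS(y, X).fit()
    b_low, b_high = float(res.params["xlow"]), float(res.params["xhigh"])
    p_low, p_high = float(res.pvalues["xlow"]), float(res.pvalues["xhigh"])
    # slopes at machine-noise scale (e.g. an exactly constant outcome) are zero
    floor = 1e-10 * (np.mean(np.abs(y)) + np.std(y) + 1e-30) / max(np.std(x), 1e-30)
    if abs(b_low) < floor:
        b_low, p_low = 0.0, 1.0
    if abs(b_high) < floor:
        b_high, p_high = 0.0, 1.0
    u = (np.sign(b_low) != np.sign(b_high)) and (b_low != 0.0) and (b_high != 0.0) \
        and (p_low < SLOPE_ALPHA) and (p_high < SLOPE_ALPHA)
    return TwoLinesResult(
        breakpoint=float(breakpoint), b_low=b_low, p_low=p_low,
        b_high=b_high, p_high=p_high, u_shaped=bool(u),
        breakpoint_method=method,
    )
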