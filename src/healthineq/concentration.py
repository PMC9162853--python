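"""Concentration curves and concentration indices with respect to income rank.

The concentration index (CI) measures income-related inequality in a health
or healthcare variable ``y``: it is twice the covariance between ``y`` and the
individual's fractional income rank, divided by the mean of ``y``; equivalently
one minus twice the area under the concentration curve.  A positive CI means
the outcome is concentrated among richer individuals ("pro-rich" for desirable
outcomes, "pro-poor" when the outcome is a burden such as out-of-pocket
expense).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "CIResult",
    "ConcentrationCurve",
    "fractional_rank",
    "concentration_index",
    "concentration_curve",
]


@dataclass(frozen=True)
class CIResult:
    """A concentration index with its provenance.

    Attributes
    ----------
    value : float
        The index, in [-1, 1] for non-negative outcomes.
    outcome_name : str
        Label of the outcome variable.
    mean_outcome : float
        Sample mean of the outcome (the CI denominator).
    n : int
        Sample size.
    method : str
        ``"covariance"`` (the convenient covariance formula, canonical) or
        ``"curve_integral"`` (one minus twice the trapezoid area under the
        concentration curve, used as a cross-check).
    """

    value: float
    outcome_name: str
    mean_outcome: float
    n: int
    method: str = "covariance"


@dataclass(frozen=True)
class ConcentrationCurve:
    """Piecewise-linear concentration curve.

    ``points`` are ordered pairs (q, C(q)) where q is the cumulative
    population fraction ranked by income and C(q) the cumulative outcome
    share; the first point is (0, 0) and the last (1, 1).
    """

    points: np.ndarray  # shape (n + 1, 2)
    n: int
    outcome_name: str = field(default="y")

    def area(self) -> float:
        """Trapezoid area under the curve."""
        q, c = self.points[:, 0], self.points[:, 1]
        return float(np.trapezoid(c, q))

    def ci(self) -> float:
        """Concentration index as 1 - 2 * area under the curve."""
        return 1.0 - 2.0 * self.area()

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.points, columns=["q", "C(q)"])


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be a nonempty vector")
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains missing values")
    return arr


def fractional_rank(income, weights=None) -> np.ndarray:
    """Midpoint fractional income ranks in (0, 1).

    Each individual receives the midpoint of the cumulative population share
    it spans when the sample is sorted by income; tied incomes receive the
    average of their positional ranks, so the unweighted mean rank is exactly
    0.5.  With ``weights`` the rank is the cumulative weight before the
    individual plus half its own weight, divided by total weight (ties again
    averaged).
    """
    inc = _as_1d(income, "income")
    if weights is None:
        # average positional rank -> midpoint fraction (rank - 0.5) / n
        return (rankdata(inc, method="average") - 0.5) / inc.size
    w = _as_1d(weights, "weights")
    if w.size != inc.size:
        raise ValueError("weights and income must have the same length")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    order = np.argsort(inc, kind="stable")
    w_sorted = w[order]
    cum = np.cumsum(w_sorted)
    mid_sorted = (cum - 0.5 * w_sorted) / cum[-1]
    mid = np.empty_like(mid_sorted)
    mid[order] = mid_sorted
    # average midpoint ranks within tied income values
    uniq, inv = np.unique(inc, return_inverse=True)
    wsum = np.bincount(inv, weights=w)
    msum = np.bincount(inv, weights=mid * w)
    return msum[inv] / wsum[inv]


def concentration_index(
    y, income, weights=None, outcome_name: str = "y"
) -> CIResult:
    """Concentration index by the convenient covariance formula.

    CI = 2 * cov(y, r) / mean(y) with r the fractional income rank and the
    covariance taken with divisor n (population convention), which makes the
    covariance and curve-integral formulas agree exactly on untied incomes.
    """
    yv = _as_1d(y, "y")
    inc = _as_1d(income, "income")
    if yv.size != inc.size:
        raise ValueError(
            f"y (n={yv.size}) and income (n={inc.size}) must have the same length"
        )
    r = fractional_rank(inc, weights)
    if weights is None:
        mean_y = yv.mean()
        if mean_y == 0:
            raise ZeroDivisionError(
                "concentration index undefined: outcome mean is zero"
            )
        cov = float(np.mean(yv * r) - mean_y * r.mean())
    else:
        w = _as_1d(weights, "weights")
        mean_y = float(np.average(yv, weights=w))
        if mean_y == 0:
            raise ZeroDivisionError(
                "concentration index undefined: outcome mean is zero"
            )
        cov = float(
            np.average(yv * r, weights=w)
            - mean_y * np.average(r, weights=w)
        )
    if (yv < 0).any():
        warnings.warn(
            "outcome has negative values; |CI| <= 1 is not guaranteed",
            stacklevel=2,
        )
    return CIResult(
        value=2.0 * cov / mean_y,
        outcome_name=outcome_name,
        mean_outcome=float(mean_y),
        n=yv.size,
        method="covariance",
    )


def concentration_curve(y, income, outcome_name: str = "y") -> ConcentrationCurve:
    """Concentration curve: cumulative outcome share vs cumulative population
    share, the sample sorted by income (stable sort; ties keep input order)."""
    yv = _as_1d(y, "y")
    inc = _as_1d(income, "income")
    if yv.size != inc.size:
        raise ValueError("y and income must have the same length")
    total = yv.sum()
    if total < 0:
        raise ValueError("concentration curve requires a non-negative outcome total")
    if total == 0:
        raise ValueError("concentration curve undefined: outcome total is zero")
    order = np.argsort(inc, kind="stable")
    n = yv.size
    q = np.arange(n + 1) / n
    c = np.concatenate(([0.0], np.cumsum(yv[order]) / total))
    pts = np.column_stack([q, c])
    return ConcentrationCurve(points=pts, n=n, outcome_name=outcome_name)
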