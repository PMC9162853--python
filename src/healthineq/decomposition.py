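"""Regression-based (Wagstaff) decomposition of a concentration index.

With a linear model y = γ + Σ_k ρ_k x_k + ε, the outcome's concentration
index splits additively into per-factor contributions

    CI(y) = Σ_k η_k · CI(x_k) + residual,    η_k = ρ_k · x̄_k / ȳ,

where η_k is the elasticity of y to x_k at sample means, CI(x_k) the
factor's own concentration index, and the residual the generalized CI of the
unexplained part (2·cov(y − Σ ρ_k x_k, rank) / ȳ).  The residual is scaled
by the outcome mean, which makes the identity close exactly on the sample
the regression was fit on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .concentration import fractional_rank
from .panel import PanelDataset
from .regression import DIDFit

__all__ = ["DecompositionTable", "elasticity", "wagstaff_decompose"]


def elasticity(coefficient: float, factor_mean: float, outcome_mean: float) -> float:
    """Elasticity of the outcome to a factor at sample means: ρ·x̄/ȳ."""
    if outcome_mean == 0:
        raise ZeroDivisionError("elasticity undefined: outcome mean is zero")
    return coefficient * factor_mean / outcome_mean


@dataclass
class DecompositionTable:
    """Per-factor contributions to an outcome's concentration index.

    ``rows`` carries one record per factor: coefficient, mean, elasticity,
    the factor's own CI, the contribution (elasticity × factor CI) and the
    contribution rate (contribution / total CI, in percent).  Fixed-effect
    dummies are absorbed into ``residual_contribution`` unless the
    decomposition was asked to list them.
    """

    outcome_name: str
    total_ci: float
    outcome_mean: float
    n: int
    rows: pd.DataFrame
    residual_contribution: float
    year: int | None = None

    def row(self, factor: str) -> dict:
        match = self.rows[self.rows["factor"] == factor]
        if match.empty:
            raise KeyError(f"factor {factor!r} not in decomposition table")
        return match.iloc[0].to_dict()

    @property
    def residual_rate(self) -> float:
        return 100.0 * self.residual_contribution / self.total_ci

    def identity_gap(self) -> float:
        """Σ contributions + residual − total CI (0 up to rounding)."""
        return float(self.rows["contribution"].sum()
                     + self.residual_contribution - self.total_ci)

    def to_frame(self) -> pd.DataFrame:
        out = self.rows.copy()
        resid = pd.DataFrame([{
            "factor": "residual", "coefficient": np.nan, "mean": np.nan,
            "elasticity": np.nan, "factor_ci": np.nan,
            "contribution": self.residual_contribution,
            "contribution_rate": self.residual_rate,
        }])
        return pd.concat([out, resid], ignore_index=True)


def _pop_cov(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(a * b) - a.mean() * b.mean())


def wagstaff_decompose(
    fit: DIDFit,
    data: PanelDataset,
    income: str = "lnpcincome",
    include_fixed_effects: bool = False,
) -> DecompositionTable:
    """Decompose the outcome's CI using an already-fitted linear model.

    The decomposition runs on exactly the rows the regression used
    (``fit.row_index``); passing a panel that no longer contains those rows is
    an error.  Each factor's contribution is computed as
    2·ρ_k·cov(x_k, rank)/ȳ, which equals η_k·CI(x_k) whenever x̄_k ≠ 0 but
    stays well-defined for factors with mean zero.
    """
    if income not in data.df.columns:
        raise KeyError(f"income column {income!r} not in panel")
    try:
        df = data.df.loc[fit.row_index]
    except KeyError as exc:
        raise ValueError(
            "fit and panel samples do not match: the regression was fit on "
            "rows absent from this panel") from exc
    y = df[fit.outcome_name].to_numpy(dtype=float)
    if not np.isclose(y.mean(), fit.outcome_mean):
        raise ValueError("fit and panel samples do not match (outcome mean differs)")
    rank = fractional_rank(df[income].to_numpy())
    ybar = y.mean()
    total_ci = 2.0 * _pop_cov(y, rank) / ybar

    factor_items = [(f, fit.coefficients[f], df[f].to_numpy(dtype=float))
                    for f in fit.factors]
    if include_fixed_effects:
        for dim, col in (("city", "city_id"), ("year", "year")):
            levels = fit.fixed_effects.get(dim, [])
            for lev in levels[1:]:  # first level is the absorbed baseline
                name = f"fe_{dim}_{lev}"
                if name in fit.fe_coefficients:
                    factor_items.append(
                        (name, fit.fe_coefficients[name],
                         (df[col] == lev).to_numpy(dtype=float)))

    records = []
    explained = np.zeros_like(y)
    for name, rho, x in factor_items:
        explained += rho * x
        xbar = x.mean()
        contribution = 2.0 * rho * _pop_cov(x, rank) / ybar
        if xbar != 0:
            eta = elasticity(rho, xbar, ybar)
            factor_ci = 2.0 * _pop_cov(x, rank) / xbar
        else:
            eta, factor_ci = np.nan, np.nan
        records.append({
            "factor": name, "coefficient": rho, "mean": xbar,
            "elasticity": eta, "factor_ci": factor_ci,
            "contribution": contribution,
            "contribution_rate": 100.0 * contribution / total_ci,
        })

    residual = 2.0 * _pop_cov(y - explained, rank) / ybar
    return DecompositionTable(
        outcome_name=fit.outcome_name,
        total_ci=total_ci,
        outcome_mean=float(ybar),
        n=y.size,
        rows=pd.DataFrame.from_records(records),
        residual_contribution=float(residual),
    )
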