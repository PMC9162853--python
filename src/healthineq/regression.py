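"""Two-way fixed-effects regressions: the time-varying DID specification.

The treatment indicator switches on at city-specific adoption waves, so with
city and year fixed effects the OLS coefficient on the indicator is a
time-varying difference-in-differences estimate.  Binary outcomes are fit as
linear probability models: the downstream inequality decomposition needs
linear coefficients, and reporting a constant and a conventional R² keeps the
whole pipeline internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panel import PanelDataset, DEFAULT_FACTORS

__all__ = ["DIDFit", "InestimableError", "fit_did", "fit_by_income_quartile"]


class InestimableError(ValueError):
    """A requested coefficient cannot be estimated on this sample."""


@dataclass
class DIDFit:
    """An OLS fit of outcome ~ factors + city FE + year FE.

    ``coefficients`` / ``standard_errors`` are keyed by factor name plus
    ``"const"``; the absorbed fixed-effect levels are bookkept but their
    dummies are not reported.  ``row_index`` records the panel-row labels the
    fit used, so decompositions can be run on exactly the same sample.
    """

    coefficients: dict
    standard_errors: dict
    residuals: np.ndarray
    r_squared: float
    n_obs: int
    fixed_effects: dict
    outcome_name: str
    outcome_mean: float
    factors: list
    row_index: np.ndarray = field(repr=False, default=None)
    cov_type: str = "HC1"
    fe_coefficients: dict = field(repr=False, default_factory=dict)

    def conf_int(self, factor: str, level: float = 0.95):
        """Normal-approximation confidence interval for one coefficient."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        b, se = self.coefficients[factor], self.standard_errors[factor]
        return b - z * se, b + z * se

    def to_frame(self) -> pd.DataFrame:
        rows = [{"factor": k, "coefficient": self.coefficients[k],
                 "std_err": self.standard_errors[k]}
                for k in list(self.factors) + ["const"]]
        return pd.DataFrame(rows)


def _design(df: pd.DataFrame, factors, fe) -> tuple[np.ndarray, list]:
    """Design matrix [const | factors | FE dummies] and its column names."""
    blocks = [np.ones((len(df), 1))]
    names = ["const"]
    if factors:
        blocks.append(df[list(factors)].to_numpy(dtype=float))
        names += list(factors)
    for dim, col in (("city", "city_id"), ("year", "year")):
        if dim in fe:
            codes, levels = pd.factorize(df[col], sort=True)
            dummies = np.zeros((len(df), len(levels) - 1))
            mask = codes > 0
            dummies[np.flatnonzero(mask), codes[mask] - 1] = 1.0
            blocks.append(dummies)
            names += [f"fe_{dim}_{lev}" for lev in levels[1:]]
    return np.hstack(blocks), names


def _drop_collinear(
    X: np.ndarray, names: list, protected: set
) -> tuple[np.ndarray, list]:
    """Remove linearly dependent columns (pivoted QR).

    Redundant fixed-effect dummies are dropped with a warning; a *protected*
    column (a requested factor) that turns out dependent — e.g. a treatment
    indicator with no within-city switch, which city dummies absorb — is not
    silently droppable and raises :class:`InestimableError`.
    """
    from scipy.linalg import qr
    import warnings

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank == X.shape[1]:
        return X, names
    # a column with weight in the null space lies in the span of the others;
    # for a protected factor that means its coefficient is not identified
    _, sv, vt = np.linalg.svd(X, full_matrices=False)
    null_basis = vt[rank:]
    involved = np.abs(null_basis).max(axis=0) > 1e-8
    bad = sorted(n for j, n in enumerate(names) if involved[j] and n in protected)
    if bad:
        raise InestimableError(
            f"factor(s) {bad} are collinear with the remaining design "
            "(no independent variation on this sample)")
    dropped = [names[j] for j in piv[rank:]]
    warnings.warn(f"dropping collinear columns: {dropped}", stacklevel=3)
    keep = sorted(piv[:rank])
    return X[:, keep], [names[j] for j in keep]


def fit_did(
    data: PanelDataset,
    outcome: str,
    factors: list | None = None,
    fe: tuple = ("city", "year"),
    cluster: bool = False,
) -> DIDFit:
    """Fit the time-varying DID regression by OLS with FE dummies.

    Rows with a missing outcome are dropped (expense outcomes are defined
    only for healthcare users).  Standard errors are heteroskedasticity-
    robust (HC1) by default, or clustered on city with ``cluster=True``.
    """
    factors = list(DEFAULT_FACTORS if factors is None else factors)
    df = data.df
    missing = [c for c in [outcome] + factors if c not in df.columns]
    if missing:
        raise KeyError(f"columns not in panel: {missing}")
    df = df.dropna(subset=[outcome])
    y = df[outcome].astype(float)
    if y.nunique() <= 1:
        raise InestimableError(f"outcome {outcome!r} is constant on this sample")
    for f in factors:
        if df[f].nunique() <= 1:
            raise InestimableError(
                f"factor {f!r} is constant on this sample; its coefficient "
                "is not estimable")
    if "city" in fe and df["city_id"].nunique() < 2:
        raise InestimableError("city fixed effects need at least 2 cities")
    if "year" in fe and df["year"].nunique() < 2:
        raise InestimableError("year fixed effects need at least 2 years")

    X, names = _design(df, factors, fe)
    X, names = _drop_collinear(X, names, protected=set(factors))
    model = sm.OLS(y.to_numpy(), X)
    if cluster:
        res = model.fit(cov_type="cluster",
                        cov_kwds={"groups": df["city_id"].to_numpy()})
        cov_type = "cluster(city)"
    else:
        res = model.fit(cov_type="HC1")
        cov_type = "HC1"

    params = dict(zip(names, res.params))
    bses = dict(zip(names, res.bse))
    keep = ["const"] + factors
    return DIDFit(
        coefficients={k: float(params[k]) for k in keep},
        standard_errors={k: float(bses[k]) for k in keep},
        residuals=np.asarray(res.resid),
        r_squared=float(res.rsquared),
        n_obs=int(res.nobs),
        fixed_effects={
            "city": sorted(df["city_id"].unique().tolist()) if "city" in fe else [],
            "year": sorted(df["year"].unique().tolist()) if "year" in fe else [],
        },
        outcome_name=outcome,
        outcome_mean=float(y.mean()),
        factors=factors,
        row_index=df.index.to_numpy(),
        cov_type=cov_type,
        fe_coefficients={k: float(params[k]) for k in names
                         if k.startswith("fe_")},
    )


def fit_by_income_quartile(
    data: PanelDataset,
    outcome: str,
    factors: list | None = None,
    fe: tuple = ("city", "year"),
    income: str = "lnpcincome",
    cluster: bool = False,
) -> dict:
    """Refit the DID separately within income quartiles of the pooled sample.

    Quartiles are cut at the pooled sample quantiles of ``income``; a value
    exactly at a boundary falls in the lower quartile (right-closed bins).
    A quartile on which the treatment (or another factor) has a single level
    is flagged inestimable and mapped to ``None``.
    """
    df = data.df
    labels = [1, 2, 3, 4]
    quartile = pd.qcut(df[income], 4, labels=labels)
    out = {}
    for q in labels:
        sub = PanelDataset(df[quartile == q], metadata=data.metadata)
        try:
            out[q] = fit_did(sub, outcome, factors, fe, cluster=cluster)
        except InestimableError:
            out[q] = None
    return out
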