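import numpy as np
import pandas as pd
import pytest

from healthineq import (
    InestimableError,
    SyntheticConfig,
    fit_by_income_quartile,
    fit_did,
    generate_panel,
)
from conftest import make_panel


def _two_city_two_year_panel(effect=0.5):
    """8 rows, additive city/year/treatment structure, zero noise: the DID
    estimate must equal the constructed effect exactly."""
    city = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    year = np.array([2012, 2012, 2014, 2014] * 2)
    treated = ((city == 1) & (year == 2014)).astype(int)
    y = 0.3 * city + 0.1 * (year == 2014) + effect * treated + 0.2
    return make_panel(
        {"city_id": city, "year": year, "urrbmi": treated, "healthy": y}, n=8)


class TestFitDid:
    def test_exact_recovery_on_noiseless_two_by_two(self):
        fit = fit_did(_two_city_two_year_panel(0.5), "healthy",
                      factors=["urrbmi"])
        assert fit.coefficients["urrbmi"] == pytest.approx(0.5, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_residuals_sum_to_zero(self, small_panel):
        fit = fit_did(small_panel, "healthy")
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-6)
        assert 0.0 <= fit.r_squared <= 1.0

    def test_constant_treatment_rejected(self):
        panel = _two_city_two_year_panel()
        df = panel.df.copy()
        df["urrbmi"] = 0
        with pytest.raises(InestimableError, match="urrbmi"):
            fit_did(type(panel)(df), "healthy", factors=["urrbmi"])

    def test_treatment_absorbed_by_city_fe_rejected(self):
        # every adopting city adopted before the first wave: no within-city
        # switch, the city dummies span the treatment indicator
        panel = _two_city_two_year_panel()
        df = panel.df.copy()
        df["urrbmi"] = (df["city_id"] == 1).astype(int)
        with pytest.raises(InestimableError, match="collinear"):
            fit_did(type(panel)(df), "healthy", factors=["urrbmi"])

    def test_constant_outcome_rejected(self):
        panel = _two_city_two_year_panel()
        df = panel.df.copy()
        df["healthy"] = 1.0
        with pytest.raises(InestimableError, match="constant"):
            fit_did(type(panel)(df), "healthy", factors=["urrbmi"])

    def test_parameter_recovery_at_scale(self, big_panel):
        true = big_panel.metadata["true_coefficients"]["healthy"]["urrbmi"]
        fit = fit_did(big_panel, "healthy")
        lo, hi = fit.conf_int("urrbmi")
        assert lo <= true <= hi

    def test_expense_fit_conditions_on_users(self, big_panel):
        fit = fit_did(big_panel, "lnoutself")
        assert fit.n_obs == big_panel.df["lnoutself"].notna().sum()
        true = big_panel.metadata["true_coefficients"]["lnoutself"]["urrbmi"]
        lo, hi = fit.conf_int("urrbmi")
        assert lo <= true <= hi

    def test_clustered_standard_errors_differ(self, small_panel):
        robust = fit_did(small_panel, "healthy")
        clustered = fit_did(small_panel, "healthy", cluster=True)
        assert clustered.cov_type == "cluster(city)"
        assert (clustered.standard_errors["urrbmi"]
                != pytest.approx(robust.standard_errors["urrbmi"]))
        # point estimates are unaffected by the covariance estimator
        assert clustered.coefficients["urrbmi"] == pytest.approx(
            robust.coefficients["urrbmi"])

    def test_dummy_fe_matches_within_transformation(self, small_panel):
        """Independent oracle: iterated two-way demeaning reproduces the
        dummy-variable estimate of the treatment coefficient."""
        df = small_panel.df
        factors = ["urrbmi", "lnpcincome", "male", "age"]
        cols = df[factors + ["healthy"]].astype(float).copy()
        cols["_city"] = df["city_id"].to_numpy()
        cols["_year"] = df["year"].to_numpy()
        vals = [c for c in cols.columns if not c.startswith("_")]
        for _ in range(200):
            before = cols[vals].to_numpy().copy()
            cols[vals] -= cols.groupby("_city")[vals].transform("mean")
            cols[vals] -= cols.groupby("_year")[vals].transform("mean")
            if np.abs(cols[vals].to_numpy() - before).max() < 1e-13:
                break
        Xw = cols[factors].to_numpy()
        yw = cols["healthy"].to_numpy()
        beta_within = np.linalg.lstsq(Xw, yw, rcond=None)[0][0]
        fit = fit_did(small_panel, "healthy", factors=factors)
        assert fit.coefficients["urrbmi"] == pytest.approx(beta_within, abs=1e-8)


class TestIncomeQuartiles:
    def test_equal_quartile_sizes_with_unique_incomes(self):
        n = 400
        rng = np.random.default_rng(5)
        panel = make_panel({
            "lnpcincome": rng.permutation(n).astype(float),
            "city_id": rng.integers(0, 4, n),
            "year": np.where(np.arange(n) % 2 == 0, 2012, 2014),
            "healthy": rng.random(n),
        }, n=n)
        df = panel.df.copy()
        # treatment switches on in two cities in the later year
        df["urrbmi"] = ((df.city_id >= 2) & (df.year == 2014)).astype(int)
        fits = fit_by_income_quartile(type(panel)(df), "healthy",
                                      factors=["urrbmi"])
        sizes = [f.n_obs for f in fits.values() if f is not None]
        assert sizes == [100, 100, 100, 100]

    def test_gradient_in_expense_effect_recovered(self):
        """When the treatment's expense effect is more negative for poorer
        individuals, the quartile estimates are ordered accordingly in
        expectation (averaged over seeds)."""
        lows, highs = [], []
        for seed in range(50):
            panel = generate_panel(SyntheticConfig(
                n_individuals=4000, n_cities=30, seed=seed,
                treatment_income_interaction={"lnoutself": 1.5}))
            fits = fit_by_income_quartile(panel, "lnoutself")
            if fits[1] is None or fits[4] is None:
                continue
            lows.append(fits[1].coefficients["urrbmi"])
            highs.append(fits[4].coefficients["urrbmi"])
        assert np.mean(lows) < np.mean(highs)
        # the configured gradient spans ~1.1 between the outer quartiles
        assert np.mean(highs) - np.mean(lows) > 0.3

    def test_uniform_effect_shows_no_systematic_ordering(self):
        signs = 0
        total = 0
        for seed in range(20):
            panel = generate_panel(SyntheticConfig(
                n_individuals=4000, n_cities=30, seed=100 + seed))
            fits = fit_by_income_quartile(panel, "lnoutself")
            if fits[1] is None or fits[4] is None:
                continue
            signs += fits[1].coefficients["urrbmi"] < fits[4].coefficients["urrbmi"]
            total += 1
        # sign test: under exchangeability the ordering is a fair coin
        assert 0.1 <= signs / total <= 0.9
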