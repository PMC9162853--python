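import numpy as np
import pytest

from healthineq import (
    SyntheticConfig,
    generate_panel,
    placebo_test,
    psm_did,
)
from healthineq.synthetic import DEFAULT_COEFFICIENTS
from conftest import make_panel


class TestPsmDid:
    def test_matched_estimate_recovers_true_effect(self, big_panel):
        # adoption selects on city wealth, so matching must not break recovery
        true = big_panel.metadata["true_coefficients"]["healthy"]["urrbmi"]
        fit, match = psm_did(big_panel, "healthy")
        lo, hi = fit.conf_int("urrbmi")
        assert lo <= true <= hi
        assert fit.n_obs == len(big_panel) - match.n_dropped

    def test_random_treatment_trims_almost_nothing(self):
        rng = np.random.default_rng(3)
        n = 2000
        panel = make_panel({
            "lnpcincome": rng.normal(8.6, 1.5, n),
            "age": rng.integers(15, 65, n),
            "male": rng.integers(0, 2, n),
            "healthy": rng.integers(0, 2, n),
            "urrbmi": rng.integers(0, 2, n),
            "city_id": rng.integers(0, 10, n),
            "year": rng.choice([2012, 2014], n),
        }, n=n)
        _, match = psm_did(panel, "healthy",
                           factors=["urrbmi", "lnpcincome", "age", "male"])
        assert match.n_dropped < 0.01 * n

    def test_duplicate_covariates_match_at_zero_distance(self):
        # each treated row has an exact control twin: matches must be exact
        # and the matched sample perfectly balanced
        m = 40
        rng = np.random.default_rng(8)
        # twin pairs plus a block of pure controls at lower income, so the
        # propensity model is informative while every treated row keeps an
        # exact control twin
        income = np.concatenate([np.repeat(rng.normal(9.0, 0.5, m), 2),
                                 rng.normal(7.0, 0.5, m)])
        age = np.concatenate([np.repeat(rng.integers(20, 60, m), 2),
                              rng.integers(20, 60, m)])
        treated = np.concatenate([np.tile([1, 0], m), np.zeros(m, dtype=int)])
        n_rows = 3 * m
        panel = make_panel({
            "lnpcincome": income, "age": age, "urrbmi": treated,
            "healthy": rng.integers(0, 2, n_rows),
            "city_id": np.arange(n_rows) % 4,
            "year": np.where(np.arange(n_rows) % 2 == 0, 2012, 2014),
        }, n=n_rows)
        _, match = psm_did(panel, "healthy",
                           factors=["urrbmi", "lnpcincome", "age"])
        scores = match.propensity_scores
        for t_lbl, c_lbl in match.pairs.items():
            assert scores[t_lbl] == pytest.approx(scores[c_lbl], abs=1e-12)
        matched = panel.df.loc[list(match.pairs.values())]
        treated_rows = panel.df.loc[list(match.pairs.keys())]
        for col in ("lnpcincome", "age"):
            pooled_sd = panel.df[col].std()
            smd = (treated_rows[col].mean() - matched[col].mean()) / pooled_sd
            assert smd == pytest.approx(0.0, abs=1e-10)

    def test_nearest_neighbor_matches_exhaustive_search(self, small_panel):
        sub = type(small_panel)(small_panel.df.iloc[::12].copy(),
                                metadata=small_panel.metadata)
        _, match = psm_did(sub, "healthy")
        scores = match.propensity_scores
        lo, hi = match.support_bounds
        control = scores[(sub.df["urrbmi"] == 0) & (scores >= lo) & (scores <= hi)]
        for t_lbl, c_lbl in match.pairs.items():
            best = np.min(np.abs(control.to_numpy() - scores[t_lbl]))
            assert abs(scores[c_lbl] - scores[t_lbl]) == pytest.approx(
                best, abs=1e-12)

    def test_all_matches_inside_common_support(self, small_panel):
        _, match = psm_did(small_panel, "healthy")
        scores = match.propensity_scores
        lo, hi = match.support_bounds
        used = list(match.pairs.keys()) + list(match.pairs.values())
        assert ((scores[used] >= lo) & (scores[used] <= hi)).all()

    def test_caliper_drops_distant_treated(self, small_panel):
        _, loose = psm_did(small_panel, "healthy")
        _, tight = psm_did(small_panel, "healthy", caliper=1e-7)
        assert tight.n_dropped >= loose.n_dropped

    def test_one_armed_sample_rejected(self, small_panel):
        df = small_panel.df.copy()
        df["urrbmi"] = 1
        with pytest.raises(ValueError):
            psm_did(type(small_panel)(df), "healthy")


@pytest.fixture(scope="module")
def null_panel():
    coefs = {k: dict(v) for k, v in DEFAULT_COEFFICIENTS.items()}
    coefs["healthy"]["urrbmi"] = 0.0
    return generate_panel(SyntheticConfig(
        n_individuals=4000, n_cities=30, seed=42,
        outcome_coefficients=coefs))


class TestPlaceboTest:
    def test_same_seed_reproduces_estimates(self, small_panel):
        a = placebo_test(small_panel, "healthy", R=20, seed=5)
        b = placebo_test(small_panel, "healthy", R=20, seed=5)
        np.testing.assert_array_equal(a.estimates, b.estimates)

    def test_null_distribution_centered_at_zero(self, null_panel):
        dist = placebo_test(null_panel, "healthy", R=200, seed=9)
        se = dist.estimates.std(ddof=1) / np.sqrt(dist.R)
        assert abs(dist.estimates.mean()) < 4 * se

    def test_large_true_effect_lands_in_the_tail(self):
        coefs = {k: dict(v) for k, v in DEFAULT_COEFFICIENTS.items()}
        coefs["healthy"]["urrbmi"] = 0.15
        panel = generate_panel(SyntheticConfig(
            n_individuals=4000, n_cities=30, seed=17,
            outcome_coefficients=coefs))
        dist = placebo_test(panel, "healthy", R=200, seed=17)
        assert dist.tail_proportion() < 0.05

    def test_city_level_variant_preserves_staggering(self, small_panel):
        dist = placebo_test(small_panel, "healthy", R=20, seed=5, level="city")
        assert dist.R == 20
        assert np.isfinite(dist.estimates).all()

    def test_matches_full_refit(self, small_panel):
        """The partialled-out shortcut must agree with an explicit OLS refit
        on a reassigned treatment."""
        import healthineq as hi

        dist = placebo_test(small_panel, "healthy", R=1, seed=31)
        # rebuild the same reassignment the test run used
        rng = np.random.default_rng(31)
        df = small_panel.df.copy()
        years = df["year"].to_numpy()
        d = np.zeros(len(df))
        for w in np.unique(years):
            rows = np.flatnonzero(years == w)
            m = int(df["urrbmi"].to_numpy()[rows].sum())
            d[rng.choice(rows, size=m, replace=False)] = 1.0
        df["urrbmi"] = d
        refit = hi.fit_did(type(small_panel)(df), "healthy")
        assert dist.estimates[0] == pytest.approx(
            refit.coefficients["urrbmi"], abs=1e-8)

    def test_zero_replicates_rejected(self, small_panel):
        with pytest.raises(ValueError):
            placebo_test(small_panel, "healthy", R=0)

    def test_density_export_shape(self, small_panel):
        dist = placebo_test(small_panel, "healthy", R=30, seed=2)
        dens = dist.density(gridsize=64)
        assert list(dens.columns) == ["estimate", "density"]
        assert len(dens) == 64
        assert (dens["density"] >= 0).all()
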