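"""Synthetic survey panels emulating a staggered city-level insurance rollout.

The real microdata behind this kind of analysis (a national labour-force
panel with three biennial waves) are access-restricted, so every downstream
stage is exercised on panels generated here with *known* ground truth:

* individuals nested in cities; log income has a city random effect, a
  persistent individual effect and a wave-level shock;
* insurance adoption happens at the city level, is absorbing, and its
  probability rises with the city's wealth percentile — which is what makes
  coverage "pro-rich" (a positive concentration index of the treatment
  indicator) and the rollout staggered;
* binary outcomes (self-rated health, outpatient visit, hospitalization) are
  Bernoulli draws from a clipped *linear* probability index, so a linear
  probability model with two-way fixed effects is correctly specified and
  coefficient-recovery tests are meaningful;
* out-of-pocket expense outcomes are generated conditional on utilization,
  with the treatment shifting the log-expense mean by a configurable
  (negative) amount.

All randomness flows from a single seeded :func:`numpy.random.default_rng`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel import PanelDataset, REQUIRED_COLUMNS, DEFAULT_FACTORS

__all__ = ["SyntheticConfig", "generate_panel", "filter_panel", "ConfigError"]


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


# Default true coefficients for the outcome-generating equations.  These are
# deliberately in the neighbourhood of estimates from published work on the
# urban-rural insurance integration so that generated panels look like the
# real study population.
_HEALTHY_COEFS = {
    "urrbmi": 0.0243, "age": -0.0210, "age2": 0.0001, "male": 0.0606,
    "married": 0.0685, "hhnum": 0.0012, "lnpcincome": 0.0367, "rural": 0.0135,
    "priedu": 0.0672, "secedu": 0.1224, "highedu": 0.1684, "superhigh": 0.3003,
    "pension": 0.0229, "sanitary": 0.0205,
}
_OUTPATIENT_COEFS = {
    "urrbmi": 0.0246, "age": 0.0039, "age2": -0.00004, "male": -0.0268,
    "married": -0.0212, "hhnum": 0.0007, "lnpcincome": -0.0058, "rural": 0.0051,
    "priedu": -0.0174, "secedu": -0.0293, "highedu": -0.0276, "superhigh": 0.0194,
    "pension": 0.0038, "sanitary": -0.0106,
}
_HOSPITAL_COEFS = {
    "urrbmi": 0.0278, "age": -0.0013, "age2": 0.00003, "male": -0.0214,
    "married": 0.0126, "hhnum": 0.0000, "lnpcincome": -0.0072, "rural": -0.0024,
    "priedu": -0.0095, "secedu": -0.0126, "highedu": -0.0147, "superhigh": -0.0122,
    "pension": 0.0034, "sanitary": -0.0027,
}
_LNOUTSELF_COEFS = {
    "urrbmi": -1.0740, "age": 0.0266, "age2": -0.0005, "male": 0.3602,
    "married": 0.3321, "hhnum": -0.2950, "lnpcincome": 0.0433, "rural": 0.0128,
    "priedu": -0.6758, "secedu": -0.6956, "highedu": -0.8669, "superhigh": 1.8758,
    "pension": -0.1324, "sanitary": -0.3828,
}
_LNHOSSELF_COEFS = {
    "urrbmi": -0.4289, "age": 0.0502, "age2": -0.0007, "male": 0.2829,
    "married": 0.1025, "hhnum": -0.1597, "lnpcincome": 0.0752, "rural": -0.5041,
    "priedu": -0.1403, "secedu": -0.6857, "highedu": -0.3383, "superhigh": -0.2324,
    "pension": -0.0194, "sanitary": -0.3301,
}

DEFAULT_COEFFICIENTS = {
    "healthy": _HEALTHY_COEFS,
    "outpatient": _OUTPATIENT_COEFS,
    "hospital": _HOSPITAL_COEFS,
    "lnoutself": _LNOUTSELF_COEFS,
    "lnhosself": _LNHOSSELF_COEFS,
}

DEFAULT_TARGET_MEANS = {
    "healthy": 0.557,
    "outpatient": 0.087,
    "hospital": 0.081,
    "lnoutself": 4.246,
    "lnhosself": 6.836,
}

#: population coverage share targeted at each wave (staggered rollout)
DEFAULT_COVERAGE_TARGETS = {2012: 0.0985, 2014: 0.1479, 2016: 0.2717}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic panel generator.

    ``adoption_wealth_exponent`` k shapes how the probability that a city has
    adopted the insurance by wave w depends on the city's wealth percentile p:
    P_w(p) = target_w * (k + 1) * p**k, so the population-level coverage at
    wave w averages to ``coverage_targets[w]`` while richer cities adopt
    earlier (k = 0 removes the wealth gradient entirely).

    ``treatment_income_interaction`` optionally makes the treatment effect on
    an outcome vary linearly with the individual's income percentile
    (effect = base + slope * (percentile - 0.5)); used to build heterogeneous-
    effect scenarios.
    """

    n_individuals: int = 20_000
    n_cities: int = 60
    waves: tuple[int, ...] = (2012, 2014, 2016)
    coverage_targets: dict = field(
        default_factory=lambda: dict(DEFAULT_COVERAGE_TARGETS))
    adoption_wealth_exponent: float = 1.0
    income_mean: float = 8.642
    income_sd_city: float = 0.45
    income_sd_individual: float = 1.20
    income_sd_wave: float = 0.80
    outcome_coefficients: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COEFFICIENTS.items()})
    target_means: dict = field(default_factory=lambda: dict(DEFAULT_TARGET_MEANS))
    expense_noise_sd: dict = field(
        default_factory=lambda: {"lnoutself": 2.5, "lnhosself": 2.6})
    city_effect_sd: float = 0.02
    year_effect_sd: float = 0.01
    treatment_income_interaction: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_cities < 2:
            raise ConfigError("n_cities must be at least 2")
        if self.n_individuals < self.n_cities:
            raise ConfigError("n_individuals must be at least n_cities")
        waves = tuple(self.waves)
        if len(waves) < 1 or any(b <= a for a, b in zip(waves, waves[1:])):
            raise ConfigError("waves must be strictly increasing")
        targets = [self.coverage_targets.get(w, 0.0) for w in waves]
        if any(not (0.0 <= t <= 1.0) for t in targets):
            raise ConfigError("coverage targets must be probabilities in [0, 1]")
        if any(b < a for a, b in zip(targets, targets[1:])):
            raise ConfigError(
                "coverage targets must be non-decreasing across waves "
                "(adoption is absorbing)")
        if self.adoption_wealth_exponent < 0:
            raise ConfigError("adoption_wealth_exponent must be non-negative")
        for out, m in self.target_means.items():
            if out in ("healthy", "outpatient", "hospital") and not 0 < m < 1:
                raise ConfigError(f"target mean for {out} must lie in (0, 1)")
        return self


def _adoption_prob(target: float, pct: np.ndarray, k: float) -> np.ndarray:
    return np.clip(target * (k + 1.0) * pct ** k, 0.0, 1.0)


def generate_panel(config: SyntheticConfig) -> PanelDataset:
    """Draw a panel from the configured data-generating process.

    Returns a validated :class:`PanelDataset`; the true coefficients, the
    calibrated intercepts and each city's adoption wave are recorded in
    ``metadata`` for parameter-recovery tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, n_city = config.n_individuals, config.n_cities
    waves = tuple(config.waves)
    n_waves = len(waves)
    k = config.adoption_wealth_exponent

    # ---- cities: wealth, region, adoption wave -----------------------------
    east_city = (rng.random(n_city) < 0.353).astype(int)
    city_wealth = rng.normal(0.0, config.income_sd_city, n_city) + 0.20 * east_city
    wealth_pct = (np.argsort(np.argsort(city_wealth)) + 0.5) / n_city
    # stratified uniforms: marginally U(0,1) but negatively dependent across
    # cities, so realized coverage tracks the per-wave targets tightly
    adopt_u = (rng.permutation(n_city) + rng.random(n_city)) / n_city
    adopted_by = {
        w: adopt_u < _adoption_prob(config.coverage_targets.get(w, 0.0), wealth_pct, k)
        for w in waves
    }
    adoption_wave = np.full(n_city, -1)
    for w in reversed(waves):
        adoption_wave[adopted_by[w]] = w

    # ---- individuals: fixed attributes -------------------------------------
    city = rng.integers(0, n_city, n)
    perm_inc = rng.normal(0.0, config.income_sd_individual, n)
    latent_inc = city_wealth[city] + perm_inc          # persistent income part
    inc_pct = (np.argsort(np.argsort(latent_inc)) + 0.5) / n
    base_age = np.clip(np.round(rng.normal(44.6, 14.6, n)), 15, 62)
    male = (rng.random(n) < 0.473).astype(int)
    married = (rng.random(n) < 0.831).astype(int)
    hhnum = np.clip(np.round(rng.normal(3.96, 1.82, n)), 1, 12)
    # education: ordered categories, correlated with permanent income
    edu_z = 0.5 * (inc_pct - 0.5) * np.sqrt(12) + np.sqrt(0.75) * rng.normal(size=n)
    edu_cut = np.quantile(edu_z, np.cumsum([0.171, 0.628, 0.124, 0.037]))
    edu = np.searchsorted(edu_cut, edu_z, side="right")  # 0=none .. 4=postgrad
    priedu = (edu == 1).astype(int)
    secedu = (edu == 2).astype(int)
    highedu = (edu == 3).astype(int)
    superhigh = (edu == 4).astype(int)
    rural = (rng.random(n) < np.clip(0.890 - 0.15 * (inc_pct - 0.5), 0, 1)).astype(int)
    pension = (rng.random(n) < np.clip(0.521 + 0.10 * (inc_pct - 0.5), 0, 1)).astype(int)
    sanitary = (rng.random(n) < np.clip(0.849 + 0.15 * (inc_pct - 0.5), 0, 1)).astype(int)

    # ---- stack waves --------------------------------------------------------
    rows = {c: [] for c in REQUIRED_COLUMNS}
    city_fx = {o: rng.normal(0.0, config.city_effect_sd, n_city)
               for o in ("healthy", "outpatient", "hospital")}
    city_fx_exp = {o: rng.normal(0.0, 0.30, n_city)
                   for o in ("lnoutself", "lnhosself")}
    year_fx = {o: rng.normal(0.0, config.year_effect_sd, n_waves)
               for o in ("healthy", "outpatient", "hospital")}
    year_fx_exp = {o: rng.normal(0.0, 0.15, n_waves)
                   for o in ("lnoutself", "lnhosself")}

    frames = []
    for j, w in enumerate(waves):
        age = np.clip(base_age + 2 * j, 15, 64)
        lninc = (config.income_mean + latent_inc
                 + rng.normal(0.0, config.income_sd_wave, n))
        urrbmi = adopted_by[w][city].astype(int)
        frames.append(pd.DataFrame({
            "person_id": np.arange(n),
            "city_id": city,
            "year": w,
            "wave_index": j,
            "urrbmi": urrbmi,
            "lnpcincome": lninc,
            "age": age,
            "age2": age ** 2,
            "male": male,
            "married": married,
            "hhnum": hhnum,
            "rural": rural,
            "priedu": priedu,
            "secedu": secedu,
            "highedu": highedu,
            "superhigh": superhigh,
            "pension": pension,
            "sanitary": sanitary,
            "east": east_city[city],
            "inc_pct": inc_pct,
        }))
    df = pd.concat(frames, ignore_index=True)

    coefs = config.outcome_coefficients
    intercepts: dict[str, float] = {}

    def linear_index(outcome: str) -> np.ndarray:
        c = coefs[outcome]
        idx = np.zeros(len(df))
        for factor, rho in c.items():
            if factor == "urrbmi":
                slope = config.treatment_income_interaction.get(outcome, 0.0)
                eff = rho + slope * (df["inc_pct"].to_numpy() - 0.5)
                idx += eff * df["urrbmi"].to_numpy()
            else:
                idx += rho * df[factor].to_numpy()
        return idx

    for outcome in ("healthy", "outpatient", "hospital"):
        idx = linear_index(outcome)
        idx += city_fx[outcome][df["city_id"]] + year_fx[outcome][df["wave_index"]]
        intercept = config.target_means[outcome] - idx.mean()
        p = np.clip(intercept + idx, 0.001, 0.999)
        df[outcome] = (rng.random(len(df)) < p).astype(int)
        intercepts[outcome] = float(intercept)

    for outcome, flag in (("lnoutself", "outpatient"), ("lnhosself", "hospital")):
        idx = linear_index(outcome)
        idx += city_fx_exp[outcome][df["city_id"]] + year_fx_exp[outcome][df["wave_index"]]
        use = df[flag].to_numpy() == 1
        intercept = config.target_means[outcome] - idx[use].mean() if use.any() else 0.0
        vals = np.full(len(df), np.nan)
        vals[use] = (intercept + idx[use]
                     + rng.normal(0.0, config.expense_noise_sd[outcome], use.sum()))
        df[outcome] = vals
        intercepts[outcome] = float(intercept)

    df = df.drop(columns=["wave_index", "inc_pct"])
    df = df[REQUIRED_COLUMNS]
    meta = {
        "true_coefficients": {o: dict(c) for o, c in coefs.items()},
        "treatment_income_interaction": dict(config.treatment_income_interaction),
        "intercepts": intercepts,
        "city_adoption_wave": adoption_wave.tolist(),
        "config": asdict(config),
    }
    return PanelDataset(df, metadata=meta).validate()


# ---------------------------------------------------------------------------
# row filtering

def filter_panel(data: PanelDataset, rules: list[dict]) -> PanelDataset:
    """Apply generic row filters, mirroring a study's sample-construction steps.

    Each rule is a mapping with a ``kind``:

    * ``{"kind": "drop_missing", "columns": [...]}`` — drop rows with a
      missing value in any listed column (all required columns if omitted,
      except the expense outcomes which are legitimately missing for
      non-users);
    * ``{"kind": "exclude", "column": c, "values": [...]}`` — drop rows whose
      ``c`` is in the value set (e.g. removing cities that never experienced
      the integration process);
    * ``{"kind": "keep", "column": c, "values": [...]}`` — keep only rows
      whose ``c`` is in the value set.

    The number of rows dropped by each rule, applied in order, is recorded in
    the returned panel's ``metadata["filter_report"]``.
    """
    df = data.df
    report = []
    for rule in rules:
        kind = rule.get("kind")
        before = len(df)
        if kind == "drop_missing":
            cols = rule.get("columns")
            if cols is None:
                cols = [c for c in REQUIRED_COLUMNS
                        if c not in ("lnoutself", "lnhosself")]
            _check_columns(df, cols)
            df = df.dropna(subset=cols)
        elif kind in ("exclude", "keep"):
            col = rule["column"]
            _check_columns(df, [col])
            mask = df[col].isin(rule["values"])
            df = df[~mask] if kind == "exclude" else df[mask]
        else:
            raise ValueError(f"unknown filter rule kind: {kind!r}")
        report.append({"rule": dict(rule), "dropped": before - len(df)})
    meta = dict(data.metadata)
    meta["filter_report"] = report
    return PanelDataset(df.reset_index(drop=True), metadata=meta)


def _check_columns(df: pd.DataFrame, cols) -> None:
    unknown = [c for c in cols if c not in df.columns]
    if unknown:
        raise KeyError(f"filter rule references unknown columns: {unknown}")
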