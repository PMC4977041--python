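"""Synthetic tract x year mortality panels with known ground truth.

The generator emulates a state-wide census-tract panel of annual natural-cause
death counts over a short span of years, with the confounding structure a
difference-in-differences design is meant to defeat:

* a spatial confounder ``Z_c`` per tract, constant over time, optionally
  correlated with the tract's long-term mean PM2.5;
* a common, non-monotone state-wide time trend ``U_t``;
* seasonal (summer / winter) temperatures whose tract-year deviations are
  partially coupled to the tract-year PM2.5 deviations — the one confounder
  that survives tract and year fixed effects;
* overdispersed counts with a recoverable quasi-Poisson dispersion;
* a planted log-linear exposure effect, optionally modified by tract- or
  county-level covariates.

Everything is deterministic given the scenario seed, and the generating
linear predictors are returned so downstream estimators can be validated
against the exact truth.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

AGE_GROUPS = ("all", "le65", "gt65")

PANEL_COLUMNS = [
    "tract_id", "county_id", "year", "age_group", "deaths", "population",
    "pm25", "temp_summer", "temp_winter",
    "pct_black", "med_income", "med_home_value", "smoking_rate", "diabetes_rate",
]

MODIFIER_COLUMNS = (
    "pct_black", "med_income", "med_home_value", "smoking_rate", "diabetes_rate",
)

# Scale anchors for a realistic state-wide tract panel: non-monotone yearly
# log-rate shifts, state-wide yearly exposure and temperature shifts, and
# cross-tract spreads.  Patterns are stretched by interpolation when the
# scenario uses a different number of years.
_YEAR_LOG_RATE = np.array([0.087, 0.084, -0.074, -0.091, -0.040, 0.018])
_PM_YEAR_SHIFT = np.array([0.95, 1.45, 0.35, 0.25, -0.75, -2.25])
_TSUMMER_YEAR_SHIFT = np.array([-0.53, 1.67, 0.47, -0.23, -0.03, -1.33])
_TWINTER_YEAR_SHIFT = np.array([-1.6, -0.9, 1.9, 0.0, 0.8, -0.2])

_ELDERLY_POP_FRACTION = 0.1355   # share of tract population aged > 65
_GT65_RATE_RATIO = 40.1 / 7.3    # age-stratum death rate relative to all ages
_LE65_RATE_RATIO = 2.1 / 7.3
_SUMMER_TRACT_SD = 0.73          # cross-tract SD of long-term seasonal means
_WINTER_TRACT_SD = 0.73
_SUMMER_DEV_SD = 0.25            # idiosyncratic tract-year deviations
_WINTER_DEV_SD = 0.25
_FIRST_YEAR = 2004
_NORMAL_IQR = 1.349              # IQR of a standard normal


def _stretch(pattern: np.ndarray, n: int) -> np.ndarray:
    """Resample a fixed yearly pattern to ``n`` years by linear interpolation."""
    pattern = np.asarray(pattern, dtype=float)
    if n == len(pattern):
        return pattern.copy()
    xp = np.linspace(0.0, 1.0, len(pattern))
    return np.interp(np.linspace(0.0, 1.0, n), xp, pattern)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic study scenario.

    Rates are log deaths per person-year; ``beta1`` is the log rate ratio per
    ug/m3 of annual PM2.5.  ``temp_effect_summer`` / ``temp_effect_winter``
    are (base slope, hinge slope) pairs of a single-knot linear spline on the
    log-rate scale, with knots at ``summer_mean`` / ``winter_mean``.
    ``interaction_coeffs`` maps a modifier or temperature column name to a
    planted effect-modification slope: the exposure slope becomes
    ``beta1 + coeff * (x - mean(x))``.  ``pm_dev_sd`` scales the idiosyncratic
    tract-year exposure deviation, the only exposure variation that survives
    both fixed effects.
    """

    n_tracts: int = 200
    n_years: int = 6
    baseline_log_rate: float = float(np.log(31.4 / 4412.0))
    beta1: float = float(np.log(1.03) / 2.0)
    tract_effect_sd: float = 0.25
    tract_exposure_confounding: float = 0.0
    year_effects: tuple | None = None
    temp_effect_summer: tuple = (-0.01, 0.04)
    temp_effect_winter: tuple = (-0.02, 0.01)
    temp_exposure_coupling: float = 0.3
    dispersion: float = 2.0
    population_range: tuple = (1800, 7500)
    pm_mean: float = 11.3
    pm_iqr: float = 2.0
    summer_mean: float = 18.6
    winter_mean: float = 5.9
    pm_dev_sd: float = 0.4
    interaction_coeffs: dict = field(default_factory=dict)
    beta1_by_age: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_tracts < 2:
            raise ValueError("n_tracts must be >= 2")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if self.dispersion < 1.0:
            raise ValueError("dispersion must be >= 1 (quasi-Poisson phi)")
        if self.population_range[0] <= 0 or self.population_range[1] < self.population_range[0]:
            raise ValueError("population_range must be positive and ordered")
        if self.year_effects is not None and len(self.year_effects) != self.n_years:
            raise ValueError(
                f"year_effects has length {len(self.year_effects)}, expected n_years={self.n_years}"
            )
        if not -1.0 <= self.tract_exposure_confounding <= 1.0:
            raise ValueError("tract_exposure_confounding must be a correlation in [-1, 1]")
        if not -1.0 <= self.temp_exposure_coupling <= 1.0:
            raise ValueError("temp_exposure_coupling must be a correlation in [-1, 1]")

    def resolved_year_effects(self) -> np.ndarray:
        if self.year_effects is not None:
            return np.asarray(self.year_effects, dtype=float)
        return _stretch(_YEAR_LOG_RATE, self.n_years)

    def stratum_beta1(self, age_group: str) -> float:
        if self.beta1_by_age and age_group in self.beta1_by_age:
            return float(self.beta1_by_age[age_group])
        return float(self.beta1)


@dataclass(frozen=True)
class PanelRecord:
    """One tract-year-stratum observation of the mortality panel."""

    tract_id: str
    county_id: str
    year: int
    age_group: str
    deaths: int
    population: int
    pm25: float
    temp_summer: float
    temp_winter: float
    pct_black: float | None = None
    med_income: float | None = None
    med_home_value: float | None = None
    smoking_rate: float | None = None
    diabetes_rate: float | None = None


def as_records(panel: pd.DataFrame) -> list[PanelRecord]:
    """View a panel DataFrame as a list of typed records."""
    cols = [c for c in PANEL_COLUMNS if c in panel.columns]
    return [PanelRecord(**row) for row in panel[cols].to_dict("records")]


@dataclass
class SimulationTruth:
    """The generator's ground truth, for recovery tests.

    ``linear_predictors`` maps ``(tract_id, year, age_group)`` to the log of
    the generating mean count (offset included), so ``exp(lp)`` is the exact
    expectation of the drawn deaths.
    """

    beta1: float
    beta1_by_age: dict
    tract_effects: dict
    year_effects: dict
    temp_coefficients: dict
    knots: dict
    dispersion: float
    interaction_coeffs: dict
    modifier_means: dict
    seed: int
    linear_predictors: dict


# ---------------------------------------------------------------------------
# structure (covariates and linear predictors) shared by panel and cohort
# ---------------------------------------------------------------------------

def _modifier_fields(cfg: ScenarioConfig, rng: np.random.Generator, n_counties: int,
                     county_of_tract: np.ndarray):
    """Tract-level SES and county-year health-behaviour modifiers.

    Income and home value are correlated lognormals; percent black is a
    skewed logistic-normal negatively correlated with income; smoking and
    diabetes prevalences are county-level with a small yearly random walk.
    """
    n, T = cfg.n_tracts, cfg.n_years
    # Gaussian copula for (black, income, home value)
    corr = np.array([[1.0, -0.4, -0.3],
                     [-0.4, 1.0, 0.6],
                     [-0.3, 0.6, 1.0]])
    L = np.linalg.cholesky(corr)
    g = rng.standard_normal((n, 3)) @ L.T
    pct_black = 100.0 / (1.0 + np.exp(-(-2.2 + 1.9 * g[:, 0])))
    med_income = np.exp(11.067 + 0.457 * g[:, 1])
    med_home_value = np.exp(12.710 + 0.436 * g[:, 2])

    smoking_base = np.clip(rng.normal(11.8, 2.9, size=n_counties), 2.0, None)
    diabetes_base = np.clip(rng.normal(7.6, 1.1, size=n_counties), 2.0, None)
    smoking_cy = np.clip(
        smoking_base[:, None] + np.cumsum(rng.normal(0.0, 0.4, size=(n_counties, T)), axis=1),
        1.0, None)
    diabetes_cy = np.clip(
        diabetes_base[:, None] + np.cumsum(rng.normal(0.0, 0.25, size=(n_counties, T)), axis=1),
        1.0, None)
    return {
        "pct_black": np.repeat(pct_black[:, None], T, axis=1),
        "med_income": np.repeat(med_income[:, None], T, axis=1),
        "med_home_value": np.repeat(med_home_value[:, None], T, axis=1),
        "smoking_rate": smoking_cy[county_of_tract, :],
        "diabetes_rate": diabetes_cy[county_of_tract, :],
    }


def _structure(cfg: ScenarioConfig, rng: np.random.Generator) -> dict:
    """Draw every covariate field and the per-stratum linear predictors.

    Draw order is fixed so that identical (config, seed) pairs give
    byte-identical panels, and so that ``generate_individual_cohort`` shares
    the same covariate realization as ``generate_panel``.
    """
    n, T = cfg.n_tracts, cfg.n_years
    tract_ids = np.array([f"T{i:04d}" for i in range(n)])
    n_counties = max(2, n // 50)
    county_of_tract = np.arange(n) % n_counties
    county_ids = np.array([f"C{c:02d}" for c in county_of_tract])
    years = np.arange(_FIRST_YEAR, _FIRST_YEAR + T)

    population = rng.integers(cfg.population_range[0], cfg.population_range[1] + 1, size=n)
    pop_gt65 = np.maximum(1, np.round(population * _ELDERLY_POP_FRACTION).astype(int))
    pop_le65 = np.maximum(1, population - pop_gt65)

    # spatial confounder Z_c, correlated with the tract-mean exposure
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    r = cfg.tract_exposure_confounding
    sigma_tm = cfg.pm_iqr / _NORMAL_IQR
    pm_tract_dev = sigma_tm * a
    z = cfg.tract_effect_sd * (r * a + np.sqrt(max(0.0, 1.0 - r * r)) * b)

    summer_base = cfg.summer_mean + _SUMMER_TRACT_SD * rng.standard_normal(n)
    winter_base = cfg.winter_mean + _WINTER_TRACT_SD * rng.standard_normal(n)

    u = cfg.resolved_year_effects()
    pm_shift = _stretch(_PM_YEAR_SHIFT, T)
    ts_shift = _stretch(_TSUMMER_YEAR_SHIFT, T)
    tw_shift = _stretch(_TWINTER_YEAR_SHIFT, T)

    # tract-year deviations: a shared meteorological factor couples the
    # exposure deviation to the temperature deviations
    met = rng.standard_normal((n, T))
    e_s = rng.standard_normal((n, T))
    e_w = rng.standard_normal((n, T))
    e_p = rng.standard_normal((n, T))
    rho = cfg.temp_exposure_coupling
    ts = summer_base[:, None] + ts_shift[None, :] + _SUMMER_DEV_SD * (0.8 * met + 0.6 * e_s)
    tw = winter_base[:, None] + tw_shift[None, :] + _WINTER_DEV_SD * (
        0.5 * met + np.sqrt(0.75) * e_w)
    pm = (cfg.pm_mean + pm_tract_dev[:, None] + pm_shift[None, :]
          + cfg.pm_dev_sd * (rho * met + np.sqrt(1.0 - rho * rho) * e_p))

    modifiers = _modifier_fields(cfg, rng, n_counties, county_of_tract)

    # temperature splines centered at the configured knots
    cs1, cs2 = cfg.temp_effect_summer
    cw1, cw2 = cfg.temp_effect_winter
    temp_part = (cs1 * (ts - cfg.summer_mean) + cs2 * np.maximum(0.0, ts - cfg.summer_mean)
                 + cw1 * (tw - cfg.winter_mean) + cw2 * np.maximum(0.0, tw - cfg.winter_mean))

    # planted effect modification of the exposure slope
    modifier_means = {}
    slope_extra = np.zeros((n, T))
    fields = dict(modifiers)
    fields["temp_summer"] = ts
    fields["temp_winter"] = tw
    for name, coeff in cfg.interaction_coeffs.items():
        if name not in fields:
            raise ValueError(f"unknown interaction variable: {name!r}")
        x = fields[name]
        modifier_means[name] = float(x.mean())
        slope_extra = slope_extra + coeff * (x - x.mean())

    base = z[:, None] + u[None, :] + temp_part   # shared across strata, per rate
    eta_rate = {}
    for age, ratio, pops in (
        ("le65", _LE65_RATE_RATIO, pop_le65),
        ("gt65", _GT65_RATE_RATIO, pop_gt65),
    ):
        b1 = cfg.stratum_beta1(age)
        eta_rate[age] = (cfg.baseline_log_rate + np.log(ratio) + base
                         + (b1 + slope_extra) * pm)

    return {
        "tract_ids": tract_ids, "county_ids": county_ids, "years": years,
        "population": population, "pop_le65": pop_le65, "pop_gt65": pop_gt65,
        "z": z, "u": u, "pm": pm, "ts": ts, "tw": tw,
        "modifiers": modifiers, "modifier_means": modifier_means,
        "eta_rate": eta_rate,
    }


def draw_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Draw counts with mean ``mu`` and variance ``dispersion * mu``.

    Pure Poisson at dispersion 1; otherwise negative binomial with size
    ``mu / (dispersion - 1)``, i.e. success probability ``1 / dispersion``,
    which matches the quasi-Poisson variance function exactly.
    """
    mu = np.asarray(mu, dtype=float)
    if dispersion < 1.0:
        raise ValueError("dispersion must be >= 1")
    if dispersion == 1.0:
        return rng.poisson(mu)
    size = mu / (dispersion - 1.0)
    return rng.negative_binomial(size, 1.0 / dispersion)


def _assemble_panel(s: dict, cfg: ScenarioConfig, deaths: dict) -> pd.DataFrame:
    n, T = cfg.n_tracts, cfg.n_years
    rows = []
    pops = {"le65": s["pop_le65"], "gt65": s["pop_gt65"], "all": s["population"]}
    deaths = dict(deaths)
    deaths["all"] = deaths["le65"] + deaths["gt65"]
    tract_rep = np.repeat(s["tract_ids"], T)
    county_rep = np.repeat(s["county_ids"], T)
    year_rep = np.tile(s["years"], n)
    for age in ("all", "le65", "gt65"):
        d = np.minimum(deaths[age].ravel(), np.repeat(pops[age], T))
        frame = pd.DataFrame({
            "tract_id": tract_rep,
            "county_id": county_rep,
            "year": year_rep,
            "age_group": age,
            "deaths": d.astype(int),
            "population": np.repeat(pops[age], T),
            "pm25": s["pm"].ravel(),
            "temp_summer": s["ts"].ravel(),
            "temp_winter": s["tw"].ravel(),
        })
        for name, arr in s["modifiers"].items():
            frame[name] = arr.ravel()
        rows.append(frame)
    panel = pd.concat(rows, ignore_index=True)
    panel = panel.sort_values(["tract_id", "year", "age_group"], ignore_index=True)
    return panel[PANEL_COLUMNS]


def _truth_from_structure(s: dict, cfg: ScenarioConfig) -> SimulationTruth:
    n, T = cfg.n_tracts, cfg.n_years
    lps = {}
    for age in ("le65", "gt65"):
        pop = s["pop_le65"] if age == "le65" else s["pop_gt65"]
        lp = s["eta_rate"][age] + np.log(pop)[:, None]
        for i in range(n):
            for j in range(T):
                lps[(s["tract_ids"][i], int(s["years"][j]), age)] = float(lp[i, j])
    for i in range(n):
        for j in range(T):
            key_le = (s["tract_ids"][i], int(s["years"][j]), "le65")
            key_gt = (s["tract_ids"][i], int(s["years"][j]), "gt65")
            lps[(s["tract_ids"][i], int(s["years"][j]), "all")] = float(
                np.log(np.exp(lps[key_le]) + np.exp(lps[key_gt])))
    return SimulationTruth(
        beta1=cfg.beta1,
        beta1_by_age={a: cfg.stratum_beta1(a) for a in ("le65", "gt65")},
        tract_effects={t: float(v) for t, v in zip(s["tract_ids"], s["z"])},
        year_effects={int(y): float(v) for y, v in zip(s["years"], s["u"])},
        temp_coefficients={"temp_summer": tuple(cfg.temp_effect_summer),
                           "temp_winter": tuple(cfg.temp_effect_winter)},
        knots={"temp_summer": cfg.summer_mean, "temp_winter": cfg.winter_mean},
        dispersion=cfg.dispersion,
        interaction_coeffs=dict(cfg.interaction_coeffs),
        modifier_means=dict(s["modifier_means"]),
        seed=cfg.seed,
        linear_predictors=lps,
    )


def generate_panel(config: ScenarioConfig) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate one tract x year x age-group panel and its ground truth.

    Counts are drawn with mean ``exp(linear predictor)`` (population offset
    included) and variance ``dispersion * mean``; the ``all`` stratum is the
    record-wise sum of the two age strata, so its variance is also
    ``dispersion`` times its mean.
    """
    rng = np.random.default_rng(config.seed)
    s = _structure(config, rng)
    deaths = {}
    for age in ("le65", "gt65"):
        pop = s["pop_le65"] if age == "le65" else s["pop_gt65"]
        mu = np.exp(s["eta_rate"][age]) * pop[:, None]
        deaths[age] = draw_counts(mu, config.dispersion, rng)
    panel = _assemble_panel(s, config, deaths)
    return panel, _truth_from_structure(s, config)


def resimulate_counts(panel: pd.DataFrame, truth: SimulationTruth, seed: int) -> pd.DataFrame:
    """Redraw the death counts of a simulated panel at its exact generating means.

    Covariates are kept fixed; only the count noise is refreshed.  Useful for
    Monte Carlo checks of the count law at a fixed linear predictor.
    """
    rng = np.random.default_rng(seed)
    out = panel.copy()
    strata = {}
    for age in ("le65", "gt65"):
        sub = out[out["age_group"] == age]
        mu = np.exp([truth.linear_predictors[(t, int(y), age)]
                     for t, y in zip(sub["tract_id"], sub["year"])])
        d = np.minimum(draw_counts(mu, truth.dispersion, rng), sub["population"].to_numpy())
        out.loc[sub.index, "deaths"] = d.astype(int)
        strata[age] = dict(zip(zip(sub["tract_id"], sub["year"]), d))
    sub = out[out["age_group"] == "all"]
    d_all = np.array([strata["le65"][(t, y)] + strata["gt65"][(t, y)]
                      for t, y in zip(sub["tract_id"], sub["year"])])
    out.loc[sub.index, "deaths"] = d_all.astype(int)
    return out


# ---------------------------------------------------------------------------
# individual-level cohort (Berkson error machinery)
# ---------------------------------------------------------------------------

def generate_individual_cohort(config: ScenarioConfig,
                               within_tract_exposure_sd: float,
                               frailty_sd: float = 0.0,
                               shared_exposure_sd: float = 0.0) -> pd.DataFrame:
    """Simulate one person-year cohort under the individual risk model.

    Each person's true exposure is the tract-year mean plus a mean-zero
    normal deviation; the analysis exposure assigned later is the tract-year
    mean, which is the Berkson error structure.  The deviation has an
    independent per-person part (SD ``within_tract_exposure_sd``) and an
    optional part shared by everyone in the tract-year (SD
    ``shared_exposure_sd``), emulating spatially correlated neighbourhood
    pollution gradients.  With purely independent deviations the aggregated
    count is exactly Poisson-binomial in the marginal death probabilities, so
    no tract-level variance inflation can occur; a shared component is what
    makes Berkson error visible as extra count dispersion.

    Death probability is ``1 - exp(-hazard)`` with hazard
    ``lambda0 * exp(beta1 * personal_exposure + gamma)`` where ``gamma`` is an
    optional personal log-frailty with SD ``frailty_sd``.

    The covariate realization (tracts, years, exposures, temperatures) is
    identical to ``generate_panel(config)`` for the same seed.
    """
    if within_tract_exposure_sd < 0:
        raise ValueError("within_tract_exposure_sd must be >= 0")
    if frailty_sd < 0:
        raise ValueError("frailty_sd must be >= 0")
    if shared_exposure_sd < 0:
        raise ValueError("shared_exposure_sd must be >= 0")
    rng = np.random.default_rng(config.seed)
    s = _structure(config, rng)
    n, T = config.n_tracts, config.n_years

    # per-capita all-age baseline hazard (exposure term excluded)
    cs1, cs2 = config.temp_effect_summer
    cw1, cw2 = config.temp_effect_winter
    temp_part = (cs1 * (s["ts"] - config.summer_mean)
                 + cs2 * np.maximum(0.0, s["ts"] - config.summer_mean)
                 + cw1 * (s["tw"] - config.winter_mean)
                 + cw2 * np.maximum(0.0, s["tw"] - config.winter_mean))
    log_lambda0 = (config.baseline_log_rate + s["z"][:, None] + s["u"][None, :] + temp_part)

    pops = s["population"]
    n_persons = int(pops.sum()) * T
    tract_idx = np.repeat(np.arange(n), pops * T)
    # within each tract, years cycle fastest
    year_idx = np.concatenate([np.tile(np.arange(T), p) for p in pops])

    lam0 = np.exp(log_lambda0[tract_idx, year_idx])
    pm_ct = s["pm"][tract_idx, year_idx]
    # deviation and frailty normals are drawn unconditionally so that runs
    # differing only in the SDs share the same downstream random stream
    # (common random numbers across scenario arms)
    shared = shared_exposure_sd * rng.standard_normal((n, T))
    dev = (within_tract_exposure_sd * rng.standard_normal(n_persons)
           + shared[tract_idx, year_idx])
    gamma = frailty_sd * rng.standard_normal(n_persons)
    pm_personal = pm_ct + dev
    hazard = lam0 * np.exp(config.beta1 * pm_personal + gamma)
    p_death = -np.expm1(-hazard)
    death = (rng.random(n_persons) < p_death).astype(np.int8)

    return pd.DataFrame({
        "tract_id": s["tract_ids"][tract_idx],
        "county_id": s["county_ids"][tract_idx],
        "year": s["years"][year_idx],
        "baseline_hazard": lam0,
        "personal_covariate": gamma,
        "personal_exposure": pm_personal,
        "tract_pm25": pm_ct,
        "temp_summer": s["ts"][tract_idx, year_idx],
        "temp_winter": s["tw"][tract_idx, year_idx],
        "death_indicator": death,
    })


def aggregate_individuals(cohort: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a person-year cohort to a tract x year panel.

    Deaths are summed, population is the person count, and the panel exposure
    is the tract-year mean of the *personal* exposures (the assigned, Berkson
    exposure).  Death totals are conserved exactly.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    grouped = cohort.groupby(["tract_id", "year"], sort=True)
    panel = grouped.agg(
        county_id=("county_id", "first"),
        deaths=("death_indicator", "sum"),
        population=("death_indicator", "size"),
        pm25=("personal_exposure", "mean"),
        temp_summer=("temp_summer", "first"),
        temp_winter=("temp_winter", "first"),
    ).reset_index()
    panel["age_group"] = "all"
    panel["deaths"] = panel["deaths"].astype(int)
    cols = [c for c in PANEL_COLUMNS if c in panel.columns]
    return panel[cols]


# ---------------------------------------------------------------------------
# seasonal means from daily series
# ---------------------------------------------------------------------------

_SUMMER_MONTHS = (6, 7, 8)
_WINTER_MONTHS = (1, 2, 12)


def seasonal_means_from_daily(daily) -> pd.DataFrame:
    """Mean summer (Jun-Aug) and winter (Jan, Feb, Dec) temperature per tract-year.

    Winter uses January, February and December of the *same* calendar year.
    ``daily`` is either a DataFrame with columns ``tract_id, date, temp`` or a
    mapping ``(tract_id, date) -> temp``.  A tract-year missing any month of a
    season is excluded with a warning.
    """
    if isinstance(daily, dict):
        daily = pd.DataFrame(
            [(t, d, v) for (t, d), v in daily.items()],
            columns=["tract_id", "date", "temp"],
        )
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month

    out = []
    for (tract, year), grp in df.groupby(["tract_id", "year"], sort=True):
        months = set(grp["month"])
        missing = ([m for m in _SUMMER_MONTHS if m not in months]
                   + [m for m in _WINTER_MONTHS if m not in months])
        if missing:
            warnings.warn(
                f"tract {tract} year {year}: missing month(s) {sorted(set(missing))}; excluded",
                stacklevel=2,
            )
            continue
        summer = grp.loc[grp["month"].isin(_SUMMER_MONTHS), "temp"].mean()
        winter = grp.loc[grp["month"].isin(_WINTER_MONTHS), "temp"].mean()
        out.append((tract, int(year), float(summer), float(winter)))
    return pd.DataFrame(out, columns=["tract_id", "year", "temp_summer", "temp_winter"])
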