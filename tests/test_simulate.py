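import numpy as np
import pandas as pd
import pytest

import didmort as dm
from didmort.simulate import draw_counts


def test_config_validation():
    with pytest.raises(ValueError):
        dm.ScenarioConfig(dispersion=0.5)
    with pytest.raises(ValueError):
        dm.ScenarioConfig(n_years=4, year_effects=(0.0, 0.1))
    with pytest.raises(ValueError):
        dm.ScenarioConfig(n_tracts=1)
    with pytest.raises(ValueError):
        dm.ScenarioConfig(population_range=(0, 10))


def test_seed_determinism():
    cfg = dm.ScenarioConfig(n_tracts=20, n_years=4, seed=7)
    p1, t1 = dm.generate_panel(cfg)
    p2, t2 = dm.generate_panel(cfg)
    pd.testing.assert_frame_equal(p1, p2)
    assert t1.linear_predictors == t2.linear_predictors
    p3, _ = dm.generate_panel(dm.ScenarioConfig(n_tracts=20, n_years=4, seed=8))
    assert not p1["deaths"].equals(p3["deaths"])


def test_panel_structural_invariants(clean_panel):
    _, panel, truth = clean_panel
    assert (panel["deaths"] <= panel["population"]).all()
    # one record per key
    assert not panel.duplicated(["tract_id", "year", "age_group"]).any()
    # contiguous years within each tract
    for _, grp in panel[panel.age_group == "all"].groupby("tract_id"):
        ys = sorted(grp["year"])
        assert ys == list(range(ys[0], ys[-1] + 1))
    # strata sum to the all-ages record
    wide = panel.pivot_table(index=["tract_id", "year"], columns="age_group",
                             values="deaths")
    assert (wide["all"] == wide["le65"] + wide["gt65"]).all()
    # every panel key has a truth entry
    for key in zip(panel["tract_id"], panel["year"], panel["age_group"]):
        assert (key[0], int(key[1]), key[2]) in truth.linear_predictors


def test_null_effect_rates_match_truth():
    """With no exposure or temperature effects and phi=1, empirical rates
    fluctuate around exp(baseline + Z_c + U_t) with Poisson noise only."""
    cfg = dm.ScenarioConfig(n_tracts=60, n_years=6, beta1=0.0, dispersion=1.0,
                            temp_effect_summer=(0.0, 0.0),
                            temp_effect_winter=(0.0, 0.0), seed=3)
    panel, truth = dm.generate_panel(cfg)
    sub = panel[panel.age_group == "all"]
    mu = np.exp([truth.linear_predictors[(t, int(y), "all")]
                 for t, y in zip(sub["tract_id"], sub["year"])])
    z = (sub["deaths"].to_numpy() - mu) / np.sqrt(mu)
    assert abs(z.mean()) < 3.0 / np.sqrt(len(z))
    assert 0.8 < z.var() < 1.2


def test_count_law_mean_matches_linear_predictor():
    """Monte Carlo mean of redrawn counts at a fixed linear predictor matches
    exp(linear predictor) within Monte Carlo error."""
    cfg = dm.ScenarioConfig(n_tracts=40, n_years=6, seed=11)
    panel, truth = dm.generate_panel(cfg)
    sub = panel[panel.age_group == "all"].reset_index(drop=True)
    mu = np.exp([truth.linear_predictors[(t, int(y), "all")]
                 for t, y in zip(sub["tract_id"], sub["year"])])
    draws = 400
    acc = np.zeros(len(sub))
    for k in range(draws):
        acc += dm.resimulate_counts(panel, truth, seed=500 + k) \
                 .loc[panel.age_group == "all", "deaths"].to_numpy()
    mean_d = acc / draws
    se = np.sqrt(truth.dispersion * mu / draws)
    zscores = (mean_d - mu) / se
    assert np.mean(np.abs(zscores) > 3) < 0.01
    assert abs(zscores.mean()) < 3.0 / np.sqrt(len(zscores))


def test_resimulate_counts_deterministic():
    cfg = dm.ScenarioConfig(n_tracts=10, n_years=3, seed=5)
    panel, truth = dm.generate_panel(cfg)
    a = dm.resimulate_counts(panel, truth, seed=1)
    b = dm.resimulate_counts(panel, truth, seed=1)
    pd.testing.assert_frame_equal(a, b)


def test_dispersion_calibration():
    """Pearson dispersion over 10,000 records at known means recovers phi=2."""
    rng = np.random.default_rng(0)
    mu = np.full(10_000, 30.0)
    y = draw_counts(mu, 2.0, rng)
    pearson = float(np.mean((y - mu) ** 2 / mu))
    assert 1.9 <= pearson <= 2.1


def test_poisson_limit_dispersion():
    rng = np.random.default_rng(1)
    mu = np.full(10_000, 30.0)
    y = draw_counts(mu, 1.0, rng)
    assert 0.9 <= float(np.mean((y - mu) ** 2 / mu)) <= 1.1


def test_confounding_is_planted():
    """With tract-level confounding, the cross-tract association of log rate
    with PM is biased away from beta1, while the within-tract (demeaned)
    association is not."""
    cfg = dm.ScenarioConfig(n_tracts=500, n_years=6, tract_exposure_confounding=0.5,
                            temp_effect_summer=(0.0, 0.0),
                            temp_effect_winter=(0.0, 0.0),
                            temp_exposure_coupling=0.0, seed=21)
    panel, truth = dm.generate_panel(cfg)
    sub = panel[panel.age_group == "all"]
    per_tract = sub.groupby("tract_id").apply(
        lambda g: pd.Series({"lr": np.log(g["deaths"].sum() / g["population"].sum()),
                             "pm": g["pm25"].mean()}), include_groups=False)
    cross = np.polyfit(per_tract["pm"], per_tract["lr"], 1)[0]
    sigma_tm = cfg.pm_iqr / 1.349
    planted_bias = 0.5 * cfg.tract_effect_sd / sigma_tm  # cov(Z, pm_c)/var(pm_c)
    assert cross - truth.beta1 > 0.5 * planted_bias
    # the two-way (tract- and year-) demeaned association is clean
    d = sub.assign(lr=np.log((sub["deaths"] + 0.5) / sub["population"]))
    for col in ("lr", "pm25"):
        d[col] = d[col] - d.groupby("tract_id")[col].transform("mean")
        d[col] = d[col] - d.groupby("year")[col].transform("mean")
    within = np.polyfit(d["pm25"], d["lr"], 1)[0]
    assert abs(within - truth.beta1) < 0.25 * planted_bias


# ---------------------------------------------------------------------------
# individual cohort
# ---------------------------------------------------------------------------

def _small_cohort_cfg(seed=9, **kw):
    base = dict(n_tracts=8, n_years=3, population_range=(150, 250),
                dispersion=1.0, seed=seed)
    base.update(kw)
    return dm.ScenarioConfig(**base)


def test_cohort_errors():
    with pytest.raises(ValueError):
        dm.generate_individual_cohort(_small_cohort_cfg(), -1.0)
    with pytest.raises(ValueError):
        dm.generate_individual_cohort(_small_cohort_cfg(), 1.0, frailty_sd=-0.1)


def test_aggregate_conserves_deaths():
    coh = dm.generate_individual_cohort(_small_cohort_cfg(), 2.0)
    panel = dm.aggregate_individuals(coh)
    assert panel["deaths"].sum() == coh["death_indicator"].sum()
    assert panel["population"].sum() == len(coh)
    assert len(panel) == coh.groupby(["tract_id", "year"]).ngroups


def test_aggregate_single_person_and_two_tracts():
    coh = pd.DataFrame({
        "tract_id": ["T1", "T2", "T2"], "county_id": "C1",
        "year": [2004, 2004, 2004],
        "personal_exposure": [10.0, 11.0, 13.0],
        "temp_summer": 18.0, "temp_winter": 5.0,
        "death_indicator": [1, 0, 1],
    })
    panel = dm.aggregate_individuals(coh)
    assert len(panel) == 2
    t1 = panel[panel.tract_id == "T1"].iloc[0]
    assert t1["deaths"] == 1 and t1["population"] == 1
    assert panel["deaths"].sum() == 2
    assert panel[panel.tract_id == "T2"]["pm25"].iloc[0] == pytest.approx(12.0)
    with pytest.raises(ValueError):
        dm.aggregate_individuals(coh.iloc[:0])


def test_aggregate_mean_matches_poisson_binomial_oracle():
    """Aggregated deaths lie within 3 SD of the sum of the per-person death
    probabilities (Poisson-binomial mean and variance)."""
    cfg = _small_cohort_cfg(seed=13, population_range=(600, 900))
    coh = dm.generate_individual_cohort(cfg, 3.0)
    p = -np.expm1(-coh["baseline_hazard"]
                  * np.exp(cfg.beta1 * coh["personal_exposure"]))
    total = coh["death_indicator"].sum()
    mean, sd = p.sum(), np.sqrt((p * (1 - p)).sum())
    assert abs(total - mean) < 3 * sd


def test_degenerate_berkson_matches_panel_expectation():
    """With zero within-tract exposure spread the aggregated cohort has the
    same expected counts as the count panel, up to the O(hazard^2) gap between
    1 - exp(-h) and h."""
    cfg = _small_cohort_cfg(seed=17, population_range=(2000, 3000))
    coh = dm.generate_individual_cohort(cfg, 0.0)
    _, truth = dm.generate_panel(cfg)
    h = coh["baseline_hazard"] * np.exp(cfg.beta1 * coh["personal_exposure"])
    expected = (-np.expm1(-h)).groupby([coh["tract_id"], coh["year"]]).sum()
    for (t, y), val in expected.items():
        mu_panel = np.exp(truth.linear_predictors[(t, int(y), "all")])
        assert val == pytest.approx(mu_panel, rel=float(h.max()))
    # personal exposures equal the tract mean exactly
    assert np.allclose(coh["personal_exposure"], coh["tract_pm25"])


def test_null_beta_death_independent_of_exposure_deviation():
    cfg = _small_cohort_cfg(seed=23, beta1=0.0, population_range=(1500, 2500),
                            baseline_log_rate=float(np.log(0.05)))
    coh = dm.generate_individual_cohort(cfg, 5.0)
    dev = coh["personal_exposure"] - coh["tract_pm25"]
    r = np.corrcoef(dev, coh["death_indicator"])[0, 1]
    assert abs(r) < 3.0 / np.sqrt(len(coh))


# ---------------------------------------------------------------------------
# seasonal means
# ---------------------------------------------------------------------------

def _daily_frame(values_by_month, tract="T1", year=2004):
    rows = []
    for month, val in values_by_month.items():
        days = pd.Period(f"{year}-{month:02d}").days_in_month
        for d in range(1, days + 1):
            v = val(d) if callable(val) else val
            rows.append((tract, f"{year}-{month:02d}-{d:02d}", v))
    return pd.DataFrame(rows, columns=["tract_id", "date", "temp"])


def test_seasonal_means_constant_and_listed_months_only():
    daily = _daily_frame({m: 20.0 for m in range(1, 13)})
    out = dm.seasonal_means_from_daily(daily)
    assert out.iloc[0]["temp_summer"] == pytest.approx(20.0)
    assert out.iloc[0]["temp_winter"] == pytest.approx(20.0)

    vals = {m: 99.0 for m in (3, 4, 5, 9, 10, 11)}
    vals.update({m: 18.0 for m in (6, 7, 8)})
    vals.update({m: 5.0 for m in (1, 2, 12)})
    out = dm.seasonal_means_from_daily(_daily_frame(vals))
    assert out.iloc[0]["temp_summer"] == pytest.approx(18.0)
    assert out.iloc[0]["temp_winter"] == pytest.approx(5.0)


def test_seasonal_means_arithmetic_oracle():
    """92 summer days valued 1..92 average to 46.5."""
    counter = {"i": 0}

    def summer_val(_):
        counter["i"] += 1
        return float(counter["i"])

    vals = {m: 0.0 for m in range(1, 13)}
    for m in (6, 7, 8):
        vals[m] = summer_val
    out = dm.seasonal_means_from_daily(_daily_frame(vals))
    assert out.iloc[0]["temp_summer"] == pytest.approx(46.5)


def test_seasonal_means_missing_month_excluded_with_warning():
    vals = {m: 10.0 for m in range(1, 13) if m != 12}
    with pytest.warns(UserWarning, match="missing month"):
        out = dm.seasonal_means_from_daily(_daily_frame(vals))
    assert len(out) == 0


def test_seasonal_means_accepts_mapping():
    daily = {("T1", f"2004-{m:02d}-15"): 7.0 for m in range(1, 13)}
    out = dm.seasonal_means_from_daily(daily)
    assert out.iloc[0]["temp_winter"] == pytest.approx(7.0)
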