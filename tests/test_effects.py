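import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import didmort as dm
from didmort.glm import DesignInfo, FitResult, ModelSpec, build_design, fit_quasipoisson


def test_percent_change_cases():
    est = dm.percent_change(0.0, 0.02, 2.0)
    assert est.percent_change == pytest.approx(0.0)
    assert est.ci_low == pytest.approx(-est.ci_high / (1 + est.ci_high / 100), rel=1e-6)

    est = dm.percent_change(np.log(1.03) / 2.0, 0.0, 2.0)
    assert est.percent_change == pytest.approx(3.0, abs=1e-12)

    est = dm.percent_change(np.log(1.03) / 2.0, 0.0, 10.0)
    assert est.percent_change == pytest.approx(100 * (1.03 ** 5 - 1), abs=1e-9)
    assert est.percent_change == pytest.approx(15.93, abs=0.01)

    with pytest.raises(ValueError):
        dm.percent_change(0.1, 0.01, 0.0)
    with pytest.raises(ValueError):
        dm.percent_change(0.1, -0.01, 2.0)


@given(st.floats(-0.2, 0.2), st.integers(1, 6))
def test_percent_change_conversion_identity(slope, k):
    """Percent change per k increments equals the compounded single-increment
    change, exactly."""
    one = dm.percent_change(slope, 0.01, 2.0)
    many = dm.percent_change(slope, 0.01, 2.0 * k)
    assert many.percent_change == pytest.approx(
        100 * ((1 + one.percent_change / 100) ** k - 1), rel=1e-10)


@given(st.floats(-0.1, 0.1), st.floats(0, 0.3))
def test_ci_endpoints_ordered(slope, se):
    est = dm.percent_change(slope, se, 2.0)
    assert est.ci_low <= est.percent_change <= est.ci_high


def _handmade_fit(params: dict, vcov: np.ndarray, moderators: dict,
                  moderator_means: dict) -> FitResult:
    idx = pd.Index(params.keys())
    design = DesignInfo(
        X=None, y=None, offset=None, columns=list(idx),
        row_keys=pd.DataFrame(), tract_levels=[], year_levels=[],
        ref_tract="", ref_year=0, knots={}, moderators=moderators,
        moderator_means=moderator_means, exposure="pm25",
        spec=ModelSpec())
    v = pd.DataFrame(vcov, index=idx, columns=idx)
    return FitResult(params=pd.Series(params), vcov=v, vcov_unscaled=v,
                     dispersion=1.0, fitted_means=None, n_obs=0, n_params=len(idx),
                     residual_df=0, converged=True, n_iterations=0,
                     dropped_records=[], design=design)


def test_conditional_effect_hand_set_coefficients():
    """beta1 = 0.01 per ug/m3 plus a winter hinge interaction of 0.005 per
    degree above the knot: at winter = knot + 1 the slope is 0.015 and the
    percent change per 2 ug/m3 is 100*(e^0.03 - 1)."""
    knot = 5.9
    fit = _handmade_fit(
        params={"pm25": 0.01, "pm25:temp_winter_hinge": 0.005},
        vcov=np.diag([1e-6, 4e-6]),
        moderators={"pm25:temp_winter_hinge": {
            "var": "temp_winter", "kind": "spline_hinge", "knot": knot,
            "mean": 0.0, "sd": 1.0}},
        moderator_means={"temp_winter": knot})
    est = dm.conditional_effect(fit, {"temp_winter": knot + 1.0}, increment=2.0)
    assert est.slope == pytest.approx(0.015)
    assert est.percent_change == pytest.approx(100 * (np.exp(0.03) - 1), abs=1e-9)
    assert est.percent_change == pytest.approx(3.045, abs=1e-3)
    # delta method with zero covariances: weighted sum of variances
    assert est.slope_se == pytest.approx(np.sqrt(1e-6 + 1.0 ** 2 * 4e-6))
    # below the knot the hinge contributes -mean/sd = 0
    est0 = dm.conditional_effect(fit, {"temp_winter": knot - 2.0})
    assert est0.slope == pytest.approx(0.01)

    with pytest.raises(ValueError, match="temp_winter"):
        dm.conditional_effect(fit, {})


def test_zero_interactions_conditional_equals_main(clean_panel):
    _, panel, _ = clean_panel
    sub = panel[panel.age_group == "all"]
    spec = dm.ModelSpec(interactions=("temp_winter", "med_income"))
    fit = fit_quasipoisson(build_design(sub, spec))
    for term in fit.design.moderators:
        fit.params[term] = 0.0
    for setting in ({"temp_winter": 3.0, "med_income": 20000.0},
                    {"temp_winter": 9.0, "med_income": 90000.0}):
        est = dm.conditional_effect(fit, setting)
        assert est.slope == pytest.approx(fit.params["pm25"], rel=1e-12)


def test_interaction_test_cases(clean_panel):
    _, panel, _ = clean_panel
    sub = panel[panel.age_group == "all"]
    fit = fit_quasipoisson(build_design(sub, dm.ModelSpec(interactions=("med_income",))))
    term = "pm25:med_income"

    fit.params[term] = 0.0
    t = dm.interaction_test(fit, [term])
    assert t.wald_statistic == pytest.approx(0.0)
    assert t.p_value == pytest.approx(1.0)

    fit.params[term] = 1.96 * np.sqrt(fit.vcov.loc[term, term])
    t = dm.interaction_test(fit, [term])
    assert t.p_value == pytest.approx(0.05, abs=1e-3)
    assert t.scope == "per-contrast"

    with pytest.raises(ValueError, match="nonexistent"):
        dm.interaction_test(fit, ["nonexistent"])


def test_joint_interaction_test_two_df():
    """Two independent unit z-scores give a chi-square(2) statistic of 2 and
    p = exp(-1)."""
    fit = _handmade_fit(
        params={"pm25": 0.0, "a": 1.0, "b": 1.0},
        vcov=np.diag([1.0, 1.0, 1.0]), moderators={}, moderator_means={})
    t = dm.interaction_test(fit, ["a", "b"])
    assert t.wald_statistic == pytest.approx(2.0)
    assert t.df == 2 and t.scope == "joint"
    assert t.p_value == pytest.approx(np.exp(-1.0), rel=1e-10)


def test_run_stratified_recovery_equal_and_unequal_slopes():
    cfg = dm.ScenarioConfig(n_tracts=300, n_years=6, seed=77)
    panel, truth = dm.generate_panel(cfg)
    res = dm.run_stratified(panel, dm.ModelSpec())
    assert set(res) == {"all", "gt65", "le65"}
    for stratum, (est, fit) in res.items():
        assert abs(est.slope - truth.beta1) < 3 * est.slope_se

    cfg2 = dm.ScenarioConfig(n_tracts=300, n_years=6, seed=78,
                             beta1_by_age={"gt65": np.log(1.03) / 2, "le65": 0.0})
    panel2, _ = dm.generate_panel(cfg2)
    res2 = dm.run_stratified(panel2, dm.ModelSpec(), strata=("gt65", "le65"))
    est_le, _ = res2["le65"]
    assert abs(est_le.slope) < 3 * est_le.slope_se


def test_run_stratified_empty_stratum_skipped(clean_panel):
    _, panel, _ = clean_panel
    sub = panel[panel.age_group != "le65"]
    with pytest.warns(UserWarning, match="empty"):
        res = dm.run_stratified(sub, dm.ModelSpec(), strata=("all", "le65"))
    assert "le65" not in res


def test_run_stratified_flags_inconsistent_sums(clean_panel):
    _, panel, _ = clean_panel
    bad = panel.copy()
    idx = bad.index[bad["age_group"] == "all"][0]
    bad.loc[idx, "deaths"] += 1
    with pytest.warns(UserWarning, match="do not sum"):
        dm.run_stratified(bad, dm.ModelSpec(), strata=("all",))


def test_modifier_effect_table_monotone_and_identity():
    fit = _handmade_fit(
        params={"pm25": 0.01, "pm25:med_income": 0.004},
        vcov=np.diag([1e-6, 1e-6]),
        moderators={"pm25:med_income": {
            "var": "med_income", "kind": "scalar", "knot": None,
            "mean": 60000.0, "sd": 30000.0}},
        moderator_means={"med_income": 60000.0})
    lo, hi, test = dm.modifier_effect_table(fit, "med_income", 30000.0, 120000.0)
    # positive interaction: higher effect at the higher decile
    assert hi.percent_change > lo.percent_change
    # linear identity: slope difference = coefficient * (high - low) / sd
    assert hi.slope - lo.slope == pytest.approx(0.004 * 90000.0 / 30000.0, rel=1e-10)
    # zero interaction: identical estimates at both deciles
    fit.params["pm25:med_income"] = 0.0
    lo0, hi0, _ = dm.modifier_effect_table(fit, "med_income", 30000.0, 120000.0)
    assert lo0.percent_change == pytest.approx(hi0.percent_change, rel=1e-12)

    with pytest.raises(ValueError, match="pct_black"):
        dm.modifier_effect_table(fit, "pct_black", 0.0, 50.0)


def test_planted_modifier_interaction_recovered():
    """The fitted slope difference across modifier deciles matches the planted
    coefficient times the decile gap."""
    coeff = -1e-6
    cfg = dm.ScenarioConfig(n_tracts=400, n_years=6, seed=101,
                            interaction_coeffs={"med_income": coeff})
    panel, _ = dm.generate_panel(cfg)
    sub = panel[panel.age_group == "all"]
    fit = fit_quasipoisson(build_design(sub, dm.ModelSpec(interactions=("med_income",))))
    lo, hi = sub["med_income"].quantile([0.1, 0.9])
    est_lo, est_hi, test = dm.modifier_effect_table(fit, "med_income",
                                                    float(lo), float(hi))
    planted_diff = coeff * (hi - lo)
    se_diff = np.sqrt(est_lo.slope_se ** 2 + est_hi.slope_se ** 2)
    assert abs((est_hi.slope - est_lo.slope) - planted_diff) < 3 * se_diff
    assert test.p_value < 0.05


def test_temperature_effect_table_shape(clean_panel):
    _, panel, _ = clean_panel
    sub = panel[panel.age_group == "all"]
    spec = dm.ModelSpec(interactions=("temp_summer", "temp_winter"))
    fit = fit_quasipoisson(build_design(sub, spec))
    tab = dm.temperature_effect_table(fit)
    assert list(tab["setting"]) == ["average", "summer -1", "summer +1",
                                    "winter -1", "winter +1"]
    assert {"percent_change", "ci_low", "ci_high",
            "interaction_p_temp_summer", "interaction_p_temp_winter"} <= set(tab.columns)
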