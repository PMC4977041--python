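"""Monte Carlo validation studies for the panel estimator.

Each study simulates panels under a declared scenario, runs the full
estimation pipeline on every replicate, and summarizes recovery of the
planted truth: slope recovery and confidence-interval coverage, the bias of a
deliberately mis-specified cross-sectional fit against its analytically
planted value, the Berkson-error check on individual-level cohorts, the
temperature effect-modification ordering, and backward-elimination
consistency.  These are the package's own design-validation experiments; the
scenario sizes are chosen to give adequate Monte Carlo power at desk-scale
run times.
"""
from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .effects import conditional_effect, default_setting, percent_change
from .glm import ModelSpec, build_design, fit_quasipoisson
from .meta import meta_analysis
from .selection import backward_eliminate
from .simulate import ScenarioConfig, aggregate_individuals, \
    generate_individual_cohort, generate_panel

IQR = 2.0  # reporting increment, ug/m3


def _rep_seed(seed: int, rep: int, stream: int = 0) -> int:
    """A well-separated 31-bit seed for one replicate."""
    return int(np.random.SeedSequence([seed, stream, rep]).generate_state(1)[0]
               % (2 ** 31))


def recovery_study(seed: int = 0, n_reps: int = 200, n_tracts: int = 200,
                   n_years: int = 6) -> dict:
    """Slope recovery and 95% CI coverage on clean overdispersed panels.

    The planted slope is ln(1.03)/2 per ug/m3 (3% per IQR of 2 ug/m3) with
    quasi-Poisson dispersion 2; the fitted model matches the generating one
    (tract + year dummies, temperature splines, offset).
    """
    spec = ModelSpec()
    pcts, covered = [], 0
    truth_pct = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_reps):
            cfg = ScenarioConfig(n_tracts=n_tracts, n_years=n_years,
                                 seed=_rep_seed(seed, rep))
            panel, truth = generate_panel(cfg)
            fit = fit_quasipoisson(build_design(panel[panel.age_group == "all"], spec))
            b, se = float(fit.params["pm25"]), float(fit.se()["pm25"])
            pcts.append(percent_change(b, se, IQR).percent_change)
            covered += (b - 1.96 * se <= truth.beta1 <= b + 1.96 * se)
            truth_pct = percent_change(truth.beta1, 0.0, IQR).percent_change
    pcts = np.asarray(pcts)
    return {
        "true_percent_change": truth_pct,
        "mean_percent_change": float(pcts.mean()),
        "mc_se": float(pcts.std(ddof=1) / np.sqrt(n_reps)),
        "coverage": covered / n_reps,
        "n_reps": n_reps,
    }


def confounding_study(seed: int = 0, n_reps: int = 200, n_tracts: int = 200,
                      n_years: int = 6, confounding: float = 0.5) -> dict:
    """Bias of the no-tract-dummy fit versus its planted value; DiD bias.

    The scenario correlates the tract effects with the tract-mean exposure at
    the given level and switches temperature effects off so the planted bias
    is purely spatial.  The 'planted' bias of the mis-specified model is the
    pseudo-true slope obtained by solving the same estimating equation with
    the exact expected counts as response (a deterministic, noise-free fit),
    averaged over replicates; a moment approximation is returned alongside.
    """
    cross_spec = ModelSpec(fixed_effects=("year",), splines=())
    did_spec = ModelSpec(splines=())
    b_cross, b_did, b_pseudo = [], [], []
    beta1 = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_reps):
            cfg = ScenarioConfig(
                n_tracts=n_tracts, n_years=n_years,
                tract_exposure_confounding=confounding,
                temp_effect_summer=(0.0, 0.0), temp_effect_winter=(0.0, 0.0),
                temp_exposure_coupling=0.0, seed=_rep_seed(seed, rep, 1))
            panel, truth = generate_panel(cfg)
            beta1 = truth.beta1
            sub = panel[panel.age_group == "all"]

            d = build_design(sub, cross_spec)
            b_cross.append(float(fit_quasipoisson(d).params["pm25"]))

            d_true = build_design(sub.assign(deaths=1), cross_spec)
            d_true.y = np.exp([truth.linear_predictors[(t, int(y), "all")]
                               for t, y in zip(d_true.row_keys["tract_id"],
                                               d_true.row_keys["year"])])
            b_pseudo.append(float(fit_quasipoisson(d_true).params["pm25"]))

            b_did.append(float(fit_quasipoisson(
                build_design(sub, did_spec)).params["pm25"]))
    b_cross, b_did, b_pseudo = map(np.asarray, (b_cross, b_did, b_pseudo))
    cfg0 = ScenarioConfig()
    sigma_tm = cfg0.pm_iqr / 1.349
    moment_bias = (confounding * cfg0.tract_effect_sd * sigma_tm
                   / (sigma_tm ** 2 + cfg0.pm_dev_sd ** 2))
    return {
        "beta1": beta1,
        "planted_bias": float((b_pseudo - beta1).mean()),
        "moment_bias": float(moment_bias),
        "cross_sectional_bias": float((b_cross - beta1).mean()),
        "did_bias": float((b_did - beta1).mean()),
        "did_mc_se": float(b_did.std(ddof=1) / np.sqrt(n_reps)),
        "n_reps": n_reps,
    }


def _berkson_config(seed: int, beta1: float, total_sd: float,
                    rate: float) -> ScenarioConfig:
    # baseline chosen so the marginal person-year death rate at the mean
    # exposure equals `rate` in both arms (the lognormal exposure deviation
    # raises the mean hazard by exp((beta1*sd)^2 / 2))
    base = float(np.log(rate) - beta1 * 11.3 - 0.5 * (beta1 * total_sd) ** 2)
    return ScenarioConfig(
        n_tracts=25, n_years=4, population_range=(80, 120),
        baseline_log_rate=base, beta1=beta1, dispersion=1.0, pm_dev_sd=2.0,
        temp_effect_summer=(0.0, 0.0), temp_effect_winter=(0.0, 0.0),
        temp_exposure_coupling=0.0, tract_effect_sd=0.15, seed=seed)


def berkson_study(seed: int = 0, n_reps: int = 500, beta1: float = 0.1,
                  total_sd: float = 10.0, shared_fraction: float = 0.3,
                  rate: float = 0.012) -> dict:
    """Berkson-error check on individual cohorts, tract-mean analysis.

    Two arms share covariates and random streams (common random numbers): one
    with no within-tract exposure spread, one with spread ``total_sd`` of
    which ``shared_fraction`` of the variance is shared within a tract-year
    (spatially correlated micro-environments).  Both arms are fitted on the
    tract-year mean exposure.  The slope should stay unbiased while its
    sampling variance inflates relative to the no-spread arm.

    With purely independent personal deviations the aggregated count is
    exactly Poisson-binomial in the marginal death probabilities, so the
    deviations add no tract-level variance at all; a shared component is what
    makes the error visible.  The scenario is a deliberately stylized,
    high-signal cohort so both properties are measurable at this replicate
    count.
    """
    spec = ModelSpec(splines=())

    def one(rep, spread):
        sd = total_sd if spread else 0.0
        cfg = _berkson_config(_rep_seed(seed, rep, 2), beta1, sd, rate)
        coh = generate_individual_cohort(
            cfg, within_tract_exposure_sd=sd * np.sqrt(1.0 - shared_fraction),
            shared_exposure_sd=sd * np.sqrt(shared_fraction))
        panel = aggregate_individuals(coh)
        # analysis exposure: the tract-year design mean (the Berkson assignment)
        panel = panel.assign(
            pm25=coh.groupby(["tract_id", "year"])["tract_pm25"].first().values)
        return float(fit_quasipoisson(build_design(panel, spec)).params["pm25"])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        b0 = np.array([one(r, False) for r in range(n_reps)])
        b1 = np.array([one(r, True) for r in range(n_reps)])
    return {
        "beta1": beta1,
        "mean_slope_no_spread": float(b0.mean()),
        "mean_slope_berkson": float(b1.mean()),
        "mc_se_berkson": float(b1.std(ddof=1) / np.sqrt(n_reps)),
        "var_no_spread": float(b0.var(ddof=1)),
        "var_berkson": float(b1.var(ddof=1)),
        "variance_ratio": float(b1.var(ddof=1) / b0.var(ddof=1)),
        "n_reps": n_reps,
    }


def interaction_ordering_study(seed: int = 0, n_reps: int = 200,
                               n_tracts: int = 200, n_years: int = 6,
                               winter_coeff: float = 0.017) -> dict:
    """Recovery of the winter-temperature effect modification ordering.

    A positive exposure x winter-temperature interaction is planted; each
    replicate fits the model with both seasonal product-term sets and asks
    whether the conditional effect at one degree above the mean winter
    temperature exceeds the effect at the mean.  The default planted slope
    change (0.017 per ug/m3 per degree C) matches the magnitude implied by
    reported conditional estimates of this design.
    """
    spec = ModelSpec(interactions=("temp_summer", "temp_winter"))
    hits, diffs = 0, []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_reps):
            cfg = ScenarioConfig(n_tracts=n_tracts, n_years=n_years,
                                 interaction_coeffs={"temp_winter": winter_coeff},
                                 seed=_rep_seed(seed, rep, 3))
            panel, _ = generate_panel(cfg)
            fit = fit_quasipoisson(build_design(panel[panel.age_group == "all"], spec))
            setting = default_setting(fit)
            at_mean = conditional_effect(fit, setting, IQR)
            plus1 = conditional_effect(
                fit, {**setting, "temp_winter": setting["temp_winter"] + 1.0}, IQR)
            diffs.append(plus1.slope - at_mean.slope)
            hits += plus1.percent_change > at_mean.percent_change
    return {
        "planted_slope_change": winter_coeff,
        "mean_slope_change": float(np.mean(diffs)),
        "ordering_rate": hits / n_reps,
        "n_reps": n_reps,
    }


CANDIDATE_MODIFIERS = ("pct_black", "med_home_value", "med_income",
                       "smoking_rate", "diabetes_rate")


def selection_study(seed: int = 0, n_runs: int = 100, n_tracts: int = 400,
                    n_years: int = 6, income_coeff: float = -1e-6) -> dict:
    """Backward-elimination consistency with one truly nonzero interaction.

    Only the median-income product is planted (a slope change of -0.1% per
    ug/m3 per $1,000); the study records how often it is retained at all and
    how often it is the sole survivor.  Step-down elimination retains the
    smallest-p null term whenever its final-stage p-value falls below alpha,
    which happens with probability close to 1 - (1 - alpha)^4 for four null
    candidates, so the sole-survivor rate has a ceiling near 80-85% even with
    overwhelming power on the true term.
    """
    sole, retained = 0, 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_runs):
            cfg = ScenarioConfig(n_tracts=n_tracts, n_years=n_years,
                                 interaction_coeffs={"med_income": income_coeff},
                                 seed=_rep_seed(seed, rep, 4))
            panel, _ = generate_panel(cfg)
            trace = backward_eliminate(panel[panel.age_group == "all"],
                                       ModelSpec(), CANDIDATE_MODIFIERS)
            sole += trace.final_terms == frozenset({"med_income"})
            retained += "med_income" in trace.final_terms
    return {
        "sole_survivor_rate": sole / n_runs,
        "retained_rate": retained / n_runs,
        "n_runs": n_runs,
    }


def meta_agreement_study(seed: int = 0, n_reps: int = 20, n_tracts: int = 300,
                         n_years: int = 6) -> dict:
    """DiD versus within-tract pooled estimates on trend-free clean panels.

    The within-tract regressions carry no year adjustment, so the comparison
    scenario has no common mortality trend (a correlated state-wide trend
    would, correctly, shift the pooled estimator: that is the confounding the
    DiD design exists to remove).  Returns the replicate means of both
    percent changes per IQR.
    """
    did_pcts, pooled_pcts, tau2s = [], [], []
    truth_pct = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_reps):
            cfg = ScenarioConfig(n_tracts=n_tracts, n_years=n_years,
                                 year_effects=(0.0,) * n_years,
                                 temp_effect_summer=(0.0, 0.0),
                                 temp_effect_winter=(0.0, 0.0),
                                 seed=_rep_seed(seed, rep, 5))
            panel, truth = generate_panel(cfg)
            truth_pct = percent_change(truth.beta1, 0.0, IQR).percent_change
            sub = panel[panel.age_group == "all"]
            fit = fit_quasipoisson(build_design(sub, ModelSpec(splines=())))
            _, pooled = meta_analysis(sub, increment=IQR)
            did_pcts.append(percent_change(float(fit.params["pm25"]),
                                           0.0, IQR).percent_change)
            pooled_pcts.append(pooled.percent_change_per_iqr.percent_change)
            tau2s.append(pooled.tau2)
    did_pcts, pooled_pcts = np.asarray(did_pcts), np.asarray(pooled_pcts)
    return {
        "true_percent_change": truth_pct,
        "did_percent_change": float(did_pcts.mean()),
        "pooled_percent_change": float(pooled_pcts.mean()),
        "did_mc_se": float(did_pcts.std(ddof=1) / np.sqrt(n_reps)),
        "pooled_mc_se": float(pooled_pcts.std(ddof=1) / np.sqrt(n_reps)),
        "mean_tau2": float(np.mean(tau2s)),
        "n_reps": n_reps,
    }
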