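"""Reported quantities: percent change per exposure increment, conditional
effects at chosen moderator settings, Wald interaction tests, and
age-stratified runs.

All effects are reported as the percent change in the mortality rate per an
exposure increment (default 2 ug/m3, the interquartile range of annual
PM2.5), with 95% normal-theory confidence intervals formed on the log-rate
scale and back-transformed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glm import FitResult, ModelSpec, build_design, fit_quasipoisson

Z95 = 1.96


@dataclass
class EffectEstimate:
    """Percent change in the rate per ``increment`` units of exposure,
    evaluated at a covariate ``setting`` (empty for the main effect)."""

    increment: float
    setting: dict
    percent_change: float
    ci_low: float
    ci_high: float
    slope: float
    slope_se: float

    def __str__(self):
        return (f"{self.percent_change:+.1f}% ({self.ci_low:.1f}, {self.ci_high:.1f}) "
                f"per {self.increment:g} unit(s)")


@dataclass
class InteractionTest:
    terms: tuple
    wald_statistic: float
    df: int
    p_value: float
    scope: str  # "joint" or "per-contrast"


def percent_change(slope: float, slope_se: float, increment: float = 2.0,
                   setting: dict | None = None) -> EffectEstimate:
    """Convert a log rate-ratio slope (per unit exposure) to a percent change
    per ``increment``, with a 95% Wald interval on the log scale."""
    if increment <= 0:
        raise ValueError("increment must be > 0")
    if slope_se < 0:
        raise ValueError("slope_se must be >= 0")
    point = 100.0 * np.expm1(slope * increment)
    lo = 100.0 * np.expm1((slope - Z95 * slope_se) * increment)
    hi = 100.0 * np.expm1((slope + Z95 * slope_se) * increment)
    return EffectEstimate(increment=increment, setting=dict(setting or {}),
                          percent_change=float(point), ci_low=float(lo),
                          ci_high=float(hi), slope=float(slope),
                          slope_se=float(slope_se))


def _moderator_vars(fit: FitResult) -> list:
    return sorted({info["var"] for info in fit.design.moderators.values()})


def default_setting(fit: FitResult) -> dict:
    """Every moderator at its fit-sample mean (the 'average' reference row)."""
    return {v: fit.design.moderator_means[v] for v in _moderator_vars(fit)}


def conditional_effect(fit: FitResult, setting: dict,
                       increment: float = 2.0) -> EffectEstimate:
    """Exposure effect at a stated moderator setting, delta-method CI.

    The slope is the exposure coefficient plus each product coefficient times
    its moderator basis value at the setting (spline moderators evaluated
    through both basis columns, with the centering and scaling frozen at fit
    time).  The variance is the exact linear-combination variance from the
    dispersion-scaled coefficient covariance.
    """
    d = fit.design
    needed = _moderator_vars(fit)
    missing = [v for v in needed if v not in setting]
    if missing:
        raise ValueError(f"setting is missing moderator value(s): {missing}")

    names = [d.exposure]
    weights = [1.0]
    for pname, info in d.moderators.items():
        v = float(setting[info["var"]])
        raw = max(0.0, v - info["knot"]) if info["kind"] == "spline_hinge" else v
        names.append(pname)
        weights.append((raw - info["mean"]) / info["sd"])
    w = np.asarray(weights)
    b = fit.params[names].to_numpy()
    V = fit.vcov.loc[names, names].to_numpy()
    slope = float(w @ b)
    se = float(np.sqrt(w @ V @ w))
    return percent_change(slope, se, increment,
                          setting={k: setting[k] for k in needed})


def interaction_test(fit: FitResult, terms) -> InteractionTest:
    """Wald chi-square test of the named coefficients being jointly zero.

    With one term this reduces to the squared z-test (a per-contrast test);
    pass several terms for the joint test of a product-term set.
    """
    terms = tuple(terms) if not isinstance(terms, str) else (terms,)
    for t in terms:
        if t not in fit.params.index:
            raise ValueError(f"term {t!r} not in the fit")
    b = fit.params[list(terms)].to_numpy()
    V = fit.vcov.loc[list(terms), list(terms)].to_numpy()
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        raise ValueError(f"singular covariance block for terms {terms}") from None
    df = len(terms)
    return InteractionTest(terms=terms, wald_statistic=stat, df=df,
                           p_value=float(stats.chi2.sf(stat, df)),
                           scope="joint" if df > 1 else "per-contrast")


def product_terms(fit: FitResult, moderator: str) -> list:
    """Names of the exposure x moderator product columns in a fit."""
    return [p for p, info in fit.design.moderators.items() if info["var"] == moderator]


def run_stratified(panel: pd.DataFrame, spec: ModelSpec | None = None,
                   strata=("all", "gt65", "le65"), increment: float = 2.0,
                   **options) -> dict:
    """Independent full fits per age stratum; same model specification.

    Validates that stratum deaths sum to the ``all`` records where all three
    strata are present; empty strata are skipped with a warning.  Returns a
    mapping stratum -> (EffectEstimate, FitResult).
    """
    spec = spec or ModelSpec()
    if "age_group" not in panel.columns:
        raise ValueError("panel has no age_group column")
    present = set(panel["age_group"].unique())
    if {"all", "le65", "gt65"} <= present:
        wide = panel.pivot_table(index=["tract_id", "year"], columns="age_group",
                                 values="deaths", aggfunc="sum")
        bad = wide[wide["all"] != wide["le65"] + wide["gt65"]]
        if len(bad):
            warnings.warn(
                f"{len(bad)} tract-year(s) where stratum deaths do not sum to 'all'",
                stacklevel=2)
    out = {}
    for stratum in strata:
        sub = panel[panel["age_group"] == stratum]
        if len(sub) == 0:
            warnings.warn(f"stratum {stratum!r} is empty; skipped", stacklevel=2)
            continue
        fit = fit_quasipoisson(build_design(sub, spec), **options)
        if fit.design.moderators:
            est = conditional_effect(fit, default_setting(fit), increment)
        else:
            est = percent_change(fit.params[spec.exposure],
                                 fit.se()[spec.exposure], increment)
        out[stratum] = (est, fit)
    return out


def modifier_effect_table(fit: FitResult, modifier: str, low: float, high: float,
                          increment: float = 2.0):
    """Conditional effects at two stated modifier values (e.g. its deciles),
    other moderators held at their fit-sample means, plus the interaction test.

    Returns ``(estimate_at_low, estimate_at_high, InteractionTest)``.
    """
    terms = product_terms(fit, modifier)
    if not terms:
        raise ValueError(f"no exposure x {modifier!r} product in the model")
    base = default_setting(fit)
    est_low = conditional_effect(fit, {**base, modifier: low}, increment)
    est_high = conditional_effect(fit, {**base, modifier: high}, increment)
    return est_low, est_high, interaction_test(fit, terms)


def temperature_effect_table(fit: FitResult, increment: float = 2.0) -> pd.DataFrame:
    """Conditional effects at the seasonal-temperature means and at one degree
    below / above each mean, the other season held at its mean.

    Requires a fit with exposure x summer and exposure x winter spline
    products.  One row per setting, with the per-set joint interaction p.
    """
    means = default_setting(fit)
    rows = []
    specs = [("average", dict(means))]
    for var, label in (("temp_summer", "summer"), ("temp_winter", "winter")):
        if var not in means:
            continue
        for delta, tag in ((-1.0, "-1"), (1.0, "+1")):
            specs.append((f"{label} {tag}", {**means, var: means[var] + delta}))
    for label, setting in specs:
        est = conditional_effect(fit, setting, increment)
        row = {"setting": label}
        row.update({f"{k}": v for k, v in setting.items()})
        row.update({
            "percent_change": est.percent_change,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "slope": est.slope, "slope_se": est.slope_se,
        })
        rows.append(row)
    df = pd.DataFrame(rows)
    for var in ("temp_summer", "temp_winter"):
        terms = product_terms(fit, var)
        if terms:
            df[f"interaction_p_{var}"] = interaction_test(fit, terms).p_value
    return df
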