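"""Within-tract Poisson regressions pooled by DerSimonian-Laird meta-analysis.

This is the sensitivity analysis that uses only within-tract exposure
variation: each tract's yearly death counts are regressed on its yearly
PM2.5 (intercept plus exposure, log-population offset, plain Poisson), and
the per-tract slopes are pooled with random-effects weights
``1 / (se^2 + tau^2)`` where ``tau^2`` is the DerSimonian-Laird moment
estimate of between-tract heterogeneity.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .effects import EffectEstimate, percent_change


@dataclass
class TractEstimate:
    tract_id: str
    slope: float
    se: float
    usable: bool
    reason: str = ""


@dataclass
class PooledResult:
    pooled_slope: float
    pooled_se: float
    tau2: float
    q_statistic: float
    n_used: int
    n_excluded: int
    percent_change_per_iqr: EffectEstimate


def _poisson_slope(x: np.ndarray, y: np.ndarray, offset: np.ndarray,
                   tol: float = 1e-10, max_iter: int = 50):
    """Two-parameter Poisson IRLS (intercept + slope, log link, offset)."""
    X = np.column_stack([np.ones_like(x), x])
    mu = y + 0.5
    eta = np.log(mu)
    beta = np.zeros(2)
    for _ in range(max_iter):
        w = mu
        z = (eta - offset) + (y - mu) / mu
        A = X.T @ (w[:, None] * X)
        try:
            new_beta = scipy.linalg.solve(A, X.T @ (w * z), assume_a="pos")
        except scipy.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(new_beta)):
            return None
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        eta = np.clip(X @ beta + offset, -40.0, 40.0)
        mu = np.exp(eta)
        if delta < tol:
            A = X.T @ (mu[:, None] * X)
            cov = scipy.linalg.inv(A)
            return float(beta[1]), float(np.sqrt(cov[1, 1]))
    return None


def fit_within_tract(panel: pd.DataFrame, tract_id: str,
                     age_group: str = "all") -> TractEstimate:
    """Poisson slope of one tract's yearly deaths on PM2.5.

    Degenerate tracts (fewer than 2 years after filtering, all-zero deaths,
    no exposure contrast, failed fit) are flagged unusable, not errored.
    """
    sub = panel[panel["tract_id"] == tract_id]
    if len(sub) == 0:
        raise ValueError(f"unknown tract: {tract_id!r}")
    if "age_group" in sub.columns:
        sub = sub[sub["age_group"] == age_group]
    sub = sub.sort_values("year")
    y = sub["deaths"].to_numpy(dtype=float)
    x = sub["pm25"].to_numpy(dtype=float)
    if len(sub) < 2:
        return TractEstimate(tract_id, np.nan, np.nan, False, "fewer than 2 years")
    if np.all(y == 0):
        return TractEstimate(tract_id, np.nan, np.nan, False, "all-zero deaths")
    if float(np.ptp(x)) == 0.0:
        return TractEstimate(tract_id, np.nan, np.nan, False, "constant exposure")
    res = _poisson_slope(x, y, np.log(sub["population"].to_numpy(dtype=float)))
    if res is None or not np.isfinite(res[0]) or res[1] <= 0:
        return TractEstimate(tract_id, np.nan, np.nan, False, "fit failed")
    return TractEstimate(tract_id, res[0], res[1], True)


def fit_all_tracts(panel: pd.DataFrame, age_group: str = "all") -> list:
    return [fit_within_tract(panel, t, age_group)
            for t in sorted(panel["tract_id"].unique())]


def pool_dersimonian_laird(estimates, increment: float = 2.0) -> PooledResult:
    """DerSimonian-Laird random-effects pool of per-tract slopes.

    Fixed-effect weights ``w = 1/se^2`` give the heterogeneity statistic
    ``Q = sum w (theta - theta_FE)^2``; the moment estimate
    ``tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w))`` then defines the
    random-effects weights ``1 / (se^2 + tau^2)``.
    """
    usable = [e for e in estimates if e.usable]
    n_excluded = len(estimates) - len(usable)
    if len(usable) < 2:
        raise ValueError(f"need >= 2 usable estimates, got {len(usable)}")
    theta = np.array([e.slope for e in usable])
    var = np.array([e.se ** 2 for e in usable])

    w = 1.0 / var
    theta_fe = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_fe) ** 2))
    df = len(usable) - 1
    denom = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0

    w_re = 1.0 / (var + tau2)
    pooled = float(np.sum(w_re * theta) / np.sum(w_re))
    pooled_se = float(np.sqrt(1.0 / np.sum(w_re)))
    return PooledResult(
        pooled_slope=pooled, pooled_se=pooled_se, tau2=tau2, q_statistic=q,
        n_used=len(usable), n_excluded=n_excluded,
        percent_change_per_iqr=percent_change(pooled, pooled_se, increment),
    )


def meta_analysis(panel: pd.DataFrame, age_group: str = "all",
                  increment: float = 2.0) -> tuple[list, PooledResult]:
    """Per-tract fits plus the pooled result, in one call."""
    estimates = fit_all_tracts(panel, age_group)
    n_bad = sum(not e.usable for e in estimates)
    if n_bad:
        warnings.warn(f"{n_bad} tract(s) excluded from the pool", stacklevel=2)
    return estimates, pool_dersimonian_laird(estimates, increment)
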