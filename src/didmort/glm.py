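"""Quasi-Poisson fixed-effects panel GLM.

Builds the difference-in-differences design — an intercept, indicator
variables for every tract and year but a reference level of each, the PM2.5
exposure, single-knot linear splines of mean summer and winter temperature,
optional exposure x moderator products — and fits it by iteratively
reweighted least squares with a log link and a log-population offset.
Standard errors are scaled by the Pearson dispersion (quasi-likelihood).

Tract and year effects enter as explicit sparse dummy columns, so the fitted
coefficients for every tract and year are directly available and the
estimator is exact (no demeaning / absorption approximation).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import sparse


@dataclass(frozen=True)
class SplineSpec:
    """Single-knot linear spline basis {x, max(0, x - knot)}.

    ``knot=None`` places the knot at the unweighted mean of the variable over
    the records entering the fit.
    """

    variable: str
    knot: float | None = None


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the panel model.

    ``fixed_effects`` says which indicator blocks enter (dropping ``"tract"``
    gives the deliberately mis-specified cross-sectional model used to
    demonstrate confounding).  ``interactions`` lists moderator column names
    to be crossed with the exposure.  A name that matches one of the spline variables expands to
    products with both spline basis columns; any other name is a scalar
    moderator (centered and scaled internally).  Scalar moderators that vary
    within tract also get a main-effect column (tract-constant ones are
    absorbed by the tract dummies).
    """

    exposure: str = "pm25"
    fixed_effects: tuple = ("tract", "year")
    splines: tuple = (SplineSpec("temp_summer"), SplineSpec("temp_winter"))
    interactions: tuple = ()
    offset: str = "population"


def build_spline_basis(x, knot: float | None = None) -> tuple[np.ndarray, float]:
    """Return the (n, 2) single-knot basis and the knot actually used."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in spline input")
    if knot is None:
        knot = float(x.mean())
    return np.column_stack([x, np.maximum(0.0, x - knot)]), float(knot)


@dataclass
class DesignInfo:
    """A realized design: matrix, response, offset and all naming metadata."""

    X: sparse.csr_matrix
    y: np.ndarray
    offset: np.ndarray
    columns: list
    row_keys: pd.DataFrame
    tract_levels: list
    year_levels: list
    ref_tract: str
    ref_year: int
    knots: dict
    moderators: dict       # product column -> evaluation metadata
    moderator_means: dict  # raw moderator variable -> fit-sample mean
    exposure: str
    spec: ModelSpec
    dropped: list = field(default_factory=list)
    flagged: list = field(default_factory=list)


_REQUIRED = ("tract_id", "year", "deaths", "population")


def build_design(panel: pd.DataFrame, spec: ModelSpec | None = None) -> DesignInfo:
    """Build the sparse DiD design from a single-stratum panel.

    Tracts with zero deaths in every year are dropped (their dummy has no
    finite maximum-likelihood estimate) with a warning; tracts observed in a
    single year are retained but flagged.
    """
    spec = spec or ModelSpec()
    if "age_group" in panel.columns:
        groups = panel["age_group"].unique()
        if len(groups) > 1:
            raise ValueError(
                f"panel mixes age groups {sorted(groups)}; filter to one stratum first")
    missing = [c for c in _REQUIRED + (spec.exposure,) if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing column(s): {missing}")

    df = panel.sort_values(["tract_id", "year"]).reset_index(drop=True)
    totals = df.groupby("tract_id")["deaths"].sum()
    dead_tracts = sorted(totals.index[totals == 0])
    dropped = [(t, "all-zero deaths") for t in dead_tracts]
    if dead_tracts:
        warnings.warn(
            f"dropping {len(dead_tracts)} tract(s) with all-zero deaths: "
            f"{dead_tracts[:5]}{'...' if len(dead_tracts) > 5 else ''}",
            stacklevel=2)
        df = df[~df["tract_id"].isin(dead_tracts)].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no records left after dropping all-zero-death tracts")

    n_per = df.groupby("tract_id")["year"].nunique()
    flagged = [(t, "single year") for t in sorted(n_per.index[n_per == 1])]
    if flagged:
        warnings.warn(f"{len(flagged)} tract(s) observed in a single year", stacklevel=2)

    tract_levels = sorted(df["tract_id"].unique())
    year_levels = sorted(df["year"].unique())
    if len(tract_levels) < 2 or len(year_levels) < 2:
        raise ValueError("need at least 2 tracts and 2 years")
    ref_tract, ref_year = tract_levels[0], year_levels[0]
    n = len(df)

    tract_code = df["tract_id"].map({t: i for i, t in enumerate(tract_levels)}).to_numpy()
    year_code = df["year"].map({y: i for i, y in enumerate(year_levels)}).to_numpy()

    def dummies(code, k):
        mask = code > 0
        rows = np.nonzero(mask)[0]
        return sparse.csr_matrix(
            (np.ones(rows.size), (rows, code[mask] - 1)), shape=(n, k - 1))

    columns = ["intercept"]
    parts = [sparse.csr_matrix(np.ones((n, 1)))]
    if "tract" in spec.fixed_effects:
        parts.append(dummies(tract_code, len(tract_levels)))
        columns += [f"tract[{t}]" for t in tract_levels[1:]]
    if "year" in spec.fixed_effects:
        parts.append(dummies(year_code, len(year_levels)))
        columns += [f"year[{y}]" for y in year_levels[1:]]

    expo = df[spec.exposure].to_numpy(dtype=float)
    if not np.all(np.isfinite(expo)):
        raise ValueError(f"non-finite values in exposure column {spec.exposure!r}")
    dense_cols = [expo]
    columns.append(spec.exposure)

    knots = {}
    spline_vars = {}
    for sp in spec.splines:
        if sp.variable not in df.columns:
            raise ValueError(f"spline variable {sp.variable!r} not in panel")
        basis, knot = build_spline_basis(df[sp.variable], sp.knot)
        knots[sp.variable] = knot
        spline_vars[sp.variable] = basis
        dense_cols += [basis[:, 0], basis[:, 1]]
        columns += [sp.variable, f"{sp.variable}_hinge"]

    moderators = {}
    moderator_means = {}
    main_cols, main_names, prod_cols, prod_names = [], [], [], []
    for name in spec.interactions:
        if name in spline_vars:
            basis = spline_vars[name]
            for j, suffix in enumerate(("", "_hinge")):
                col = basis[:, j]
                mean, sd = float(col.mean()), float(col.std())
                if sd <= 0:
                    raise ValueError(f"moderator basis column {name}{suffix} is constant")
                pname = f"{spec.exposure}:{name}{suffix}"
                prod_cols.append(expo * (col - mean) / sd)
                prod_names.append(pname)
                moderators[pname] = {
                    "var": name, "kind": "spline_hinge" if j else "spline_base",
                    "knot": knots[name], "mean": mean, "sd": sd,
                }
            moderator_means[name] = float(df[name].mean())
        else:
            if name not in df.columns:
                raise ValueError(f"moderator {name!r} not in panel")
            col = df[name].to_numpy(dtype=float)
            if not np.all(np.isfinite(col)):
                raise ValueError(f"non-finite values in moderator {name!r}")
            mean, sd = float(col.mean()), float(col.std())
            if sd <= 0:
                raise ValueError(f"moderator {name!r} is constant")
            std = (col - mean) / sd
            within = df.assign(_m=std).groupby("tract_id")["_m"].var(ddof=0)
            if float(within.max()) > 1e-12:
                # time-varying moderator: tract dummies do not absorb it
                main_cols.append(std)
                main_names.append(name)
            pname = f"{spec.exposure}:{name}"
            prod_cols.append(expo * std)
            prod_names.append(pname)
            moderators[pname] = {"var": name, "kind": "scalar",
                                 "knot": None, "mean": mean, "sd": sd}
            moderator_means[name] = mean
    dense_cols += main_cols + prod_cols
    columns += main_names + prod_names

    if len(set(columns)) != len(columns):
        raise ValueError("duplicated terms in design")
    parts.append(sparse.csr_matrix(np.column_stack(dense_cols)))
    X = sparse.hstack(parts, format="csr")

    y = df["deaths"].to_numpy(dtype=float)
    pop = df["population"].to_numpy(dtype=float)
    if np.any(pop <= 0):
        raise ValueError("non-positive population")
    return DesignInfo(
        X=X, y=y, offset=np.log(pop), columns=columns,
        row_keys=df[["tract_id", "year"]].copy(),
        tract_levels=tract_levels, year_levels=year_levels,
        ref_tract=ref_tract, ref_year=ref_year,
        knots=knots, moderators=moderators, moderator_means=moderator_means,
        exposure=spec.exposure, spec=spec, dropped=dropped, flagged=flagged,
    )


@dataclass
class FitResult:
    """Coefficients, quasi-likelihood covariance and fit diagnostics."""

    params: pd.Series
    vcov: pd.DataFrame
    vcov_unscaled: pd.DataFrame
    dispersion: float
    fitted_means: np.ndarray
    n_obs: int
    n_params: int
    residual_df: int
    converged: bool
    n_iterations: int
    dropped_records: list
    design: DesignInfo

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.params.index)

    def coef_table(self) -> pd.DataFrame:
        from scipy import stats
        se = self.se()
        z = self.params / se
        return pd.DataFrame({
            "term": self.params.index,
            "estimate": self.params.to_numpy(),
            "se": se.to_numpy(),
            "z": z.to_numpy(),
            "p": 2.0 * stats.norm.sf(np.abs(z.to_numpy())),
        }).reset_index(drop=True)


def _name_rank_deficiency(A: np.ndarray, columns: list) -> list:
    _, r, piv = scipy.linalg.qr(A, pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(A.shape) * np.finfo(float).eps
    rank = int((d > tol).sum())
    return [columns[j] for j in piv[rank:]]


def fit_quasipoisson(design: DesignInfo, tol: float = 1e-8,
                     max_iter: int = 100) -> FitResult:
    """Fit the Poisson log-likelihood by IRLS; scale the covariance by the
    Pearson dispersion.

    Convergence is declared when the largest absolute coefficient change
    falls below ``tol``.  A saturated fit (zero residual degrees of freedom)
    succeeds with an undefined (NaN) dispersion and unscaled covariance,
    with a warning.  Non-convergence returns a flagged partial result.
    """
    X, y, off = design.X, design.y, design.offset
    n, p = X.shape
    if n < p:
        raise ValueError(f"more parameters ({p}) than observations ({n})")

    mu = y + 0.5
    eta = np.log(mu)
    beta = np.zeros(p)
    converged = False
    it = 0
    A = None
    for it in range(1, max_iter + 1):
        w = mu
        z = (eta - off) + (y - mu) / mu
        WX = X.multiply(w[:, None]).tocsr()
        A = np.asarray((X.T @ WX).todense())
        rhs = X.T @ (w * z)
        try:
            new_beta = scipy.linalg.solve(A, rhs, assume_a="pos")
        except scipy.linalg.LinAlgError:
            offending = _name_rank_deficiency(A, design.columns)
            raise ValueError(
                f"design is rank deficient; offending column(s): {offending}") from None
        if not np.all(np.isfinite(new_beta)):
            raise ValueError("IRLS produced non-finite coefficients")
        delta = float(np.max(np.abs(new_beta - beta)))
        beta = new_beta
        eta = np.clip(X @ beta + off, -40.0, 40.0)
        mu = np.exp(eta)
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"IRLS did not converge in {max_iter} iterations "
                      f"(last max coefficient change {delta:.3g})", stacklevel=2)

    # exact Fisher information at the final coefficients
    WX = X.multiply(mu[:, None]).tocsr()
    A = np.asarray((X.T @ WX).todense())
    try:
        cov_unscaled = scipy.linalg.inv(A)
    except scipy.linalg.LinAlgError:
        offending = _name_rank_deficiency(A, design.columns)
        raise ValueError(
            f"design is rank deficient; offending column(s): {offending}") from None

    residual_df = n - p
    pearson = float(np.sum((y - mu) ** 2 / mu))
    if residual_df > 0:
        dispersion = pearson / residual_df
        cov = dispersion * cov_unscaled
    else:
        warnings.warn(
            "saturated model: dispersion undefined; reporting unscaled "
            "(phi = 1) standard errors", stacklevel=2)
        dispersion = float("nan")
        cov = cov_unscaled.copy()

    idx = pd.Index(design.columns)
    return FitResult(
        params=pd.Series(beta, index=idx),
        vcov=pd.DataFrame(cov, index=idx, columns=idx),
        vcov_unscaled=pd.DataFrame(cov_unscaled, index=idx, columns=idx),
        dispersion=dispersion,
        fitted_means=mu,
        n_obs=n, n_params=p, residual_df=residual_df,
        converged=converged, n_iterations=it,
        dropped_records=list(design.dropped),
        design=design,
    )


def fit_panel(panel: pd.DataFrame, spec: ModelSpec | None = None,
              **options) -> FitResult:
    """Convenience: build the design and fit in one call."""
    return fit_quasipoisson(build_design(panel, spec), **options)


def predict_mean(fit: FitResult, records: pd.DataFrame) -> np.ndarray:
    """Expected counts for new records at the fitted coefficients.

    Records must reference tracts and years seen in the fit; an unknown level
    raises an error naming it.  Spline knots and moderator centers are the
    ones frozen at fit time.
    """
    d = fit.design
    spec = d.spec
    df = records
    beta = fit.params

    eta = np.full(len(df), beta["intercept"], dtype=float)
    for t in df["tract_id"]:
        if t not in d.tract_levels:
            raise ValueError(f"unknown tract level: {t!r}")
    for y in df["year"]:
        if y not in d.year_levels:
            raise ValueError(f"unknown year level: {y!r}")
    tmap = {t: (beta[f"tract[{t}]"] if t != d.ref_tract else 0.0) for t in d.tract_levels}
    ymap = {y: (beta[f"year[{y}]"] if y != d.ref_year else 0.0) for y in d.year_levels}
    eta += df["tract_id"].map(tmap).to_numpy(dtype=float)
    eta += df["year"].map(ymap).to_numpy(dtype=float)

    expo = df[spec.exposure].to_numpy(dtype=float)
    eta += beta[spec.exposure] * expo
    for sp in spec.splines:
        basis, _ = build_spline_basis(df[sp.variable], d.knots[sp.variable])
        eta += beta[sp.variable] * basis[:, 0] + beta[f"{sp.variable}_hinge"] * basis[:, 1]
    for pname, info in d.moderators.items():
        v = df[info["var"]].to_numpy(dtype=float)
        raw = np.maximum(0.0, v - info["knot"]) if info["kind"] == "spline_hinge" else v
        std = (raw - info["mean"]) / info["sd"]
        if info["kind"] == "scalar" and info["var"] in beta.index:
            eta += beta[info["var"]] * std
        eta += beta[pname] * expo * std
    eta += np.log(df["population"].to_numpy(dtype=float))
    return np.exp(eta)
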