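"""Panel readers/writers, the ground-truth sidecar format, and descriptive
summaries of a panel (tract-level distribution and yearly means)."""
from __future__ import annotations

import configparser
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import MODIFIER_COLUMNS, PANEL_COLUMNS, SimulationTruth

REQUIRED_COLUMNS = ("tract_id", "year", "age_group", "deaths", "population",
                    "pm25", "temp_summer", "temp_winter")


def read_panel(path) -> pd.DataFrame:
    """Read a panel CSV, validate it, and return it in canonical row order.

    Rejects missing required columns (naming them), duplicated
    (tract, year, age_group) keys, non-integer death counts, and rows where
    deaths exceed population.  Row order of the input file is immaterial.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {missing}")

    deaths = df["deaths"].to_numpy()
    frac = np.asarray(deaths, dtype=float) % 1.0
    if np.any(frac != 0):
        row = int(np.nonzero(frac != 0)[0][0])
        raise ValueError(f"non-integer deaths at row {row + 2} (1-based, with header)")
    df["deaths"] = df["deaths"].astype(int)
    df["population"] = df["population"].astype(int)
    df["year"] = df["year"].astype(int)

    over = df.index[df["deaths"] > df["population"]]
    if len(over):
        raise ValueError(f"deaths exceed population at row {int(over[0]) + 2} "
                         f"(1-based, with header)")
    dup = df.duplicated(subset=["tract_id", "year", "age_group"], keep=False)
    if dup.any():
        key = df.loc[dup.idxmax(), ["tract_id", "year", "age_group"]].tolist()
        raise ValueError(f"duplicate (tract, year, age_group) key: {tuple(key)}")

    df = df.sort_values(["tract_id", "year", "age_group"], ignore_index=True)
    cols = [c for c in PANEL_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    return df[cols]


def write_panel(panel: pd.DataFrame, path) -> None:
    """Write a panel CSV in canonical column and row order."""
    df = panel.sort_values(["tract_id", "year", "age_group"], ignore_index=True)
    cols = [c for c in PANEL_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ground-truth sidecar (key-value text, one mapping per section)
# ---------------------------------------------------------------------------

def write_truth(truth: SimulationTruth, path) -> None:
    cp = configparser.ConfigParser()
    cp.optionxform = str
    cp["scalars"] = {"beta1": repr(truth.beta1),
                     "dispersion": repr(truth.dispersion),
                     "seed": str(truth.seed)}
    cp["beta1_by_age"] = {k: repr(v) for k, v in truth.beta1_by_age.items()}
    cp["tract_effects"] = {k: repr(v) for k, v in truth.tract_effects.items()}
    cp["year_effects"] = {str(k): repr(v) for k, v in truth.year_effects.items()}
    cp["temp_coefficients"] = {k: f"{v[0]!r},{v[1]!r}"
                               for k, v in truth.temp_coefficients.items()}
    cp["knots"] = {k: repr(v) for k, v in truth.knots.items()}
    cp["interaction_coeffs"] = {k: repr(v) for k, v in truth.interaction_coeffs.items()}
    cp["modifier_means"] = {k: repr(v) for k, v in truth.modifier_means.items()}
    cp["linear_predictors"] = {f"{t}|{y}|{a}": repr(v)
                               for (t, y, a), v in truth.linear_predictors.items()}
    with open(path, "w") as fh:
        cp.write(fh)


def read_truth(path) -> SimulationTruth:
    cp = configparser.ConfigParser()
    cp.optionxform = str
    with open(path) as fh:
        cp.read_file(fh)
    lps = {}
    for key, val in cp["linear_predictors"].items():
        t, y, a = key.split("|")
        lps[(t, int(y), a)] = float(val)
    return SimulationTruth(
        beta1=float(cp["scalars"]["beta1"]),
        beta1_by_age={k: float(v) for k, v in cp["beta1_by_age"].items()},
        tract_effects={k: float(v) for k, v in cp["tract_effects"].items()},
        year_effects={int(k): float(v) for k, v in cp["year_effects"].items()},
        temp_coefficients={k: tuple(float(x) for x in v.split(","))
                           for k, v in cp["temp_coefficients"].items()},
        knots={k: float(v) for k, v in cp["knots"].items()},
        dispersion=float(cp["scalars"]["dispersion"]),
        interaction_coeffs={k: float(v) for k, v in cp["interaction_coeffs"].items()},
        modifier_means={k: float(v) for k, v in cp["modifier_means"].items()},
        seed=int(cp["scalars"]["seed"]),
        linear_predictors=lps,
    )


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

_PCTS = (5, 25, 50, 75, 95)


@dataclass
class PanelSummary:
    """Tract-level distribution of study variables, yearly means, and totals."""

    tract_table: pd.DataFrame   # per-variable mean and percentiles of tract means
    yearly_mean: pd.DataFrame   # variable x year means across tracts
    yearly_sd: pd.DataFrame
    totals: dict

    def __str__(self):
        lines = ["Tract-level distribution (mean of tract-specific means):",
                 self.tract_table.round(2).to_string(), "",
                 "Yearly means across tracts:",
                 self.yearly_mean.round(2).to_string(), ""]
        t = self.totals
        lines.append(f"Total deaths: {t['total_deaths']:,}")
        if "deaths_gt65" in t:
            lines.append(f"Deaths at ages > 65: {t['deaths_gt65']:,} "
                         f"({t['over65_share_pct']}% of the total)")
        return "\n".join(lines)


def _tract_stats(series_by_tract: pd.Series) -> list:
    vals = series_by_tract.to_numpy(dtype=float)
    return [float(vals.mean())] + [float(np.percentile(vals, p)) for p in _PCTS]


def summarize_panel(panel: pd.DataFrame) -> PanelSummary:
    """Descriptive tables: per-variable mean and 5/25/50/75/95th percentiles of
    tract-specific means, yearly means +/- SD across tracts, and death totals
    (with the over-65 share as a rounded percent).

    Percentiles use linear interpolation between order statistics.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    groups = [g for g in ("all", "gt65", "le65") if g in set(panel["age_group"])]

    rows, names = [], []
    for g in groups:
        sub = panel[panel["age_group"] == g]
        per_tract = sub.groupby("tract_id").agg(
            deaths=("deaths", "mean"), population=("population", "mean"))
        rate = sub.assign(rate=1000.0 * sub["deaths"] / sub["population"]) \
                  .groupby("tract_id")["rate"].mean()
        rows.append(_tract_stats(per_tract["deaths"]))
        names.append(f"deaths_per_year ({g})")
        rows.append(_tract_stats(rate))
        names.append(f"mortality_rate_per_1000 ({g})")
        rows.append(_tract_stats(per_tract["population"]))
        names.append(f"population ({g})")
    base = panel[panel["age_group"] == groups[0]]
    for var in ("pm25", "temp_summer", "temp_winter"):
        if var in base.columns:
            rows.append(_tract_stats(base.groupby("tract_id")[var].mean()))
            names.append(var)
    tract_table = pd.DataFrame(
        rows, index=names, columns=["mean"] + [f"p{p}" for p in _PCTS])

    yearly_vars = ["deaths", "pm25", "temp_summer", "temp_winter"]
    ym = base.groupby("year")[[v for v in yearly_vars if v in base.columns]].mean().T
    ys = base.groupby("year")[[v for v in yearly_vars if v in base.columns]].std().T

    totals = {"total_deaths": int(base["deaths"].sum())}
    if "gt65" in groups:
        gt = int(panel.loc[panel["age_group"] == "gt65", "deaths"].sum())
        totals["deaths_gt65"] = gt
        totals["over65_share_pct"] = int(round(100.0 * gt / totals["total_deaths"]))
    return PanelSummary(tract_table=tract_table, yearly_mean=ym, yearly_sd=ys,
                        totals=totals)
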