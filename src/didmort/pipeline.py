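"""End-to-end analysis runs: simulate or read a panel, summarize, fit the
difference-in-differences model, compute effects and interaction tests,
optionally run backward elimination and the within-tract meta-analysis, and
write every result table plus a plain-text report to an output directory."""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from .effects import (default_setting, modifier_effect_table, run_stratified,
                      temperature_effect_table)
from .glm import ModelSpec, SplineSpec, build_design, fit_quasipoisson
from .meta import meta_analysis
from .selection import backward_eliminate
from .simulate import ScenarioConfig, generate_panel

log = logging.getLogger("didmort")


@dataclass
class RunConfig:
    """One analysis run: exactly one of ``input_path`` / ``scenario``."""

    scenario: ScenarioConfig | None = None
    input_path: str | None = None
    outdir: str = "didmort_out"
    seed: int = 0
    increment: float = 2.0
    strata: tuple = ("all", "gt65", "le65")
    temperature_interactions: bool = True
    modifier_interactions: tuple = ()
    selection_candidates: tuple = ()
    run_meta: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.scenario is None) == (self.input_path is None):
            raise ValueError("provide exactly one of scenario / input_path")
        if self.increment <= 0:
            raise ValueError("increment must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scenario = raw.pop("scenario", None)
        if scenario is not None:
            scenario = ScenarioConfig(**{
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in scenario.items()})
        for key in ("strata", "modifier_interactions", "selection_candidates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(scenario=scenario, **raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        if self.scenario is not None:
            data["scenario"] = dataclasses.asdict(self.scenario)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False, default_flow_style=None)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the in-memory results and writes
    every table under ``config.outdir``.  Deterministic given config + seed."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    results: dict = {}
    try:
        config.to_yaml(out / "config_echo.yaml")

        if config.scenario is not None:
            scenario = replace(config.scenario, seed=config.seed)
            log.info("simulating panel: %d tracts x %d years, seed %d",
                     scenario.n_tracts, scenario.n_years, config.seed)
            panel, truth = generate_panel(scenario)
            dio.write_panel(panel, out / "panel.csv")
            dio.write_truth(truth, out / "truth.cfg")
            results["truth"] = truth
        else:
            log.info("reading panel from %s", config.input_path)
            panel = dio.read_panel(config.input_path)
        results["panel"] = panel

        summary = dio.summarize_panel(panel)
        summary.tract_table.to_csv(out / "table_tracts.csv")
        summary.yearly_mean.to_csv(out / "table_yearly_mean.csv")
        (out / "summary.txt").write_text(str(summary) + "\n")
        results["summary"] = summary

        spec = ModelSpec()
        log.info("fitting stratified DiD models: %s", config.strata)
        strat = run_stratified(panel, spec, strata=config.strata,
                               increment=config.increment)
        results["stratified"] = strat
        report = ["Percent change in mortality per "
                  f"{config.increment:g} ug/m3 PM2.5 (DiD fit):"]
        for stratum, (est, fit) in strat.items():
            fit.coef_table().to_csv(out / f"coefficients_{stratum}.csv", index=False)
            report.append(f"  {stratum:>5}: {est}   "
                          f"[dispersion {fit.dispersion:.2f}, "
                          f"{'converged' if fit.converged else 'NOT converged'}]")

        if config.temperature_interactions and "all" in dict(strat):
            log.info("fitting temperature-interaction model")
            ispec = replace(spec, interactions=("temp_summer", "temp_winter"))
            ifit = fit_quasipoisson(build_design(
                panel[panel["age_group"] == "all"], ispec))
            ttab = temperature_effect_table(ifit, config.increment)
            ttab.to_csv(out / "effects_temperature.csv", index=False)
            results["temperature_effects"] = ttab
            report.append("\nConditional effects at seasonal-temperature settings "
                          "written to effects_temperature.csv")

        if config.modifier_interactions:
            rows = []
            sub = panel[panel["age_group"] == "all"]
            for mod in config.modifier_interactions:
                log.info("modifier interaction: %s", mod)
                mspec = replace(spec, interactions=(mod,))
                mfit = fit_quasipoisson(build_design(sub, mspec))
                lo, hi = sub[mod].quantile([0.1, 0.9])
                est_lo, est_hi, test = modifier_effect_table(
                    mfit, mod, float(lo), float(hi), config.increment)
                for decile, est in (("p10", est_lo), ("p90", est_hi)):
                    rows.append({"modifier": mod, "decile": decile,
                                 "value": est.setting[mod],
                                 "percent_change": est.percent_change,
                                 "ci_low": est.ci_low, "ci_high": est.ci_high,
                                 "interaction_p": test.p_value})
            mtab = pd.DataFrame(rows)
            mtab.to_csv(out / "effects_modifiers.csv", index=False)
            results["modifier_effects"] = mtab

        if config.selection_candidates:
            log.info("backward elimination over %s", config.selection_candidates)
            trace = backward_eliminate(panel[panel["age_group"] == "all"], spec,
                                       config.selection_candidates)
            trace.as_frame().to_csv(out / "selection_trace.csv", index=False)
            if trace.final_fit is not None:
                trace.final_fit.coef_table().to_csv(
                    out / "selection_final_coefficients.csv", index=False)
            results["selection"] = trace
            report.append(f"\nBackward elimination retained: "
                          f"{sorted(trace.final_terms) or 'none'}")

        if config.run_meta:
            log.info("within-tract meta-analysis")
            estimates, pooled = meta_analysis(panel, increment=config.increment)
            pd.DataFrame([dataclasses.asdict(e) for e in estimates]).to_csv(
                out / "meta_tract_estimates.csv", index=False)
            (out / "meta_summary.txt").write_text(
                f"pooled slope: {pooled.pooled_slope!r}\n"
                f"pooled se: {pooled.pooled_se!r}\n"
                f"tau2: {pooled.tau2!r}\nQ: {pooled.q_statistic!r}\n"
                f"n_used: {pooled.n_used}\nn_excluded: {pooled.n_excluded}\n"
                f"percent change per IQR: {pooled.percent_change_per_iqr}\n")
            results["meta"] = pooled
            report.append(f"\nWithin-tract meta-analysis: "
                          f"{pooled.percent_change_per_iqr} "
                          f"(tau2 {pooled.tau2:.4g}, Q {pooled.q_statistic:.1f}, "
                          f"{pooled.n_used} tracts)")

        (out / "report.txt").write_text("\n".join(report) + "\n")
        results["report"] = "\n".join(report)
        log.info("done; outputs in %s", out)
    finally:
        log.removeHandler(handler)
        handler.close()
    return results
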