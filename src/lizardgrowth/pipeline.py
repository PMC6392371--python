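"""End-to-end analysis pipeline: intervals -> fits -> curves -> summaries -> correlations.

Stages compose through documented CSV schemas so they can run as one call
(:func:`run_full_analysis`) or as individual command-line steps.  Inputs are
either real capture/prey/climate tables or a simulate block; every run
writes a manifest recording the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

import lizardgrowth

from .errors import AlignmentError, ConvergenceError, SchemaError
from .fit import compare_models, fit_all_families
from .life_history import (
    DEFAULT_MATURITY_RULES,
    age_at_maturity,
    anova_growth,
    build_growth_curve,
    correlate_growth_env,
    monthly_growth_series,
    summarize_groups,
)
from .prey import monthly_env_table, read_climate, read_prey
from .records import extract_intervals, read_captures, write_intervals
from .simulate import EnvConfig, SimConfig, simulate_capture_recapture, simulate_env

__all__ = ["PipelineConfig", "run_fit", "run_full_analysis"]

DEFAULT_L0 = 22.1
ENV_COVARIATES = ["prey_count", "prey_categories", "temp_c", "precip_mm"]


@dataclasses.dataclass
class PipelineConfig:
    """Where the data come from and how the analysis is parameterised."""

    captures: str | None = None
    prey: str | None = None
    climate: str | None = None
    simulate: bool = False
    seed: int | None = None
    l0: float = DEFAULT_L0
    maturity_svl: dict | None = None  # sex -> mm
    window: tuple[int, int] = (30, 100)
    out_dir: str = "results"
    sim_overrides: dict = dataclasses.field(default_factory=dict)
    env_overrides: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.simulate and self.captures is None:
            raise ValueError("config needs input paths or simulate=true")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        return cls(**raw)


def _load_or_simulate(config: PipelineConfig):
    if config.simulate:
        sim = SimConfig(seed=config.seed, **config.sim_overrides)
        _, captures = simulate_capture_recapture(sim)
        env_seed = None if config.seed is None else config.seed + 1
        env = EnvConfig(seed=env_seed, **config.env_overrides)
        prey, climate = simulate_env(env)
        return captures, prey, climate
    captures = read_captures(config.captures)
    prey = read_prey(config.prey) if config.prey else None
    climate = read_climate(config.climate) if config.climate else None
    return captures, prey, climate


def _write_manifest(config: PipelineConfig, out_dir: Path, outputs: list[str]) -> None:
    manifest = {
        "package": "lizardgrowth",
        "version": lizardgrowth.__version__,
        "config": dataclasses.asdict(config),
        "outputs": sorted(outputs),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_fit(config: PipelineConfig, strict: bool = True) -> dict:
    """Fit all three families per sex and select the best; write the report.

    Returns ``{sex: ModelComparison}``.  With ``strict`` a non-converged
    selected fit raises :class:`ConvergenceError` (mapped to exit code 3).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    captures, _, _ = _load_or_simulate(config)
    intervals = extract_intervals(captures, window=config.window)
    write_intervals(intervals, out_dir / "intervals.csv")
    rows, comparisons = [], {}
    for sex, sub in intervals.groupby("sex"):
        if len(sub) < 3:
            continue
        fits = fit_all_families(sub)
        comp = compare_models(fits)
        comparisons[sex] = comp
        rows.extend(f.to_row(sex=sex) for f in fits)
        if strict and not comp.best.converged:
            pd.DataFrame(rows).to_csv(out_dir / "fit_report.csv", index=False)
            raise ConvergenceError(f"selected fit for {sex} did not converge")
    report = pd.DataFrame(rows)
    report.to_csv(out_dir / "fit_report.csv", index=False)
    selected = pd.DataFrame(
        [{"sex": sex, "selected_family": comp.selected.value} for sex, comp in comparisons.items()]
    )
    selected.to_csv(out_dir / "selected_models.csv", index=False)
    _write_manifest(config, out_dir, ["intervals.csv", "fit_report.csv", "selected_models.csv"])
    return comparisons


def run_full_analysis(config: PipelineConfig) -> dict:
    """The whole chain: fits, growth curves, maturity ages, group summaries,
    ANOVA contrasts and growth--environment correlations, all written as CSV.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    captures, prey, climate = _load_or_simulate(config)
    intervals = extract_intervals(captures, window=config.window)
    write_intervals(intervals, out_dir / "intervals.csv")
    outputs = ["intervals.csv", "fit_report.csv", "selected_models.csv"]

    rows, comparisons = [], {}
    for sex, sub in intervals.groupby("sex"):
        if len(sub) < 3:
            continue
        fits = fit_all_families(sub)
        comp = compare_models(fits)
        comparisons[sex] = comp
        rows.extend(f.to_row(sex=sex) for f in fits)
    pd.DataFrame(rows).to_csv(out_dir / "fit_report.csv", index=False)
    pd.DataFrame(
        [{"sex": sex, "selected_family": comp.selected.value} for sex, comp in comparisons.items()]
    ).to_csv(out_dir / "selected_models.csv", index=False)

    # growth curves and maturity ages from the selected model per sex
    maturity_rules = config.maturity_svl or {
        sex: rule.svl_at_maturity for sex, rule in DEFAULT_MATURITY_RULES.items()
    }
    curve_frames, maturity_rows = [], []
    for sex, comp in comparisons.items():
        best = comp.best
        if not best.converged or config.l0 >= best.a1:
            continue
        curve = build_growth_curve(best, config.l0)
        horizon = curve.time_to_length(0.99 * best.a1)
        tab = curve.to_frame(t_max=horizon, step=5.0)
        tab.insert(0, "sex", sex)
        curve_frames.append(tab)
        svl = maturity_rules.get(sex)
        if svl is not None and config.l0 < svl < best.a1:
            days = age_at_maturity(curve, svl)
            maturity_rows.append(
                {
                    "sex": sex,
                    "family": best.family.value,
                    "maturity_svl_mm": svl,
                    "age_days": days,
                    "age_months": days / 30.0,
                }
            )
    if curve_frames:
        pd.concat(curve_frames, ignore_index=True).to_csv(out_dir / "growth_curves.csv", index=False)
        outputs.append("growth_curves.csv")
    pd.DataFrame(maturity_rows).to_csv(out_dir / "maturity.csv", index=False)
    outputs.append("maturity.csv")

    summarize_groups(intervals).to_csv(out_dir / "group_summary.csv", index=False)
    outputs.append("group_summary.csv")

    anova_rows = []
    for factor in ("sex", "season", "year", "age_class"):
        if intervals[factor].nunique() < 2:
            continue
        for res in anova_growth(intervals, [factor]):
            anova_rows.append(
                {
                    "factor": res.factor,
                    "f_stat": res.f_stat,
                    "df_num": res.df[0],
                    "df_den": res.df[1],
                    "p_value": res.p_value,
                }
            )
    pd.DataFrame(anova_rows).to_csv(out_dir / "anova.csv", index=False)
    outputs.append("anova.csv")

    if prey is not None and climate is not None:
        monthly_gr = monthly_growth_series(intervals)
        env = monthly_env_table(prey, climate)
        merged = monthly_gr.merge(env, on=["year", "month"], how="inner")
        merged = merged[merged["complete"]]
        if len(merged) < 3:
            raise AlignmentError(
                "fewer than 3 months where growth and environmental series overlap"
            )
        corr_rows = []
        for cov in ENV_COVARIATES:
            res = correlate_growth_env(merged["mean_gr"], merged[cov], covariate=cov)
            corr_rows.append(
                {"covariate": cov, "r": res.coefficient, "n": res.n, "p_value": res.p_value}
            )
        pd.DataFrame(corr_rows).to_csv(out_dir / "correlations.csv", index=False)
        outputs.append("correlations.csv")

    _write_manifest(config, out_dir, outputs)
    return {
        "comparisons": comparisons,
        "maturity": maturity_rows,
        "outputs": outputs,
    }
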