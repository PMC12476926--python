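"""End-to-end orchestration: simulate -> ITV -> models -> report.

Stages communicate through the CSV/JSON schemas defined by the library
modules, so each stage can also be run standalone from the command
line.  A run directory is self-describing: it holds a verbatim copy of
the configuration, the simulated (or supplied) inputs, every
intermediate table, and — when data were simulated — the truth record.
All outputs are deterministic given the configuration and seed.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from itvar import itv as itv_mod
from itvar.hierarchical import HierarchicalITV, HierModelSpec
from itvar.ranges import (
    DEFAULT_PREDICTORS,
    RangeRegression,
    backward_select,
    build_range_design,
    mean_itv_correlation,
    mean_trait_response,
)
from itvar.env import species_ranges
from itvar.simulate import (
    CoupledConfig,
    SimulationConfig,
    _rng,
    scenario_config,
    simulate_coupled_itv_range,
    simulate_traits,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"  # fixed format so reruns are byte-identical


def _derive_seed(master: int, label: str) -> int:
    """Stable (hash-randomization-proof) per-stage seed below 2**31."""
    key = zlib.crc32(label.encode())
    return int(
        np.random.SeedSequence(master, spawn_key=(key,)).generate_state(1)[0] % 2**31
    )


def packaged_site_table() -> pd.DataFrame:
    """The packaged eight-site environment table (MAP, geology,
    elevation, rainfall CV %, mean terrain roughness)."""
    with resources.files("itvar").joinpath("data/table1_sites.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass
class PipelineConfig:
    """Everything a full run needs; serialized verbatim into the run dir."""

    scenario: str | None = "paper_scale"
    traits_csv: str | None = None
    sites_csv: str | None = None
    occurrences_csv: str | None = None
    min_sites: int = 4
    min_per_site: int = 6
    env_variables: tuple[str, ...] = ("terrain_roughness", "rainfall_cv")
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    chains: int = 4
    iterations: int = 2000
    error_scaling: str = "sd_over_n"
    ci_levels: tuple[float, ...] = (0.90, 0.95)
    reg_draws: int = 2000
    save_draws: bool = False
    seed: int = 0
    out_dir: str = "runs/itvar"

    def __post_init__(self):
        if self.scenario is None and self.traits_csv is None:
            raise ValueError("need either a scenario or a traits_csv input")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("env_variables", "predictors", "ci_levels"):
            d[key] = list(d[key])
        return d

    def write(self, out: Path) -> None:
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def simulate_stage(config: PipelineConfig) -> Path:
    """Generate inputs for the configured scenario into the run directory."""
    out = Path(config.out_dir)
    config.write(out)
    scen = scenario_config(config.scenario, seed=config.seed)
    if isinstance(scen, CoupledConfig):
        observations, occurrences, truth = simulate_coupled_itv_range(scen)
        occurrences.to_csv(out / "occurrences.csv", index=False, float_format=_FLOAT_FMT)
        truth_json = {
            "config": truth["config"],
            "true_ranges": _jsonable(truth["true_ranges"]),
            "response": _jsonable(truth["response"]),
            "coefficients": _jsonable(truth["coefficients"]),
        }
        sites = pd.DataFrame(
            {
                "site": sorted(observations["site"].unique()),
            }
        )
    else:
        assert isinstance(scen, SimulationConfig)
        observations, truth = simulate_traits(scen)
        truth_json = _jsonable(truth.to_dict())
        # the generative env predictor is exposed as terrain roughness;
        # rainfall CV is an independent site property (no true effect)
        rng = _rng(config.seed, "env")
        sites = truth.env.rename(columns={"env": "terrain_roughness"}).copy()
        sites["rainfall_cv"] = np.round(rng.uniform(25.0, 60.0, size=len(sites)), 2)
        if config.scenario == "paper_scale":
            from itvar.simulate import OccurrenceConfig, simulate_occurrences

            occ, occ_truth = simulate_occurrences(
                OccurrenceConfig(n_species=scen.n_species, seed=config.seed)
            )
            occ.to_csv(out / "occurrences.csv", index=False, float_format=_FLOAT_FMT)
            truth_json["occurrence_ranges"] = _jsonable(occ_truth)
    observations.to_csv(out / "traits.csv", index=False, float_format=_FLOAT_FMT)
    sites.to_csv(out / "sites.csv", index=False, float_format=_FLOAT_FMT)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_json, fh, sort_keys=True, indent=1)
    logger.info("simulated scenario %s: %d observations", config.scenario, len(observations))
    return out


def itv_stage(config: PipelineConfig) -> Path:
    """Filter observations and write within-/across-site ITV* tables."""
    out = Path(config.out_dir)
    traits_path = config.traits_csv or out / "traits.csv"
    observations = itv_mod.read_trait_table(traits_path)
    kept, report = itv_mod.filter_included(
        observations, min_sites=config.min_sites, min_per_site=config.min_per_site
    )
    within, across = itv_mod.itv_table(kept)
    within.to_csv(out / "itv_within.csv", index=False, float_format=_FLOAT_FMT)
    across.to_csv(out / "itv_across.csv", index=False, float_format=_FLOAT_FMT)
    kept.to_csv(out / "traits_included.csv", index=False, float_format=_FLOAT_FMT)
    with open(out / "filter_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, sort_keys=True, indent=1)
    return out


def run_h1(config: PipelineConfig) -> dict:
    """Fit the hierarchical model per trait x environmental variable.

    Writes a posterior summary and a species-slope classification per
    fit; returns ``{(trait, env_var): results}``.
    """
    out = Path(config.out_dir)
    within = pd.read_csv(out / "itv_within.csv")
    sites = pd.read_csv(config.sites_csv or out / "sites.csv")
    results = {}
    for trait in sorted(within["trait"].unique()):
        sub = within[within["trait"] == trait]
        for env_var in config.env_variables:
            if env_var not in sites.columns:
                logger.warning("site table lacks %s; skipping", env_var)
                continue
            spec = HierModelSpec(
                env_variable=env_var,
                chains=config.chains,
                iterations=config.iterations,
                seed=_derive_seed(config.seed, f"{trait}:{env_var}"),
                error_scaling=config.error_scaling,
            )
            model = HierarchicalITV.from_frames(sub, sites, env_var)
            res = model.fit(spec)
            tag = f"{trait}_{env_var}"
            res.summary().reset_index().to_csv(
                out / f"posterior_summary_{tag}.csv", index=False, float_format=_FLOAT_FMT
            )
            res.classify_slopes(0.95).to_csv(
                out / f"species_slopes_{tag}.csv", index=False, float_format=_FLOAT_FMT
            )
            if config.save_draws:
                res.draws_frame().to_csv(
                    out / f"draws_{tag}.csv", index=False, float_format=_FLOAT_FMT
                )
            results[(trait, env_var)] = res
            logger.info(
                "H1 %s: mu2 = %.3f [%.3f, %.3f]",
                tag,
                res.posterior_mean("mu2"),
                *res.credible_interval("mu2", 0.95),
            )
    return results


def run_h2(config: PipelineConfig) -> dict:
    """Range regressions per trait: ITV response, mean-trait response,
    AIC backward selection, VIF, and the mean-ITV Pearson correlation."""
    out = Path(config.out_dir)
    across = pd.read_csv(out / "itv_across.csv")
    occ_path = config.occurrences_csv or out / "occurrences.csv"
    if not Path(occ_path).exists():
        logger.warning("no occurrence data; skipping H2")
        return {}
    occurrences = pd.read_csv(occ_path)
    ranges = species_ranges(occurrences)
    ranges.to_csv(out / "species_ranges.csv", index=False, float_format=_FLOAT_FMT)
    observations = pd.read_csv(out / "traits_included.csv")
    means = mean_trait_response(observations)

    results = {}
    fit_stats = {}
    for trait in sorted(across["trait"].unique()):
        sub = across[across["trait"] == trait]
        responses = {
            "itv": sub.loc[:, ["species", "log_itv_star"]],
            "mean": means[means["trait"] == trait]
            .rename(columns={"mean_log_trait": "log_itv_star"})
            .loc[:, ["species", "log_itv_star"]],
        }
        for kind, resp in responses.items():
            tag = f"{trait}_{kind}"
            design = build_range_design(resp, ranges, config.predictors)
            seed = _derive_seed(config.seed, f"{trait}:{kind}")
            full = RangeRegression(design).fit(
                ci_levels=config.ci_levels, draws=config.reg_draws, seed=seed
            )
            trace, final = backward_select(design, seed=seed, draws=config.reg_draws)
            final.summary().reset_index().to_csv(
                out / f"range_fit_{tag}.csv", index=False, float_format=_FLOAT_FMT
            )
            trace.to_frame().to_csv(
                out / f"selection_trace_{tag}.csv", index=False, float_format=_FLOAT_FMT
            )
            if len(final.design.X.columns) >= 2:
                final.vif().rename_axis("predictor").reset_index().to_csv(
                    out / f"vif_{tag}.csv", index=False, float_format=_FLOAT_FMT
                )
            leave_one_out = (
                trace.steps[-1].candidates if trace.steps[-1].candidates else {}
            )
            fit_stats[tag] = {
                "n": final._stats["n"],
                "r2_final": final.r2,
                "aic_full": full.aic,
                "aic_final": final.aic,
                "aic_without": {k: float(v) for k, v in leave_one_out.items()},
                "final_predictors": list(trace.final_predictors),
                "significant_90": final.significant_terms(0.90),
            }
            results[tag] = (trace, final)
        # mean-vs-ITV correlation at the species scale
        merged = responses["itv"].merge(
            responses["mean"], on="species", suffixes=("_itv", "_mean")
        )
        if len(merged) >= 3:
            r, p = mean_itv_correlation(
                merged["log_itv_star_mean"], merged["log_itv_star_itv"]
            )
            fit_stats[f"{trait}_mean_itv_correlation"] = {"r": r, "p": p}
    with open(out / "fit_stats.json", "w") as fh:
        json.dump(_jsonable(fit_stats), fh, sort_keys=True, indent=1)
    return results


def report(run_dir) -> str:
    """Assemble a markdown summary from a completed run's artifacts."""
    out = Path(run_dir)
    lines = ["# ITV analysis run report", ""]
    missing = []

    summaries = sorted(out.glob("posterior_summary_*.csv"))
    if summaries:
        lines += ["## Within-site ITV vs site environmental variability", ""]
        lines += ["| model | mu2 (mean ± sd) | 95% CI | significant species slopes |",
                  "|---|---|---|---|"]
        for path in summaries:
            tag = path.stem.replace("posterior_summary_", "")
            summ = pd.read_csv(path).set_index("parameter")
            mu2 = summ.loc["mu2"]
            slopes_path = out / f"species_slopes_{tag}.csv"
            n_sig = ""
            if slopes_path.exists():
                sl = pd.read_csv(slopes_path)
                sl = sl[sl["species"] != ""] if "species" in sl else sl
                n_sig = str(int((sl["label"] != "nonsignificant").sum()))
            lines.append(
                f"| {tag} | {mu2['mean']:.3f} ± {mu2['sd']:.3f} "
                f"| [{mu2['q2.5']:.3f}, {mu2['q97.5']:.3f}] | {n_sig} |"
            )
        lines.append("")
    else:
        missing.append("hierarchical-model summaries (posterior_summary_*.csv)")

    stats_path = out / "fit_stats.json"
    if stats_path.exists():
        with open(stats_path) as fh:
            stats = json.load(fh)
        lines += ["## Across-site ITV and mean traits vs environmental ranges", ""]
        for tag in sorted(stats):
            entry = stats[tag]
            if tag.endswith("_correlation"):
                lines.append(
                    f"- **{tag}**: Pearson r = {entry['r']:.3f}, p = {entry['p']:.3g}"
                )
                continue
            lines.append(
                f"- **{tag}**: R² = {100 * entry['r2_final']:.2f}%, "
                f"AIC full = {entry['aic_full']:.2f}, final = {entry['aic_final']:.2f}; "
                f"retained: {', '.join(entry['final_predictors']) or '(intercept only)'}; "
                f"significant at 90%: {', '.join(entry['significant_90']) or 'none'}"
            )
            for drop, aic in sorted(entry.get("aic_without", {}).items()):
                lines.append(f"    - AIC without {drop}: {aic:.2f}")
        lines.append("")
    else:
        missing.append("range-model statistics (fit_stats.json)")

    if missing:
        lines += ["## Missing artifacts", ""]
        lines += [f"- {m}" for m in missing]
        lines.append("")
    text = "\n".join(lines)
    with open(out / "report.md", "w") as fh:
        fh.write(text)
    return text


def run_all(config: PipelineConfig) -> Path:
    """simulate (if scenario) -> ITV -> H1 -> H2 -> report."""
    out = Path(config.out_dir)
    config.write(out)
    if config.scenario is not None:
        simulate_stage(config)
    itv_stage(config)
    run_h1(config)
    run_h2(config)
    report(out)
    return out
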