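"""Synthetic data with the statistical structure the analysis assumes.

Generators mirror the fitted models in the forward direction:

* :func:`simulate_traits` draws species random intercepts/slopes from
  their normal hyperdistributions, builds each cell's true log ITV*
  (hypermeans + deviations + environment effect + residual scaled by
  sample size), then draws that many individual log-trait values with
  the matching variance and exponentiates to the trait scale.
* :func:`simulate_dem` produces constant, ramp or iid-Gaussian
  elevation grids with known terrain-roughness expectations.
* :func:`simulate_monthly_precip` produces 12 monthly totals hitting a
  target coefficient of variation.
* :func:`simulate_occurrences` draws records from species-specific
  uniform niches with known central-95% widths.
* :func:`simulate_coupled_itv_range` couples the two hypotheses: range
  widths are drawn first, species-level log ITV* is a linear function
  of the standardized widths, and within-site data are allocated
  consistently.

Every generator returns a truth record holding all drawn latent values,
so parameter recovery can be scored for every estimand the pipeline
reports.  All randomness flows from one master seed through named
substreams, so regenerating with the same seed is bit-identical.

Trait values carry species-specific mean log-traits drawn once per
species; those locations cancel out of every ITV quantity (ITV is
location-free on the log scale), so they are nuisance realism only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from itvar.env import DEMGrid, standardize
from itvar.itv import TRAITS

logger = logging.getLogger(__name__)

_SUBSTREAMS = {"traits": 0, "dem": 1, "precip": 2, "occurrences": 3, "coupled": 4, "env": 5}


def _rng(master_seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(_SUBSTREAMS[component],))
    )


@dataclass
class SimulationConfig:
    """All knobs of the trait-data generator.

    Defaults emulate the study design: 8 sites, ~33 species, unbalanced
    per-cell sample sizes (Poisson mean 12, truncated at 6 — above the
    inclusion minimum), species present at a random >= 4 of the sites,
    community-mean log ITV* around -3 (variances of a few percent on
    the log-trait scale) with moderate between-species spread.
    """

    n_species: int = 33
    n_sites: int = 8
    mu1: float = -3.0
    mu2: float = 0.0
    sigma1: float = 0.3
    sigma2: float = 0.2
    tau: float = 0.5
    error_scaling: str = "sd_over_n"
    traits: tuple[str, ...] = ("wood_density",)
    # per-cell sample-size law: fixed n, or Poisson(mean) truncated at minimum
    n_fixed: int | None = None
    n_poisson_mean: float = 12.0
    n_min: int = 6
    # site occupancy: "all" or random subset of >= min_sites_present sites
    occupancy: str = "random"
    min_sites_present: int = 4
    # site environmental-variability values: explicit list, else Uniform(lo, hi)
    env_values: tuple[float, ...] | None = None
    env_range: tuple[float, float] = (0.0, 1.0)
    standardize_env: bool = True
    # species mean log-trait distribution (nuisance location)
    species_mean_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.sigma1, self.sigma2, self.tau) < 0:
            raise ValueError("sigma1, sigma2, tau must be >= 0")
        if self.n_sites < 2:
            raise ValueError("need >= 2 sites")
        if self.n_fixed is not None and self.n_fixed < 2:
            raise ValueError("fixed per-cell n must be >= 2")
        if self.n_min < 2:
            raise ValueError("minimum per-cell n must be >= 2 after truncation")
        if self.error_scaling not in ("sd_over_n", "sd_over_sqrt_n"):
            raise ValueError(f"unknown error_scaling {self.error_scaling!r}")
        unknown = set(self.traits) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown trait(s) {sorted(unknown)}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TraitTruth:
    """Latent values behind one simulated trait dataset."""

    config: dict
    env: pd.DataFrame  # site, env (on the model scale)
    species: pd.DataFrame  # trait, species, delta1, delta2, beta1, beta2, mean_log_trait
    cells: pd.DataFrame  # trait, species, site, n, true_log_itv_star

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "env": self.env.to_dict(orient="list"),
            "species": self.species.to_dict(orient="list"),
            "cells": self.cells.to_dict(orient="list"),
        }


def _site_env(config: SimulationConfig, rng) -> np.ndarray:
    if config.env_values is not None:
        env = np.asarray(config.env_values, dtype=float)
        if env.size != config.n_sites:
            raise ValueError("env_values length must equal n_sites")
    else:
        env = rng.uniform(*config.env_range, size=config.n_sites)
    if config.standardize_env:
        env = (env - env.mean()) / env.std(ddof=1)
    return env


def simulate_traits(config: SimulationConfig) -> tuple[pd.DataFrame, TraitTruth]:
    """Generate individual trait observations plus a full truth record.

    The per-cell true log ITV* is
    ``mu1 + delta1_sp + (mu2 + delta2_sp) * env_si + eps / w`` with
    ``eps ~ N(0, tau)`` and ``w = n`` (or ``sqrt(n)``); individual log
    traits are drawn Normal(species mean, sqrt(exp(true log ITV*)))
    and exponentiated, so empirical ITV* estimates the truth with the
    usual chi-square sampling noise of a variance.
    """
    rng = _rng(config.seed, "traits")
    env = _site_env(config, rng)
    sites = [f"S{j+1}" for j in range(config.n_sites)]
    species = [f"sp{i+1:03d}" for i in range(config.n_species)]

    obs_rows = []
    sp_rows = []
    cell_rows = []
    for trait in config.traits:
        d1 = rng.normal(0.0, config.sigma1, size=config.n_species)
        d2 = rng.normal(0.0, config.sigma2, size=config.n_species)
        mean_log = rng.normal(0.0, config.species_mean_sd, size=config.n_species)
        for i, sp in enumerate(species):
            sp_rows.append(
                {
                    "trait": trait,
                    "species": sp,
                    "delta1": d1[i],
                    "delta2": d2[i],
                    "beta1": config.mu1 + d1[i],
                    "beta2": config.mu2 + d2[i],
                    "mean_log_trait": mean_log[i],
                }
            )
            if config.occupancy == "all":
                present = np.arange(config.n_sites)
            else:
                lo = min(config.min_sites_present, config.n_sites)
                k = rng.integers(lo, config.n_sites + 1)
                present = np.sort(rng.choice(config.n_sites, size=k, replace=False))
            for j in present:
                if config.n_fixed is not None:
                    n = config.n_fixed
                else:
                    n = max(int(rng.poisson(config.n_poisson_mean)), config.n_min)
                w = n if config.error_scaling == "sd_over_n" else np.sqrt(n)
                eps = rng.normal(0.0, config.tau) if config.tau > 0 else 0.0
                true_log_itv = (
                    config.mu1 + d1[i] + (config.mu2 + d2[i]) * env[j] + eps / w
                )
                cell_rows.append(
                    {
                        "trait": trait,
                        "species": sp,
                        "site": sites[j],
                        "n": n,
                        "true_log_itv_star": true_log_itv,
                    }
                )
                sd = float(np.sqrt(np.exp(true_log_itv)))
                logs = rng.normal(mean_log[i], sd, size=n)
                for v in np.exp(logs):
                    obs_rows.append(
                        {"site": sites[j], "species": sp, "trait": trait, "value": v}
                    )

    observations = pd.DataFrame(obs_rows, columns=["site", "species", "trait", "value"])
    truth = TraitTruth(
        config=config.to_dict(),
        env=pd.DataFrame({"site": sites, "env": env}),
        species=pd.DataFrame(sp_rows),
        cells=pd.DataFrame(cell_rows),
    )
    return observations, truth


def design_from_truth(truth: TraitTruth, trait: str | None = None) -> pd.DataFrame:
    """Model-ready design using the *true* per-cell log ITV* values.

    Bypasses individual-level sampling noise: the response is exactly
    the generative ``mu1 + delta1 + (mu2 + delta2) env + eps/w`` value,
    so the fitted model matches the generator and parameter recovery is
    well-posed (used by the sampler-validation tests).
    """
    cells = truth.cells
    if trait is not None:
        cells = cells[cells["trait"] == trait]
    cells = cells.reset_index(drop=True)
    env_map = truth.env.set_index("site")["env"]
    species = sorted(cells["species"].unique())
    idx = {sp: i for i, sp in enumerate(species)}
    out = pd.DataFrame(
        {
            "log_itv_star": cells["true_log_itv_star"].astype(float),
            "species": cells["species"],
            "species_idx": cells["species"].map(idx).astype(int),
            "site": cells["site"],
            "env": cells["site"].map(env_map).astype(float),
            "n": cells["n"].astype(int),
        }
    )
    out.attrs["species_order"] = species
    return out


def simulate_dem(
    kind: str = "gaussian_noise",
    n_rows: int = 50,
    n_cols: int = 50,
    value: float = 100.0,
    slope: float = 2.0,
    sd: float = 1.0,
    cell_size: float = 5.0,
    seed: int = 0,
) -> DEMGrid:
    """Elevation grids with known roughness: ``constant``, ``ramp``
    (rising ``slope`` per cell along columns; interior TRI = 0.75*slope),
    or ``gaussian_noise`` (iid N(0, sd); expected interior TRI =
    2*sd/sqrt(pi), the mean absolute difference of two iid normals).
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be positive")
    if kind == "constant":
        z = np.full((n_rows, n_cols), value, dtype=float)
    elif kind == "ramp":
        z = value + slope * np.tile(np.arange(n_cols, dtype=float), (n_rows, 1))
    elif kind == "gaussian_noise":
        z = value + _rng(seed, "dem").normal(0.0, sd, size=(n_rows, n_cols))
    else:
        raise ValueError(f"unknown DEM kind {kind!r}")
    return DEMGrid(elevation=z, cell_size=cell_size)


def simulate_monthly_precip(
    mean_mm: float, target_cv_pct: float, seed: int = 0
) -> np.ndarray:
    """Twelve non-negative monthly totals whose sample CV hits the target.

    Deviations are drawn once, then rescaled: affinely when that keeps
    all months non-negative, otherwise multiplicatively on the log
    scale with the spread factor solved so the sample CV matches
    (logged, since the affine route was infeasible).
    """
    if mean_mm <= 0:
        raise ValueError("mean monthly precipitation must be positive")
    if target_cv_pct < 0:
        raise ValueError("target CV must be >= 0")
    if target_cv_pct == 0:
        return np.full(12, float(mean_mm))
    rng = _rng(seed, "precip")
    z = rng.standard_normal(12)
    z = (z - z.mean()) / z.std(ddof=1)  # exact mean 0, sample sd 1
    x = mean_mm + (target_cv_pct / 100.0) * mean_mm * z
    if np.all(x >= 0):
        return x
    logger.info(
        "target CV %.1f%% forces negative months under affine rescale; "
        "switching to lognormal spread",
        target_cv_pct,
    )

    def cv_gap(lam: float) -> float:
        v = np.exp(lam * z)
        v = v / v.mean() * mean_mm
        return 100.0 * v.std(ddof=1) / v.mean() - target_cv_pct

    lam = brentq(cv_gap, 1e-9, 20.0)
    v = np.exp(lam * z)
    return v / v.mean() * mean_mm


@dataclass
class OccurrenceConfig:
    """Species-specific uniform niches for occurrence simulation.

    Each attribute of each species is Uniform(center - w/2, center + w/2);
    the recoverable central-95% width is 0.95 * w.  Defaults give niche
    centers and widths on island-plausible scales.
    """

    n_species: int = 33
    records_per_species: int = 300
    attributes: tuple[str, ...] = ("elevation", "map", "pet", "cwd", "irradiance", "cloudiness")
    # (center_lo, center_hi, width_lo, width_hi) per attribute
    niche: dict = field(
        default_factory=lambda: {
            "elevation": (100.0, 900.0, 100.0, 800.0),
            "map": (1200.0, 2300.0, 200.0, 1200.0),
            "pet": (1100.0, 1700.0, 100.0, 600.0),
            "cwd": (0.0, 500.0, 50.0, 400.0),
            "irradiance": (1600.0, 2000.0, 50.0, 350.0),
            "cloudiness": (20.0, 70.0, 5.0, 40.0),
        }
    )
    geology_classes: tuple[str, ...] = ("volcanic", "limestone", "alluvial", "ultramafic")
    seed: int = 0


def simulate_occurrences(config: OccurrenceConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occurrence records plus a truth table of recoverable range widths."""
    rng = _rng(config.seed, "occurrences")
    rows = []
    truth_rows = []
    for i in range(config.n_species):
        sp = f"sp{i+1:03d}"
        truth = {"species": sp}
        n = config.records_per_species
        rec = {"species": np.repeat(sp, n)}
        for attr in config.attributes:
            c_lo, c_hi, w_lo, w_hi = config.niche[attr]
            center = rng.uniform(c_lo, c_hi)
            width = rng.uniform(w_lo, w_hi)
            rec[attr] = rng.uniform(center - width / 2, center + width / 2, size=n)
            truth[f"{attr}_range"] = 0.95 * width
        k = rng.integers(1, len(config.geology_classes) + 1)
        classes = rng.choice(config.geology_classes, size=k, replace=False)
        rec["geology"] = rng.choice(classes, size=n)
        truth["geology_count"] = int(k)
        truth_rows.append(truth)
        rows.append(pd.DataFrame(rec))
    occurrences = pd.concat(rows, ignore_index=True)
    return occurrences, pd.DataFrame(truth_rows)


@dataclass
class CoupledConfig:
    """Hypothesis-2 end-to-end scenario: ITV driven by range breadth.

    ``coefficients`` maps predictor column names (on the standardized
    scale) to true slopes; unnamed predictors are inactive.  The
    species-level response is
    ``intercept + X_std @ beta + Normal(0, noise_sd)``.
    """

    n_species: int = 200
    coefficients: dict = field(default_factory=dict)
    intercept: float = -3.0
    noise_sd: float = 0.5
    occurrence: OccurrenceConfig | None = None
    n_sites: int = 8
    n_per_cell: int = 12
    trait: str = "wood_density"
    seed: int = 0


def simulate_coupled_itv_range(
    config: CoupledConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full Hypothesis-2 dataset: observations, occurrences, truth.

    Range widths are drawn first; species-level true log ITV* follows
    the linear model on standardized true widths; individual trait
    values are then drawn so the across-site pooled ITV* estimates
    exp(true response).  Returns ``(observations, occurrences, truth)``
    where truth holds the true widths, standardized design, response
    and coefficient vector.
    """
    occ_cfg = config.occurrence or OccurrenceConfig(
        n_species=config.n_species, seed=config.seed
    )
    if occ_cfg.n_species != config.n_species or occ_cfg.seed != config.seed:
        occ_cfg = OccurrenceConfig(
            **{**asdict(occ_cfg), "n_species": config.n_species, "seed": config.seed}
        )
    occurrences, true_ranges = simulate_occurrences(occ_cfg)

    pred_cols = [f"{a}_range" for a in occ_cfg.attributes] + ["geology_count"]
    X_raw = true_ranges.set_index("species").loc[:, pred_cols].astype(float)
    X_std, std_params = standardize(X_raw)
    beta = np.array([config.coefficients.get(c, 0.0) for c in pred_cols])

    rng = _rng(config.seed, "coupled")
    y = (
        config.intercept
        + X_std.to_numpy() @ beta
        + rng.normal(0.0, config.noise_sd, size=config.n_species)
    )

    sites = [f"S{j+1}" for j in range(config.n_sites)]
    obs_rows = []
    for i, sp in enumerate(X_std.index):
        sd = float(np.sqrt(np.exp(y[i])))
        mean_log = rng.normal(0.0, 1.0)
        for site in sites:
            logs = rng.normal(mean_log, sd, size=config.n_per_cell)
            for v in np.exp(logs):
                obs_rows.append(
                    {"site": site, "species": sp, "trait": config.trait, "value": v}
                )
    observations = pd.DataFrame(obs_rows, columns=["site", "species", "trait", "value"])
    truth = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "occurrence"},
            "predictors": pred_cols,
        },
        "true_ranges": true_ranges,
        "X_std": X_std,
        "response": pd.Series(y, index=X_std.index, name="true_log_itv_star"),
        "coefficients": pd.Series(beta, index=pred_cols, name="beta"),
    }
    return observations, occurrences, truth


# ---------------------------------------------------------------------------
# scenario presets

SCENARIOS = ("h1_null", "h1_positive", "h2_null", "h2_strong", "paper_scale")


def scenario_config(name: str, seed: int = 0):
    """Named scenario presets used by the command-line pipeline.

    * ``h1_null`` / ``h1_positive`` — 30 species x 8 sites, complete
      grid, community slope mu2 = 0 / 0.8.
    * ``h2_null`` / ``h2_strong`` — coupled ITV-range data with no
      active predictor / one strong predictor (PET range, 0.5).
    * ``paper_scale`` — 33 species x 8 sites, both traits, unbalanced
      occupancy and sample sizes, plus matching occurrence records.
    """
    if name in ("h1_null", "h1_positive"):
        return SimulationConfig(
            n_species=30,
            n_sites=8,
            mu1=-3.0,
            mu2=0.0 if name == "h1_null" else 0.8,
            sigma1=0.3,
            sigma2=0.2,
            tau=0.5,
            occupancy="all",
            seed=seed,
        )
    if name in ("h2_null", "h2_strong"):
        coeff = {} if name == "h2_null" else {"pet_range": 0.5}
        n_sp = 33 if name == "h2_null" else 200
        return CoupledConfig(n_species=n_sp, coefficients=coeff, seed=seed)
    if name == "paper_scale":
        return SimulationConfig(
            n_species=33,
            n_sites=8,
            traits=("wood_density", "lma"),
            occupancy="random",
            seed=seed,
        )
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
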