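"""Sample-size-corrected intraspecific trait variation (ITV*).

ITV of a species at a site is the population (denominator *n*) variance
of its log-transformed trait values; ITV* applies Bessel's correction,

    ITV* = n / (n - 1) * ITV,

which is the ordinary unbiased sample variance of the log values.
Because the statistic is computed on logs it is invariant to rescaling
of the trait and identical for a trait and its inverse (relevant for
LMA, whose inverse — specific leaf area — is an equivalent indicator).
Downstream models use log ITV* as the response.

The module also implements the inclusion filter used to restrict an
unbalanced trait survey to species x site cells with enough individuals
for a stable variance estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed trait vocabulary: wood density (g/cm^3) and leaf mass per area (g/cm^2).
TRAITS = ("wood_density", "lma")

#: Default inclusion thresholds: a species must occur at >3 sites with
#: >5 individuals per site, i.e. at least 4 qualifying sites of at
#: least 6 individuals each.
MIN_SITES = 4
MIN_PER_SITE = 6


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row-level value violates an invariant (e.g. non-positive trait)."""


@dataclass
class FilterReport:
    """Accounting of what the inclusion filter removed and why."""

    min_sites: int
    min_per_site: int
    n_obs_in: int
    n_obs_out: int
    dropped_cells: list[dict] = field(default_factory=list)
    dropped_species: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "min_sites": self.min_sites,
            "min_per_site": self.min_per_site,
            "n_obs_in": self.n_obs_in,
            "n_obs_out": self.n_obs_out,
            "dropped_cells": self.dropped_cells,
            "dropped_species": self.dropped_species,
        }


def _validate_observations(df: pd.DataFrame, source: str = "trait table") -> pd.DataFrame:
    required = ["site", "species", "trait", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s) {missing}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[values.isna() | (values <= 0)]
    if len(bad):
        first = bad[0]
        raise ValidationError(
            f"{source}: row {first} has non-positive or non-numeric value "
            f"{df.loc[first, 'value']!r} (log transform requires value > 0); "
            f"{len(bad)} offending row(s) in total"
        )
    unknown = sorted(set(df["trait"].unique()) - set(TRAITS))
    if unknown:
        raise ValidationError(f"{source}: unknown trait label(s) {unknown}; expected {TRAITS}")
    out = df.loc[:, required].copy()
    out["value"] = values
    return out


def read_trait_table(path) -> pd.DataFrame:
    """Read a trait observation table (CSV columns site,species,trait,value).

    Returns a validated DataFrame, one row per individual observation,
    row order preserved.
    """
    df = pd.read_csv(path)
    out = _validate_observations(df, source=str(path))
    logger.info("read %d trait observations from %s", len(out), path)
    return out


def write_trait_table(observations: pd.DataFrame, path) -> None:
    """Write observations back to the CSV schema read_trait_table expects."""
    observations.loc[:, ["site", "species", "trait", "value"]].to_csv(path, index=False)


def filter_included(
    observations: pd.DataFrame,
    min_sites: int = MIN_SITES,
    min_per_site: int = MIN_PER_SITE,
) -> tuple[pd.DataFrame, FilterReport]:
    """Restrict observations to qualifying species x site cells.

    A cell (species, site) qualifies when it holds at least ``min_per_site``
    individuals; a species is retained when it has at least ``min_sites``
    qualifying cells.  The site-count rule is evaluated on qualifying
    cells only — cells below the per-site minimum cannot contribute a
    reliable variance and do not count toward a species' site tally.

    Filtering is applied per trait (a species may qualify for one trait
    and not the other).  Returns the retained observations and a
    :class:`FilterReport`.
    """
    if min_sites < 1 or min_per_site < 1:
        raise ValueError("thresholds must be >= 1")
    report = FilterReport(min_sites, min_per_site, n_obs_in=len(observations), n_obs_out=0)
    if observations.empty:
        warnings.warn("filter_included: empty input", stacklevel=2)
        return observations.copy(), report

    counts = (
        observations.groupby(["trait", "species", "site"], sort=False)
        .size()
        .rename("n")
        .reset_index()
    )
    qualifying = counts[counts["n"] >= min_per_site]
    for _, row in counts[counts["n"] < min_per_site].iterrows():
        report.dropped_cells.append(
            {
                "trait": row["trait"],
                "species": row["species"],
                "site": row["site"],
                "n": int(row["n"]),
                "reason": f"n < {min_per_site}",
            }
        )
    site_tally = qualifying.groupby(["trait", "species"], sort=False).size()
    kept_keys = set(site_tally[site_tally >= min_sites].index)
    for key, tally in site_tally[site_tally < min_sites].items():
        report.dropped_species.append(
            {
                "trait": key[0],
                "species": key[1],
                "qualifying_sites": int(tally),
                "reason": f"qualifying sites < {min_sites}",
            }
        )
    # species whose every cell failed the per-site rule never reach site_tally
    all_keys = set(counts.set_index(["trait", "species"]).index)
    for key in sorted(all_keys - set(site_tally.index)):
        report.dropped_species.append(
            {
                "trait": key[0],
                "species": key[1],
                "qualifying_sites": 0,
                "reason": f"qualifying sites < {min_sites}",
            }
        )

    kept_cells = {
        (r["trait"], r["species"], r["site"])
        for _, r in qualifying.iterrows()
        if (r["trait"], r["species"]) in kept_keys
    }
    mask = [
        (t, sp, si) in kept_cells
        for t, sp, si in zip(observations["trait"], observations["species"], observations["site"])
    ]
    out = observations[mask].copy()
    report.n_obs_out = len(out)
    logger.info(
        "inclusion filter: %d -> %d observations (%d cells, %d species-trait combos dropped)",
        len(observations),
        len(out),
        len(report.dropped_cells),
        len(report.dropped_species),
    )
    return out, report


def compute_itv_star(values, scope: str = "within_site") -> dict:
    """Compute the corrected ITV* of one vector of trait values.

    Parameters
    ----------
    values : array-like of positive reals, length >= 2
        Trait measurements for one species at one site (scope
        ``within_site``) or pooled over sites (``across_site``).
    scope : str
        Recorded in the output for bookkeeping only.

    Returns
    -------
    dict with keys ``n``, ``itv_raw`` (denominator-n variance of the
    natural-log values), ``itv_star`` (Bessel-corrected), and
    ``log_itv_star`` (NaN when itv_star == 0).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"ITV undefined for n={x.size} (< 2 values)")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("trait values must be positive and finite (log transform)")
    logs = np.log(x)
    n = x.size
    itv_raw = float(np.mean((logs - logs.mean()) ** 2))
    itv_star = n / (n - 1) * itv_raw
    log_itv_star = float(np.log(itv_star)) if itv_star > 0 else np.nan
    return {
        "scope": scope,
        "n": n,
        "itv_raw": itv_raw,
        "itv_star": itv_star,
        "log_itv_star": log_itv_star,
    }


def itv_table(observations: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build within-site and across-site ITV* tables from filtered observations.

    Returns ``(within, across)``:

    * ``within`` — one row per qualifying species x site cell per trait;
    * ``across`` — one row per species per trait, pooling all that
      species' retained observations (n equals the sum of cell n's).

    Zero-variance cells (all values identical) are dropped with a
    warning: their log ITV* is undefined.
    """
    cols = ["trait", "species", "site", "n", "itv_raw", "itv_star", "log_itv_star"]
    if observations.empty:
        empty_w = pd.DataFrame(columns=cols)
        empty_a = pd.DataFrame(columns=[c for c in cols if c != "site"])
        return empty_w, empty_a

    within_rows = []
    for (trait, sp, si), grp in observations.groupby(["trait", "species", "site"], sort=True):
        rec = compute_itv_star(grp["value"].to_numpy(), scope="within_site")
        within_rows.append({"trait": trait, "species": sp, "site": si, **_strip(rec)})
    across_rows = []
    for (trait, sp), grp in observations.groupby(["trait", "species"], sort=True):
        rec = compute_itv_star(grp["value"].to_numpy(), scope="across_site")
        across_rows.append({"trait": trait, "species": sp, **_strip(rec)})

    within = pd.DataFrame(within_rows, columns=cols)
    across = pd.DataFrame(across_rows, columns=[c for c in cols if c != "site"])
    for name, df in (("within-site", within), ("across-site", across)):
        zero = df["itv_star"] == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance {name} cell(s) dropped "
                "(log ITV* undefined)",
                stacklevel=2,
            )
    within = within[within["itv_star"] > 0].reset_index(drop=True)
    across = across[across["itv_star"] > 0].reset_index(drop=True)
    return within, across


def _strip(rec: dict) -> dict:
    return {k: rec[k] for k in ("n", "itv_raw", "itv_star", "log_itv_star")}
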