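"""Environmental-variability metrics at site and species scale.

Site scale
    * terrain roughness index (TRI): per DEM cell, the mean absolute
      elevation difference to its valid 8-neighborhood; the site value
      is the mean over valid cells — a spatial-heterogeneity metric.
    * rainfall CV: coefficient of variation of the twelve mean monthly
      precipitation totals — a seasonality (temporal) metric, percent.

Species scale
    * environmental range breadth: width of the central 95% quantile
      interval of an attribute (elevation, MAP, PET, CWD, irradiance,
      cloudiness) over a species' occurrence records.
    * geological range: count of distinct geology classes occupied.

TRI uses the mean-absolute-difference convention; edge cells use only
their existing neighbors (no padding).  Quantiles use linear
interpolation between order statistics.  Standard deviations are the
n-1 (sample) convention throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default geology vocabulary; extensible via the ``classes`` argument
#: of :func:`geology_class_count`.
GEOLOGY_CLASSES = ("volcanic", "limestone", "alluvial", "ultramafic")

#: Occurrence attributes for which range breadths are computed.
RANGE_ATTRIBUTES = ("elevation", "map", "pet", "cwd", "irradiance", "cloudiness")


@dataclass
class DEMGrid:
    """A digital elevation model on a regular grid.

    ``elevation`` is a 2-D float array with NaN marking nodata cells.
    """

    elevation: np.ndarray
    cell_size: float = 5.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata_value: float = -9999.0

    def __post_init__(self):
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.ndim != 2 or min(self.elevation.shape) < 1:
            raise ValueError("elevation must be a 2-D array with >= 1 cell")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape


def read_ascii_grid(path) -> DEMGrid:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: ESRI ASCII header missing '{key}'")
    arr = np.array(rows, dtype=float)
    if arr.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: data block {arr.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value", -9999.0)
    arr[arr == nodata] = np.nan
    return DEMGrid(
        elevation=arr,
        cell_size=header["cellsize"],
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        nodata_value=nodata,
    )


def write_ascii_grid(dem: DEMGrid, path) -> None:
    """Write a :class:`DEMGrid` as an ESRI ASCII grid."""
    nrows, ncols = dem.shape
    arr = np.where(np.isnan(dem.elevation), dem.nodata_value, dem.elevation)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {dem.xllcorner:.6f}\n")
        fh.write(f"yllcorner {dem.yllcorner:.6f}\n")
        fh.write(f"cellsize {dem.cell_size:.6f}\n")
        fh.write(f"NODATA_value {dem.nodata_value:g}\n")
        for row in arr:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def terrain_roughness_index(dem: DEMGrid) -> np.ndarray:
    """Per-cell TRI: mean |elevation difference| to the valid 8-neighborhood.

    Edge cells average over their existing neighbors only.  Cells that
    are nodata, or have no valid neighbor, get NaN.
    """
    z = dem.elevation
    if not np.any(np.isfinite(z)):
        raise ValueError("all-nodata grid: TRI undefined")
    nrows, ncols = z.shape
    total = np.zeros_like(z)
    count = np.zeros_like(z)
    shifts = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for dr, dc in shifts:
        r0, r1 = max(dr, 0), nrows + min(dr, 0)
        c0, c1 = max(dc, 0), ncols + min(dc, 0)
        diff = np.abs(z[r0:r1, c0:c1] - z[r0 - dr:r1 - dr, c0 - dc:c1 - dc])
        valid = np.isfinite(diff)
        total[r0 - dr:r1 - dr, c0 - dc:c1 - dc] += np.where(valid, diff, 0.0)
        count[r0 - dr:r1 - dr, c0 - dc:c1 - dc] += valid
    with np.errstate(invalid="ignore", divide="ignore"):
        tri = total / count
    tri[~np.isfinite(z)] = np.nan
    tri[count == 0] = np.nan
    return tri


def site_roughness(dem: DEMGrid) -> float:
    """Site-level topographic variability: mean of valid per-cell TRI."""
    tri = terrain_roughness_index(dem)
    valid = np.isfinite(tri)
    if not valid.any():
        raise ValueError("no valid TRI cells")
    return float(tri[valid].mean())


def rainfall_cv(monthly) -> float:
    """Coefficient of variation (%) of twelve monthly precipitation totals.

    100 * sample standard deviation / mean.  Scale-invariant; zero for a
    uniform seasonal profile.
    """
    x = np.asarray(monthly, dtype=float)
    if x.size != 12:
        raise ValueError(f"expected 12 monthly values, got {x.size}")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("monthly precipitation must be non-negative and finite")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("CV undefined: mean monthly precipitation is 0")
    return float(100.0 * x.std(ddof=1) / mean)


def env_range_95(values) -> float:
    """Breadth of the central 95% interval (2.5th to 97.5th percentile).

    Quantiles use linear interpolation between order statistics; at
    least two finite values are required.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError(f"env_range_95 needs >= 2 finite values, got {x.size}")
    lo, hi = np.quantile(x, [0.025, 0.975], method="linear")
    return float(hi - lo)


def geology_class_count(geology_labels, classes: tuple[str, ...] | None = None) -> int:
    """Number of distinct geology classes in a species' occurrence records."""
    labels = list(geology_labels)
    if not labels:
        raise ValueError("geology_class_count needs >= 1 record")
    distinct = set(labels)
    if classes is not None:
        unknown = distinct - set(classes)
        if unknown:
            raise ValueError(f"geology labels {sorted(unknown)} not in vocabulary {classes}")
    return len(distinct)


def species_ranges(
    occurrences: pd.DataFrame,
    attributes: tuple[str, ...] = RANGE_ATTRIBUTES,
) -> pd.DataFrame:
    """Per-species environmental range breadths from occurrence records.

    ``occurrences`` needs columns ``species``, ``geology`` and the
    numeric ``attributes``.  Species with fewer than two finite values
    for any attribute are excluded with a warning.  Returns one row per
    species with columns ``<attr>_range`` and ``geology_count``.
    """
    required = {"species", "geology", *attributes}
    missing = required - set(occurrences.columns)
    if missing:
        raise ValueError(f"occurrences missing column(s) {sorted(missing)}")
    rows = []
    for sp, grp in occurrences.groupby("species", sort=True):
        try:
            row = {"species": sp}
            for attr in attributes:
                row[f"{attr}_range"] = env_range_95(grp[attr].to_numpy())
            row["geology_count"] = geology_class_count(grp["geology"])
        except ValueError as exc:
            logger.warning("species %s excluded from range table: %s", sp, exc)
            continue
        rows.append(row)
    cols = ["species", *[f"{a}_range" for a in attributes], "geology_count"]
    return pd.DataFrame(rows, columns=cols)


def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score each column to mean 0, sd 1 (sample sd, ddof=1).

    Returns the standardized matrix and a two-row DataFrame of the
    per-column ``mean`` and ``sd`` used, for back-transformation.
    Raises on a zero-variance column, naming it.
    """
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    degenerate = sds[(sds == 0) | ~np.isfinite(sds)].index.tolist()
    if degenerate:
        raise ValueError(f"zero-variance predictor column(s): {degenerate}")
    z = (matrix - means) / sds
    params = pd.DataFrame({"mean": means, "sd": sds}).T
    return z, params


def destandardize(z: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`standardize` using its returned parameters."""
    return z * params.loc["sd"] + params.loc["mean"]
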