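"""Patch identification and landscape metrics.

A *patch* is a maximal 4-connected set of cells sharing one nonzero
species code.  Patch perimeter counts every unit cell edge between a
patch cell and anything outside the patch — bare substrate, a cell of
another species, or the plot boundary (no torus wrap).

Seven plot-level metrics summarise the mosaic:

====  =====================================  =========
MPS   mean patch size                        cm^2
PSCV  patch-size coefficient of variation    %
TE    total edge (sum of patch perimeters)   cm
NP    number of patches                      count
MSI   mean shape index, P / (4 sqrt(A))      —
PR    patch-type (species) richness          count
SHDI  Shannon diversity of patch-type area   nats
====  =====================================  =========

The shape index uses the raster square-normalised form so that any
solid square scores exactly 1 and irregular shapes score higher.  SHDI
proportions are taken over vegetated area only (bare substrate is not a
patch type), hence SHDI = 0 whenever a single species is present,
regardless of total cover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import DegenerateInputError, ValidationError
from .grids import SpeciesGrid, SpeciesRegistry

__all__ = [
    "PatchRecord",
    "PlotMetricsRecord",
    "label_patches",
    "shape_index",
    "plot_metrics",
    "plot_metrics_table",
    "species_metrics",
    "distribution_summary",
    "metric_correlations",
    "METRIC_NAMES",
]

METRIC_NAMES = ("MPS", "PSCV", "TE", "NP", "MSI", "PR", "SHDI")

#: 4-neighbour (von Neumann) structuring element
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PatchRecord:
    """One connected patch of a single species."""

    plot_id: str
    species_code: int
    area: float  # cm^2
    perimeter: float  # cm
    shape_index: float


@dataclass(frozen=True)
class PlotMetricsRecord:
    """The seven landscape metrics of one plot; NaN where undefined."""

    plot_id: str
    MPS: float
    PSCV: float
    TE: float
    NP: int
    MSI: float
    PR: int
    SHDI: float


def shape_index(area: float, perimeter: float, cell_size: float = 1.0) -> float:
    """Square-normalised raster shape index P / (4 sqrt(A)).

    ``area`` in cm^2 and ``perimeter`` in cm are converted to cell units
    with ``cell_size`` (cm), making the index scale-free: 1 for any solid
    square, growing without bound with irregularity.
    """
    if area <= 0 or perimeter <= 0:
        raise DegenerateInputError("area and perimeter must be positive")
    cells = area / cell_size**2
    edges = perimeter / cell_size
    return edges / (4.0 * math.sqrt(cells))


def label_patches(grid: SpeciesGrid, connectivity: int = 4) -> list[PatchRecord]:
    """Identify every patch of the grid and return one record per patch.

    Labeling runs species by species, so two touching patches of
    different species remain distinct.  ``connectivity`` is 4 (default,
    the four-neighbour rule) or 8.
    """
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")
    structure = _STRUCT4 if connectivity == 4 else _STRUCT8
    records: list[PatchRecord] = []
    values = grid.values
    c = grid.cell_size
    for code in grid.species_present():
        mask = values == code
        lab, n = ndimage.label(mask, structure=structure)
        if n == 0:
            continue
        areas = np.bincount(lab.ravel(), minlength=n + 1)[1:]
        # shared 4-adjacencies within a component; perimeter = 4A - 2*adjacencies
        adj = np.zeros(n + 1, dtype=int)
        horiz = (lab[:, 1:] == lab[:, :-1]) & (lab[:, 1:] > 0)
        vert = (lab[1:, :] == lab[:-1, :]) & (lab[1:, :] > 0)
        adj += np.bincount(lab[:, 1:][horiz], minlength=n + 1)
        adj += np.bincount(lab[1:, :][vert], minlength=n + 1)
        perims = 4 * areas - 2 * adj[1:]
        for a, p in zip(areas, perims):
            records.append(
                PatchRecord(
                    plot_id=grid.plot_id,
                    species_code=int(code),
                    area=float(a) * c**2,
                    perimeter=float(p) * c,
                    shape_index=shape_index(float(a) * c**2, float(p) * c, c),
                )
            )
    return records


def plot_metrics(patches: list[PatchRecord], plot_id: str | None = None) -> PlotMetricsRecord:
    """Aggregate one plot's patches into the seven landscape metrics.

    An empty patch list yields NP = 0 with every other metric NaN.
    PSCV uses the population standard deviation, so a single patch gives
    PSCV = 0 exactly.
    """
    if not patches:
        if plot_id is None:
            raise ValidationError("plot_id required for an empty patch list")
        return PlotMetricsRecord(plot_id, math.nan, math.nan, math.nan, 0, math.nan, 0, math.nan)
    ids = {p.plot_id for p in patches}
    if len(ids) > 1:
        raise ValidationError(f"patches span several plots: {sorted(ids)}")
    pid = plot_id or next(iter(ids))

    areas = np.array([p.area for p in patches])
    perims = np.array([p.perimeter for p in patches])
    shapes = np.array([p.shape_index for p in patches])
    species = np.array([p.species_code for p in patches])

    mps = float(areas.mean())
    pscv = 100.0 * float(areas.std(ddof=0)) / mps
    te = float(perims.sum())
    np_ = len(patches)
    msi = float(shapes.mean())
    pr = len(np.unique(species))
    total = areas.sum()
    p_i = np.array([areas[species == s].sum() for s in np.unique(species)]) / total
    shdi = float(-(p_i * np.log(p_i)).sum())
    return PlotMetricsRecord(pid, mps, pscv, te, np_, msi, pr, shdi)


def plot_metrics_table(grids: list[SpeciesGrid], connectivity: int = 4) -> pd.DataFrame:
    """Plot x metric table (the R-table of the ordination) from rasters."""
    rows = []
    for g in grids:
        rec = plot_metrics(label_patches(g, connectivity), plot_id=g.plot_id)
        rows.append({"plot_id": rec.plot_id, **{m: getattr(rec, m) for m in METRIC_NAMES}})
    return pd.DataFrame(rows).set_index("plot_id")


def species_metrics(
    patches: list[PatchRecord],
    n_plots: int,
    registry: SpeciesRegistry | None = None,
) -> pd.DataFrame:
    """Species-level landscape traits aggregated over all plots.

    Returns a table indexed by species with columns ``frequency`` (% of
    plots occupied), ``MPS``/``MPS_sd`` (cm^2; sample sd, NaN for a single
    patch), ``CA`` (total cover, cm^2), ``MSI``/``MSI_sd``, ``NP`` and
    ``TE``.
    """
    if not patches:
        raise ValidationError("no patches")
    if n_plots < 1:
        raise ValidationError("n_plots must be >= 1")
    df = pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in patches],
            "species_code": [p.species_code for p in patches],
            "area": [p.area for p in patches],
            "perimeter": [p.perimeter for p in patches],
            "shape_index": [p.shape_index for p in patches],
        }
    )
    if registry is not None:
        unknown = set(df["species_code"]) - set(registry.codes)
        if unknown:
            raise ValidationError(f"unknown species codes: {sorted(unknown)}")
    out = df.groupby("species_code").agg(
        frequency=("plot_id", lambda s: 100.0 * s.nunique() / n_plots),
        MPS=("area", "mean"),
        MPS_sd=("area", lambda a: a.std(ddof=1)),
        CA=("area", "sum"),
        MSI=("shape_index", "mean"),
        MSI_sd=("shape_index", lambda s: s.std(ddof=1)),
        NP=("area", "size"),
        TE=("perimeter", "sum"),
    )
    if registry is not None:
        out.index = [registry.label(c) for c in out.index]
        out.index.name = "species"
    return out


def distribution_summary(values) -> dict[str, float]:
    """Mean, sd, type-7 quartiles, max and moment skewness (g1) of a sample.

    With fewer than two observations the sd and skewness are NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("empty sample")
    q1, q2, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation = type 7
    out = {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else math.nan,
        "q1": float(q1),
        "median": float(q2),
        "q3": float(q3),
        "max": float(x.max()),
        "skewness": float(stats.skew(x, bias=True)) if x.size > 1 else math.nan,
    }
    return out


def metric_correlations(R: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations among the metric columns of R.

    Returns ``(r, p)`` DataFrames; correlations with a constant column are
    NaN.  Requires at least 3 plots.
    """
    if R.shape[0] < 3:
        raise DegenerateInputError("metric correlations need >= 3 plots")
    cols = list(R.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        xi = R.iloc[:, i].to_numpy(dtype=float)
        for j in range(i, k):
            xj = R.iloc[:, j].to_numpy(dtype=float)
            if xi.std() == 0 or xj.std() == 0:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
            else:
                res = stats.pearsonr(xi, xj)
                r[i, j] = r[j, i] = res.statistic
                p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )
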