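"""Species-patch raster I/O.

A sample plot is a small raster (by default 100 x 100 cells of 1 cm) in
which every cell holds the integer code of the single vascular-plant
species occupying it, with 0 reserved for bare substrate.  Two plain-text
formats are supported:

* ``long_csv`` — the canonical interchange format, one row per occupied
  cell with header ``plot_id,row,col,species_code``; unlisted cells are
  bare.
* ``ascii_grid`` — the ESRI ASCII grid dialect
  (``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value`` header
  followed by the matrix) for GIS interoperability; NODATA cells map to
  bare substrate on read.

Coordinates are 0-based ``(row, col)`` with row 0 at the top.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import GridParseError, ValidationError

__all__ = [
    "SpeciesGrid",
    "SpeciesRegistry",
    "read_grid",
    "write_grid",
]

TERRAIN_AGE_CLASSES = ("ta1", "ta2", "ta3")
COBBLE_CLASSES = ("ts1", "ts2", "ts3")

_ASCII_NODATA = -9999


@dataclass(frozen=True)
class SpeciesRegistry:
    """Bidirectional map between integer species codes and short labels.

    Code 0 is reserved for bare substrate and may not be registered.
    ``full_names`` optionally maps labels to binomials.
    """

    labels: Mapping[int, str]
    full_names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = list(self.labels)
        if 0 in codes:
            raise ValidationError("species code 0 is reserved for bare substrate")
        if any(c < 0 for c in codes):
            raise ValidationError("species codes must be positive integers")
        names = list(self.labels.values())
        if len(set(names)) != len(names):
            raise ValidationError("species labels must be unique")

    @property
    def codes(self) -> frozenset[int]:
        return frozenset(self.labels)

    def label(self, code: int) -> str:
        return self.labels[code]

    def code(self, label: str) -> int:
        for c, lab in self.labels.items():
            if lab == label:
                return c
        raise KeyError(label)

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "SpeciesRegistry":
        """Register labels with consecutive codes 1, 2, ..."""
        return cls({i + 1: lab for i, lab in enumerate(labels)})


@dataclass
class SpeciesGrid:
    """One plot's raster of species codes plus covariate metadata.

    ``values`` is an integer matrix (rows x cols); 0 means bare substrate.
    ``cell_size`` is the cell edge length in cm.  The terrain-age class
    (ta1-ta3, increasing time since deglaciation) and cobble-cover class
    (ts1-ts3, increasing cover of >64 mm stones) may be missing.
    """

    plot_id: str
    values: np.ndarray
    cell_size: float = 1.0
    terrain_age_class: str | None = None
    cobble_class: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValidationError("grid values must be a 2-D matrix with rows, cols >= 1")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.array_equal(self.values, self.values.astype(int)):
                raise ValidationError("grid values must be integer species codes")
            self.values = self.values.astype(int)
        if (self.values < 0).any():
            raise ValidationError("species codes must be >= 0")
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be > 0")
        if self.terrain_age_class is not None and self.terrain_age_class not in TERRAIN_AGE_CLASSES:
            raise ValidationError(f"unknown terrain-age class {self.terrain_age_class!r}")
        if self.cobble_class is not None and self.cobble_class not in COBBLE_CLASSES:
            raise ValidationError(f"unknown cobble-cover class {self.cobble_class!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def species_present(self) -> list[int]:
        codes = np.unique(self.values)
        return [int(c) for c in codes if c != 0]

    def validate_registry(self, registry: SpeciesRegistry) -> None:
        unknown = set(self.species_present()) - set(registry.codes)
        if unknown:
            raise ValidationError(
                f"plot {self.plot_id}: species codes not in registry: {sorted(unknown)}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpeciesGrid):
            return NotImplemented
        return (
            self.plot_id == other.plot_id
            and self.cell_size == other.cell_size
            and self.terrain_age_class == other.terrain_age_class
            and self.cobble_class == other.cobble_class
            and np.array_equal(self.values, other.values)
        )

    def copy(self) -> "SpeciesGrid":
        return dataclasses.replace(self, values=self.values.copy())


# ---------------------------------------------------------------------------
# readers / writers


def _read_long_csv(path: Path, shape: tuple[int, int], plot_id: str | None) -> SpeciesGrid:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message is informative
        raise GridParseError(f"{path}: {exc}") from exc
    required = {"plot_id", "row", "col", "species_code"}
    if not required.issubset(df.columns):
        raise GridParseError(
            f"{path}: long CSV must have header plot_id,row,col,species_code "
            f"(line 1: got {list(df.columns)})"
        )
    if df.empty and plot_id is None:
        raise GridParseError(f"{path}: empty long CSV and no plot_id given")
    if not df.empty:
        ids = df["plot_id"].unique()
        if len(ids) > 1:
            raise ValidationError(f"{path}: multiple plot_ids in one grid file: {list(ids)}")
        plot_id = plot_id or str(ids[0])
    dup = df.duplicated(subset=["row", "col"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate cell (row={int(first['row'])}, col={int(first['col'])})"
        )
    values = np.zeros(shape, dtype=int)
    rows = df["row"].to_numpy(dtype=int)
    cols = df["col"].to_numpy(dtype=int)
    if df.shape[0] and (
        rows.min() < 0 or cols.min() < 0 or rows.max() >= shape[0] or cols.max() >= shape[1]
    ):
        raise ValidationError(f"{path}: cell coordinates outside the {shape} grid")
    values[rows, cols] = df["species_code"].to_numpy(dtype=int)
    return SpeciesGrid(plot_id=str(plot_id), values=values)


def _read_ascii_grid(path: Path, plot_id: str | None) -> SpeciesGrid:
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise GridParseError(f"{path}: missing {key} in ASCII grid header (line {i + 1})")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = int(header.get("nodata_value", _ASCII_NODATA))
    body = [ln for ln in lines[i:] if ln.strip()]
    if len(body) != nrows:
        raise GridParseError(f"{path}: expected {nrows} data rows, found {len(body)}")
    try:
        values = np.array([[int(tok) for tok in ln.split()] for ln in body])
    except ValueError as exc:
        raise GridParseError(f"{path}: non-integer cell value ({exc})") from exc
    if values.shape != (nrows, ncols):
        raise GridParseError(f"{path}: data block is {values.shape}, header says {(nrows, ncols)}")
    values[values == nodata] = 0
    return SpeciesGrid(
        plot_id=plot_id or path.stem,
        values=values,
        cell_size=float(header["cellsize"]),
    )


def read_grid(
    path: str | Path,
    format: str = "long_csv",
    *,
    shape: tuple[int, int] = (100, 100),
    plot_id: str | None = None,
    registry: SpeciesRegistry | None = None,
) -> SpeciesGrid:
    """Read one plot's species-patch raster.

    Parameters
    ----------
    path : file path
    format : ``"long_csv"`` or ``"ascii_grid"``
    shape : grid shape used to materialise a long CSV (ignored for ASCII)
    plot_id : overrides the plot id recorded in the file / filename stem
    registry : if given, every nonzero code must be registered
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "long_csv":
        grid = _read_long_csv(path, shape, plot_id)
    elif format == "ascii_grid":
        grid = _read_ascii_grid(path, plot_id)
    else:
        raise ValueError(f"unknown grid format {format!r}")
    if registry is not None:
        grid.validate_registry(registry)
    return grid


def write_grid(grid: SpeciesGrid, path: str | Path, format: str = "long_csv") -> Path:
    """Write a grid in the named format; returns the path written."""
    path = Path(path)
    if format == "long_csv":
        rows, cols = np.nonzero(grid.values)
        df = pd.DataFrame(
            {
                "plot_id": grid.plot_id,
                "row": rows,
                "col": cols,
                "species_code": grid.values[rows, cols],
            }
        )
        df.to_csv(path, index=False)
    elif format == "ascii_grid":
        nrows, ncols = grid.shape
        header = (
            f"ncols {ncols}\n"
            f"nrows {nrows}\n"
            f"xllcorner 0\n"
            f"yllcorner 0\n"
            f"cellsize {grid.cell_size:g}\n"
            f"NODATA_value {_ASCII_NODATA}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            for row in grid.values:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
    else:
        raise ValueError(f"unknown grid format {format!r}")
    return path
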