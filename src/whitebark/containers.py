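"""Core in-memory containers shared across the pipeline.

The study operates on a local metric grid (row/col indices times a cell
size in metres) rather than a geographic CRS: the science needs elevation
structure, not projection handling.  Row 0 is the north edge; the grid
origin ``(x0, y0)`` is the lower-left (south-west) corner, matching the
ESRI ASCII grid convention used for on-disk rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MONTHS = np.arange(1, 13)
#: days per calendar month (non-leap; monthly climatology ignores leap days)
DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of the analysis raster grid.

    Cell membership uses half-open intervals: a point belongs to cell
    ``(i, j)`` iff ``x0 + j*cell <= x < x0 + (j+1)*cell`` and the analogous
    relation in y with row 0 at the north edge.  This rule is shared by the
    synthetic plot sampler and the occurrence collocation step so pixel
    assignment is bit-stable across modules.
    """

    rows: int
    cols: int
    cell_size_m: float = 800.0
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size_m / 1000.0) ** 2

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def xy_to_rowcol(self, x, y):
        """Map metric coordinates to (row, col) indices (vectorized)."""
        col = np.floor((np.asarray(x, float) - self.x0) / self.cell_size_m).astype(int)
        row_from_south = np.floor(
            (np.asarray(y, float) - self.y0) / self.cell_size_m
        ).astype(int)
        row = self.rows - 1 - row_from_south
        return row, col

    def rowcol_to_xy(self, row, col):
        """Cell-centre coordinates of (row, col)."""
        x = self.x0 + (np.asarray(col, float) + 0.5) * self.cell_size_m
        y = self.y0 + (self.rows - np.asarray(row, float) - 0.5) * self.cell_size_m
        return x, y

    def contains_rowcol(self, row, col):
        return (row >= 0) & (row < self.rows) & (col >= 0) & (col < self.cols)


#: climate variables carried by a ClimateCube
CLIMATE_VARS = ("tmin", "tmax", "tmean", "ppt", "tdew")


@dataclass
class ClimateCube:
    """Monthly climate rasters indexed (year, month, row, col).

    ``data[var]`` has shape ``(n_years, 12, rows, cols)``; ``years`` is the
    sorted array of calendar years covered.  Units: temperatures in degrees
    Celsius, precipitation in mm per month.
    """

    years: np.ndarray
    data: dict[str, np.ndarray]
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        if self.years.size == 0:
            raise ValueError("ClimateCube requires at least one year")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("ClimateCube years must be consecutive")
        expected = (self.years.size, 12, self.geometry.rows, self.geometry.cols)
        for var, arr in self.data.items():
            if arr.shape != expected:
                raise ValueError(
                    f"variable {var!r} has shape {arr.shape}, expected {expected}"
                )

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    def year_index(self, year: int) -> int:
        idx = int(np.searchsorted(self.years, year))
        if idx >= self.years.size or self.years[idx] != year:
            raise KeyError(f"year {year} not in cube ({self.years[0]}–{self.years[-1]})")
        return idx

    def subset_years(self, start: int, end: int) -> "ClimateCube":
        """Inclusive year-range view (copies the slices)."""
        i0, i1 = self.year_index(start), self.year_index(end)
        return ClimateCube(
            years=self.years[i0 : i1 + 1],
            data={v: a[i0 : i1 + 1] for v, a in self.data.items()},
            geometry=self.geometry,
        )


def concat_cubes(first: ClimateCube, second: ClimateCube) -> ClimateCube:
    """Splice two cubes along the year axis (e.g. history + future).

    The second cube must start exactly one year after the first ends and
    share grid geometry and variables.
    """
    if second.years[0] != first.years[-1] + 1:
        raise ValueError(
            f"cubes are not contiguous: {first.years[-1]} then {second.years[0]}"
        )
    if first.geometry != second.geometry:
        raise ValueError("cubes have different grid geometry")
    if set(first.data) != set(second.data):
        raise ValueError("cubes carry different variables")
    return ClimateCube(
        years=np.concatenate([first.years, second.years]),
        data={
            v: np.concatenate([first.data[v], second.data[v]], axis=0)
            for v in first.data
        },
        geometry=first.geometry,
    )
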