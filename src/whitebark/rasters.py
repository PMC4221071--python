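"""Plain-text raster I/O (ESRI ASCII grid).

The ASCII grid format keeps every artifact human-readable and
diff-able: a six-line header (ncols, nrows, xllcorner, yllcorner,
cellsize, NODATA_value) followed by rows of cell values north to south.
Values are written with 17 significant digits so float64 data and the
grid geometry round-trip bit-exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .containers import GridGeometry

__all__ = ["read_raster", "write_raster"]

_NODATA_DEFAULT = -9999.0


def write_raster(
    path: str | Path,
    array: np.ndarray,
    geometry: GridGeometry,
    nodata: float = _NODATA_DEFAULT,
) -> None:
    """Write a 2-D raster as an ESRI ASCII grid; NaN becomes ``nodata``."""
    arr = np.asarray(array, dtype=float)
    if arr.shape != geometry.shape:
        raise ValueError(f"array shape {arr.shape} != geometry {geometry.shape}")
    out = np.where(np.isnan(arr), nodata, arr)
    header = (
        f"ncols {geometry.cols}\n"
        f"nrows {geometry.rows}\n"
        f"xllcorner {geometry.x0!r}\n"
        f"yllcorner {geometry.y0!r}\n"
        f"cellsize {geometry.cell_size_m!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.17g")


def read_raster(path: str | Path) -> tuple[np.ndarray, GridGeometry, float]:
    """Read an ESRI ASCII grid: (array with NaN at nodata, geometry, nodata)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh, ndmin=2)
    geometry = GridGeometry(
        rows=int(header["nrows"]),
        cols=int(header["ncols"]),
        cell_size_m=header["cellsize"],
        x0=header["xllcorner"],
        y0=header["yllcorner"],
    )
    if data.shape != geometry.shape:
        raise ValueError(f"data shape {data.shape} does not match header {geometry.shape}")
    nodata = header["nodata_value"]
    data = np.where(data == nodata, np.nan, data)
    return data, geometry, nodata
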