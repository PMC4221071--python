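"""Assembly of multi-source occurrence plots into per-pixel samples.

Raw survey records (one row per field plot, possibly from several
inventory programmes) pass through three quality steps before model
fitting:

* an adult filter — presences count only when the recorded stem is at
  least 20 cm DBH, so that the modelled envelope reflects established,
  reproductively capable individuals;
* an elevation cull — records whose field-recorded elevation disagrees
  with the DEM by more than 300 m are discarded (a guard against plot
  coordinate error);
* pixel collocation — all records falling in the same predictor pixel
  collapse to a single sample, with any presence overriding absences.
  This corrects false absences: a gridded-inventory absence collocated
  with a targeted-survey presence becomes a presence.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import GridGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "filter_adults",
    "cull_by_elevation",
    "collocate_to_pixels",
    "assemble",
]


def filter_adults(records: pd.DataFrame, dbh_min_cm: float = 20.0) -> pd.DataFrame:
    """Keep presences only when DBH >= ``dbh_min_cm`` (inclusive).

    Absence records are unaffected — the filter concerns what counts as
    an established presence, not where surveys happened.
    """
    keep = (records["present"] == 0) | (records["dbh_cm"] >= dbh_min_cm)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("adult filter dropped %d sub-adult presence records", dropped)
    return records.loc[keep].reset_index(drop=True)


def cull_by_elevation(
    records: pd.DataFrame, dem: np.ndarray, geometry: GridGeometry, max_diff_m: float = 300.0
) -> pd.DataFrame:
    """Drop records whose recorded elevation differs from the DEM at the
    record's pixel by strictly more than ``max_diff_m`` (a 300 m
    disagreement is kept; 300.001 m is dropped)."""
    row, col = geometry.xy_to_rowcol(records["x"].to_numpy(), records["y"].to_numpy())
    inside = geometry.contains_rowcol(row, col)
    if not inside.all():
        bad = records.loc[~inside, "plot_id"].tolist()
        raise ValueError(f"records outside DEM extent: {bad[:5]}")
    diff = np.abs(records["elev_m"].to_numpy() - dem[row, col])
    keep = diff <= max_diff_m
    dropped = int((~keep).sum())
    if dropped:
        logger.info("elevation cull dropped %d records (> %g m from DEM)", dropped, max_diff_m)
    return records.loc[keep].reset_index(drop=True)


def collocate_to_pixels(records: pd.DataFrame, geometry: GridGeometry) -> pd.DataFrame:
    """Reduce records to one presence/absence sample per predictor pixel.

    A pixel is a presence if ANY contributing record is a presence
    (presence overrides absence — the false-absence correction); it is an
    absence only when every record in it is an absence.

    Returns a DataFrame with columns ``pixel_row, pixel_col, present,
    plot_ids`` (contributing plot ids, comma-joined), sorted row-major.
    """
    row, col = geometry.xy_to_rowcol(records["x"].to_numpy(), records["y"].to_numpy())
    inside = geometry.contains_rowcol(row, col)
    if not inside.all():
        raise ValueError("records outside grid extent")
    df = records.assign(pixel_row=row, pixel_col=col)
    grouped = (
        df.groupby(["pixel_row", "pixel_col"], sort=True)
        .agg(
            present=("present", "max"),
            plot_ids=("plot_id", lambda s: ",".join(map(str, s))),
            n_records=("plot_id", "size"),
        )
        .reset_index()
    )
    return grouped


def assemble(
    records: pd.DataFrame,
    dem: np.ndarray,
    geometry: GridGeometry,
    dbh_min_cm: float = 20.0,
    max_elev_diff_m: float = 300.0,
) -> pd.DataFrame:
    """Full assembly: adult filter, elevation cull, pixel collocation."""
    filtered = filter_adults(records, dbh_min_cm)
    culled = cull_by_elevation(filtered, dem, geometry, max_elev_diff_m)
    return collocate_to_pixels(culled, geometry)
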