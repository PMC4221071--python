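"""Projection of the fitted envelope under future climate ensembles.

For each (scenario, member, target year) the pipeline computes 30-year
trailing-window normals of the covariates (splicing the historical cube
in front of the future cube where the window predates it), predicts the
presence-probability surface with the fitted ensemble, thresholds it to
a binary suitability map, and summarizes suitable area, the percentage
of the historical reference area, and the elevation distribution of
suitable cells.  Ensemble statistics are always taken across members
AFTER each member has been projected — never by averaging member
climates first — so interannual and inter-member variability survive
the nonlinearity of the classifier.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ClimateCube, GridGeometry, concat_cubes

logger = logging.getLogger(__name__)

__all__ = [
    "moving_window_normals",
    "predict_surface",
    "binary_map",
    "suitable_area",
    "percent_reference",
    "elevation_stats",
    "ensemble_summary",
]


def moving_window_normals(
    cube: ClimateCube,
    target_year: int,
    window: int = 30,
    history: ClimateCube | None = None,
) -> tuple[ClimateCube, tuple[int, int]]:
    """Trailing-window subset ending at ``target_year``.

    Returns the cube restricted to ``[target_year - window + 1,
    target_year]`` plus that year range.  When the window predates the
    cube and a ``history`` cube is supplied, the two are spliced; years
    must then be contiguous across the splice.
    """
    start = target_year - window + 1
    full = cube
    if history is not None and start < cube.years[0]:
        full = concat_cubes(history.subset_years(int(history.years[0]), int(cube.years[0]) - 1), cube)
    if start < full.years[0] or target_year > full.years[-1]:
        raise ValueError(
            f"window {start}–{target_year} not covered by years "
            f"{full.years[0]}–{full.years[-1]}"
        )
    return full.subset_years(start, target_year), (start, target_year)


def predict_surface(model, normal_rasters: dict[str, np.ndarray]) -> np.ndarray:
    """Per-cell presence-vote fraction from covariate normal rasters.

    NaN cells in any covariate propagate to NaN in the surface (masked
    terrain stays masked).
    """
    missing = [c for c in model.covariate_names if c not in normal_rasters]
    if missing:
        raise KeyError(f"missing covariate rasters: {missing}")
    first = normal_rasters[model.covariate_names[0]]
    shape = first.shape
    X = np.column_stack(
        [np.asarray(normal_rasters[c], float).ravel() for c in model.covariate_names]
    )
    valid = ~np.isnan(X).any(axis=1)
    probs = np.full(X.shape[0], np.nan)
    if valid.any():
        probs[valid] = model.predict_proba(X[valid])
    return probs.reshape(shape)


def binary_map(prob_raster: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold a probability surface: cell >= threshold -> 1, else 0;
    NaN stays NaN (float raster with values {0, 1, NaN})."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    prob = np.asarray(prob_raster, dtype=float)
    out = np.where(prob >= threshold, 1.0, 0.0)
    out[np.isnan(prob)] = np.nan
    return out


def suitable_area(presence_raster: np.ndarray, cell_area_km2: float) -> float:
    """Total suitable area: count of presence cells times cell area."""
    if cell_area_km2 <= 0:
        raise ValueError("cell area must be positive")
    return float(np.nansum(presence_raster == 1.0) * cell_area_km2)


def percent_reference(area_km2: float, reference_area_km2: float) -> float:
    """Area as a percentage of the historical-reference suitable area
    (may exceed 100 when a member projects expansion)."""
    if reference_area_km2 <= 0:
        raise ValueError("reference area must be positive")
    return 100.0 * area_km2 / reference_area_km2


def elevation_stats(
    presence_raster: np.ndarray, dem: np.ndarray
) -> tuple[float, float, float]:
    """(mean, 2.5th, 97.5th percentile) elevation of suitable cells.

    Percentiles use linear interpolation.  With no suitable cells the
    stats are undefined: returns NaNs with a warning.
    """
    mask = presence_raster == 1.0
    if not mask.any():
        logger.warning("no suitable cells; elevation stats undefined")
        return (np.nan, np.nan, np.nan)
    elev = np.asarray(dem, float)[mask]
    lo, hi = np.percentile(elev, [2.5, 97.5], method="linear")
    return (float(elev.mean()), float(lo), float(hi))


def ensemble_summary(series: pd.DataFrame) -> pd.DataFrame:
    """Across-member mean and sample SD of percent reference area.

    ``series`` is the tidy projection table with columns ``scenario,
    member, year, pct_reference_area`` (one row per member-year).
    Returns one row per (scenario, year) with ``mean_pct`` and ``sd_pct``
    (sample standard deviation, n - 1 denominator).
    """
    n_members = series.groupby("scenario")["member"].nunique()
    if (n_members < 2).any():
        raise ValueError("ensemble summary requires at least 2 members per scenario")
    out = (
        series.groupby(["scenario", "year"])["pct_reference_area"]
        .agg(mean_pct="mean", sd_pct=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return out
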