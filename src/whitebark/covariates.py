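"""Climate-normal covariates and low-collinearity variable selection.

Covariates are 30-year monthly normals of climate and water-balance
variables named ``<var><month>`` (``tmax7`` = mean July maximum
temperature, ``pack4`` = mean April snow water equivalent).  Selection
runs in two passes: a PCA proxy filter on the correlation matrix keeps
one representative variable per retained component, then a greedy
pairwise-correlation filter in physiological-precedence order enforces a
maximum absolute Pearson r between every pair of kept variables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import GridGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PRECEDENCE",
    "compute_normals",
    "stack_normals",
    "extract_at_pixels",
    "pca_proxy_filter",
    "correlation_filter",
    "select_covariates",
]

#: physiological precedence order of the candidate variable-month normals:
#: winter cold (tmin1), spring atmospheric demand (vpd3), spring moisture
#: (ppt4), spring snowpack (pack4), summer heat (tmax7), summer water use
#: (aet7), late-summer demand (pet8), autumn moisture (ppt9)
DEFAULT_PRECEDENCE = ["tmin1", "vpd3", "ppt4", "pack4", "tmax7", "aet7", "pet8", "ppt9"]


def compute_normals(
    stack: np.ndarray, years: np.ndarray, window: tuple[int, int]
) -> np.ndarray:
    """Mean over the years of ``window`` (inclusive) per calendar month.

    ``stack`` has shape ``(n_years, 12, rows, cols)``; the result is
    ``(12, rows, cols)``.
    """
    years = np.asarray(years)
    y0, y1 = window
    if y0 < years[0] or y1 > years[-1] or y0 > y1:
        raise ValueError(
            f"window {window} outside available years {years[0]}–{years[-1]}"
        )
    i0 = int(np.searchsorted(years, y0))
    i1 = int(np.searchsorted(years, y1))
    return stack[i0 : i1 + 1].mean(axis=0)


def stack_normals(
    monthly_stacks: dict[str, np.ndarray],
    years: np.ndarray,
    window: tuple[int, int],
    variables: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Compute named variable-month normal rasters from monthly stacks.

    ``monthly_stacks`` maps a base variable name (``tmax``, ``pack`` ...)
    to a ``(n_years, 12, rows, cols)`` array.  Returns a dict keyed by
    ``<var><month>`` covering all 12 months, or only the requested
    ``variables`` (e.g. ``["tmax7", "pack4"]``).
    """
    out: dict[str, np.ndarray] = {}
    if variables is None:
        for var, stack in monthly_stacks.items():
            normals = compute_normals(stack, years, window)
            for m in range(12):
                out[f"{var}{m + 1}"] = normals[m]
        return out
    for name in variables:
        var, month = _split_name(name)
        if var not in monthly_stacks:
            raise KeyError(f"no monthly stack for variable {var!r} (from {name!r})")
        normals = compute_normals(monthly_stacks[var], years, window)
        out[name] = normals[month - 1]
    return out


def _split_name(name: str) -> tuple[str, int]:
    """Split ``tmax7`` -> (``tmax``, 7); month suffix is 1–12."""
    i = len(name)
    while i > 0 and name[i - 1].isdigit():
        i -= 1
    if i == len(name) or i == 0:
        raise ValueError(f"covariate name {name!r} lacks a <var><month> form")
    month = int(name[i:])
    if not 1 <= month <= 12:
        raise ValueError(f"covariate name {name!r} has month outside 1–12")
    return name[:i], month


def extract_at_pixels(
    normal_rasters: dict[str, np.ndarray], samples: pd.DataFrame
) -> pd.DataFrame:
    """Build the covariate matrix: one row per pixel sample, one column
    per named normal raster, preserving the row order of ``samples``."""
    rows = samples["pixel_row"].to_numpy()
    cols = samples["pixel_col"].to_numpy()
    out = {}
    for name, raster in normal_rasters.items():
        if (
            rows.min() < 0
            or cols.min() < 0
            or rows.max() >= raster.shape[0]
            or cols.max() >= raster.shape[1]
        ):
            raise IndexError(f"sample pixel outside raster {name!r}")
        out[name] = raster[rows, cols]
    matrix = pd.DataFrame(out, index=samples.index)
    if matrix.isna().any().any():
        raise ValueError("covariate matrix contains missing values")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate covariate names")
    return matrix


def pca_proxy_filter(matrix: pd.DataFrame, variance_target: float = 0.95) -> list[str]:
    """PCA proxy selection of candidate covariates.

    Standardizes columns (PCA on the correlation matrix), retains the
    leading components that together explain ``variance_target`` of the
    variance, and for each retained component keeps the not-yet-kept
    variable with the largest absolute loading.  Constant columns are
    dropped with a warning before the decomposition.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 columns for the PCA proxy filter")
    sd = matrix.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        logger.warning("dropping constant columns before PCA: %s", constant)
        matrix = matrix.drop(columns=constant)
    z = (matrix - matrix.mean()) / matrix.std(ddof=0)
    pca = PCA()
    pca.fit(z.to_numpy())
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cumvar, variance_target) + 1)
    n_keep = min(n_keep, len(cumvar))
    kept: list[str] = []
    names = list(matrix.columns)
    for comp in pca.components_[:n_keep]:
        order = np.argsort(-np.abs(comp))
        for j in order:
            if names[j] not in kept:
                kept.append(names[j])
                break
    return kept


def correlation_filter(
    matrix: pd.DataFrame,
    candidates: list[str],
    r_max: float = 0.75,
    precedence: list[str] | None = None,
) -> list[str]:
    """Greedy collinearity filter in precedence order.

    Walking the candidates from highest physiological precedence to
    lowest, a variable is kept iff its absolute Pearson correlation with
    every already-kept variable is at most ``r_max``.  Candidates absent
    from the precedence list follow it in their given order.
    """
    if not candidates:
        raise ValueError("no candidate variables to filter")
    missing = [c for c in candidates if c not in matrix.columns]
    if missing:
        raise KeyError(f"candidates not in matrix: {missing}")
    precedence = precedence if precedence is not None else DEFAULT_PRECEDENCE
    rank = {name: i for i, name in enumerate(precedence)}
    ordered = sorted(
        candidates, key=lambda c: (rank.get(c, len(precedence)), candidates.index(c))
    )
    corr = matrix[ordered].corr(method="pearson")
    kept: list[str] = []
    for name in ordered:
        if all(abs(corr.loc[name, k]) <= r_max for k in kept):
            kept.append(name)
    return kept


def select_covariates(
    matrix: pd.DataFrame,
    variance_target: float = 0.95,
    r_max: float = 0.75,
    precedence: list[str] | None = None,
) -> list[str]:
    """Two-pass selection: PCA proxies, then the correlation filter."""
    candidates = pca_proxy_filter(matrix, variance_target)
    return correlation_filter(matrix, candidates, r_max, precedence)
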