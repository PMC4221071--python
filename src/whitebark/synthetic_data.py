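"""Synthetic study system: terrain, monthly climate, soils, a virtual
species, and a pseudo-GCM future ensemble.

The generators emulate the statistical structure the downstream analysis
assumes — an elevation-lapsed monthly climate with regional interannual
anomalies, thin high-elevation soils, a cold-limited virtual species whose
presence probability is a known logistic function of July maximum
temperature and April snowpack, and an ensemble of future trajectories
with divergent member-specific warming trends — so that every stage of
the pipeline can be exercised and validated against known truth without
any external data.

Every generator is a pure function of (config, seed): fixed seed implies
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import ScenarioSpec, SyntheticConfig
from .containers import CLIMATE_VARS, ClimateCube, GridGeometry

__all__ = [
    "VirtualSpeciesTruth",
    "make_terrain",
    "make_climate",
    "make_soil",
    "sample_virtual_species",
    "make_gcm_ensemble",
    "seasonal_tmean",
    "seasonal_ppt",
]


def grid_geometry(cfg: SyntheticConfig) -> GridGeometry:
    return GridGeometry(cfg.grid_rows, cfg.grid_cols, cfg.cell_size_m)


# ---------------------------------------------------------------------------
# terrain


def make_terrain(
    cfg: SyntheticConfig,
    bumps: list[tuple[float, float, float, float]] | None = None,
    plane_amplitude: float | None = None,
) -> np.ndarray:
    """Generate a smooth ridged DEM (metres) on the config grid.

    The surface is a sloping plane plus a sum of 2-D Gaussian bumps,
    rescaled affinely to span ``cfg.elev_range_m`` exactly.

    Parameters
    ----------
    bumps
        Optional explicit list of ``(row, col, amplitude, sigma_cells)``
        mountain bumps; drawn from the config seed when omitted.
    plane_amplitude
        Relative height of the background north-south slope (default 0.3
        of a unit bump); pass 0 for a flat background.
    """
    if cfg.grid_rows < 8 or cfg.grid_cols < 8:
        raise ValueError("grid dims must be at least 8x8")
    rng = np.random.default_rng([cfg.seed, 101])
    rows, cols = cfg.grid_rows, cfg.grid_cols
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    if bumps is None:
        bumps = [
            (
                rng.uniform(0.15 * rows, 0.85 * rows),
                rng.uniform(0.15 * cols, 0.85 * cols),
                rng.uniform(0.6, 1.0),
                rng.uniform(0.08, 0.2) * min(rows, cols),
            )
            for _ in range(cfg.n_bumps)
        ]
    if plane_amplitude is None:
        plane_amplitude = 0.3
    surface = plane_amplitude * (1.0 - rr / max(rows - 1, 1))
    for br, bc, amp, sigma in bumps:
        surface += amp * np.exp(-((rr - br) ** 2 + (cc - bc) ** 2) / (2 * sigma**2))
    lo, hi = cfg.elev_range_m
    smin, smax = surface.min(), surface.max()
    if smax == smin:  # degenerate flat surface
        return np.full((rows, cols), 0.5 * (lo + hi))
    return lo + (surface - smin) * (hi - lo) / (smax - smin)


# ---------------------------------------------------------------------------
# climate


def seasonal_tmean(cfg: SyntheticConfig, elev_m, month: int):
    """Deterministic (noise-free) monthly mean temperature, degC.

    Sinusoidal seasonal cycle peaking in July plus a linear elevation
    lapse whose magnitude weakens in winter (``winter_lapse_factor``,
    emulating persistent valley inversions).  This is the closed form
    the generated climate fluctuates around, used directly by recovery
    tests.
    """
    seasonal = cfg.seasonal_amplitude_c * np.cos(2 * np.pi * (month - 7) / 12.0)
    w = winter_weight(month)
    lapse = cfg.lapse_rate_c_per_km * (cfg.winter_lapse_factor * w + (1.0 - w))
    return (
        cfg.sea_level_mean_temp_c + lapse * np.asarray(elev_m, float) / 1000.0 + seasonal
    )


def seasonal_ppt(cfg: SyntheticConfig, elev_m, month: int):
    """Deterministic monthly precipitation (mm): orographic increase with
    elevation and a seasonal cycle peaking in May."""
    shape = 1.0 + cfg.ppt_seasonal_amplitude * np.cos(2 * np.pi * (month - 5) / 12.0)
    base = cfg.base_ppt_mm_per_month + cfg.orographic_ppt_mm_per_m * np.asarray(
        elev_m, float
    )
    return np.maximum(base * shape, 0.0)


def make_heterogeneity(cfg: SyntheticConfig, dem: np.ndarray) -> dict[str, np.ndarray]:
    """Spatial climate heterogeneity beyond the elevation lapse.

    Returns a dict of smooth anomaly fields, each constructed orthogonal
    to the DEM (so the lapse and the anomaly components of the climate
    are separately controllable by design):

    * ``winter_temp_c`` — winter cold-air pooling/continentality offset,
      sd ``winter_heterogeneity_multiplier * temp_heterogeneity_c``;
    * ``summer_temp_c`` — summer slope-heating offset, sd
      ``temp_heterogeneity_c``;
    * ``winter_ppt_factor`` / ``summer_ppt_factor`` — multiplicative
      precipitation patterns (snowfall vs. convective season), mean ~1,
      relative sd ``ppt_heterogeneity``;
    * ``dew_depression_c`` — spatially varying dewpoint depression
      (humid vs. arid cells), mean ``dewpoint_depression_c``.

    Monthly values interpolate sinusoidally between the winter and
    summer members of each pair.  These fields decorrelate temperature,
    moisture, and humidity covariates from raw elevation and from each
    other, as real mountain climates do; without them every covariate
    would be an exact affine function of elevation and the generating
    envelope would not be identifiable.
    """
    rng = np.random.default_rng([cfg.seed, 206])
    rows, cols = cfg.grid_rows, cfg.grid_cols
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    dem_z = (dem - dem.mean()).ravel()
    dem_z /= np.linalg.norm(dem_z) or 1.0

    def smooth_field() -> np.ndarray:
        f = np.zeros((rows, cols))
        for _ in range(12):
            br = rng.uniform(0, rows)
            bc = rng.uniform(0, cols)
            amp = rng.uniform(-1.0, 1.0)
            sigma = rng.uniform(0.1, 0.3) * min(rows, cols)
            f += amp * np.exp(-((rr - br) ** 2 + (cc - bc) ** 2) / (2 * sigma**2))
        # west-east gradient (prevailing-wind rain shadow / continentality)
        f += rng.uniform(-0.6, 0.6) * (cc / max(cols - 1, 1) - 0.5)
        flat = f.ravel()
        flat = flat - flat @ dem_z * dem_z  # remove the elevation component
        flat -= flat.mean()
        return (flat / (flat.std() or 1.0)).reshape(rows, cols)  # mean 0, unit sd

    t_winter_sd = cfg.winter_heterogeneity_multiplier * cfg.temp_heterogeneity_c
    return {
        "winter_temp_c": t_winter_sd * smooth_field(),
        "summer_temp_c": cfg.temp_heterogeneity_c * smooth_field(),
        "winter_ppt_factor": np.maximum(
            1.0 + cfg.ppt_heterogeneity * smooth_field(), 0.2
        ),
        "summer_ppt_factor": np.maximum(
            1.0 + cfg.ppt_heterogeneity * smooth_field(), 0.2
        ),
        "dew_depression_c": np.maximum(
            cfg.dewpoint_depression_c
            + cfg.dewpoint_depression_heterogeneity_c * smooth_field(),
            0.5,
        ),
    }


def winter_weight(month: int) -> float:
    """Sinusoidal winter weight: 1 in January, 0 in July."""
    return 0.5 * (1.0 + np.cos(2 * np.pi * (month - 1) / 12.0))


def _year_anomalies(cfg: SyntheticConfig, n_years: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Regional (spatially constant) per-year anomalies: additive degC for
    temperature, multiplicative factor for precipitation."""
    t_anom = rng.normal(0.0, cfg.interannual_temp_sd_c, size=n_years)
    p_anom = np.maximum(1.0 + rng.normal(0.0, cfg.interannual_ppt_cv, size=n_years), 0.2)
    if cfg.interannual_temp_sd_c == 0:
        t_anom = np.zeros(n_years)
    if cfg.interannual_ppt_cv == 0:
        p_anom = np.ones(n_years)
    return t_anom, p_anom


def make_climate(
    dem: np.ndarray, cfg: SyntheticConfig, years: tuple[int, int] | None = None
) -> ClimateCube:
    """Generate the historical monthly climate cube over ``years``.

    tmean follows :func:`seasonal_tmean` plus the spatial heterogeneity
    offset of :func:`make_heterogeneity` and a spatially constant
    per-year Gaussian anomaly; tmax/tmin are tmean +/- the diurnal half
    range; dewpoint is tmean minus a fixed depression; precipitation
    follows :func:`seasonal_ppt` times the heterogeneity factor and a
    multiplicative per-year anomaly.  The physical ordering
    tmin <= tmean <= tmax and tdew <= tmean holds by construction.
    """
    years = years if years is not None else cfg.years
    y0, y1 = years
    if y0 > y1:
        raise ValueError("years range is empty")
    n_years = y1 - y0 + 1
    rng = np.random.default_rng([cfg.seed, 202])
    t_anom, p_anom = _year_anomalies(cfg, n_years, rng)
    het = make_heterogeneity(cfg, dem)

    geom = grid_geometry(cfg)
    shape = (n_years, 12, cfg.grid_rows, cfg.grid_cols)
    tmean = np.empty(shape)
    ppt = np.empty(shape)
    for m in range(12):
        w = winter_weight(m + 1)
        offset = w * het["winter_temp_c"] + (1.0 - w) * het["summer_temp_c"]
        ppt_factor = w * het["winter_ppt_factor"] + (1.0 - w) * het["summer_ppt_factor"]
        tmean[:, m] = (seasonal_tmean(cfg, dem, m + 1) + offset)[None] + t_anom[
            :, None, None
        ]
        ppt[:, m] = (seasonal_ppt(cfg, dem, m + 1) * ppt_factor)[None] * p_anom[
            :, None, None
        ]
    data = {
        "tmean": tmean,
        "tmin": tmean - cfg.diurnal_half_range_c,
        "tmax": tmean + cfg.diurnal_half_range_c,
        "tdew": tmean - het["dew_depression_c"][None, None],
        "ppt": ppt,
    }
    return ClimateCube(years=np.arange(y0, y1 + 1), data=data, geometry=geom)


# ---------------------------------------------------------------------------
# soils


def make_soil(dem: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Soil available water capacity (mm): deep valley soils thinning
    towards bare alpine terrain, with mild multiplicative texture noise."""
    rng = np.random.default_rng([cfg.seed, 303])
    lo, hi = cfg.elev_range_m
    rel = (dem - lo) / (hi - lo)  # 0 valley floor .. 1 highest peak
    awc = cfg.awc_base_mm - (cfg.awc_base_mm - cfg.awc_min_mm) * rel
    awc = awc * rng.uniform(0.95, 1.05, size=dem.shape)
    return np.maximum(awc, cfg.awc_min_mm * 0.5)


# ---------------------------------------------------------------------------
# virtual species


@dataclass(frozen=True)
class VirtualSpeciesTruth:
    """The generating bioclimatic envelope of the virtual species.

    Presence probability at a cell is ``logistic(beta0 + beta_tmax7 * z_t
    + beta_pack4 * z_p)`` where ``z_t`` is the July maximum temperature
    normal and ``z_p`` is ``log1p`` of the April snow-water-equivalent
    normal, each standardized by the recorded domain mean/sd.  The log
    makes the snowpack response saturating — a deep pack is no better
    than an adequate one, and perennial-ice cells do not dominate the
    scale — while leaving tree-ensemble recovery unaffected (trees are
    invariant to monotone covariate transforms).  A cold-limited,
    snow-associated species requires ``beta_tmax7 < 0`` and
    ``beta_pack4 > 0``.
    """

    beta0: float
    beta_tmax7: float
    beta_pack4: float
    tmax7_mean: float = 0.0
    tmax7_sd: float = 1.0
    pack4_mean: float = 0.0
    pack4_sd: float = 1.0

    def __post_init__(self) -> None:
        if not self.beta_tmax7 < 0:
            raise ValueError("beta_tmax7 must be negative (cold-limited species)")
        if not self.beta_pack4 > 0:
            raise ValueError("beta_pack4 must be positive (snow-associated species)")

    @classmethod
    def from_domain(
        cls, cfg: SyntheticConfig, tmax7: np.ndarray, pack4: np.ndarray
    ) -> "VirtualSpeciesTruth":
        """Standardize the betas against the supplied covariate rasters."""
        log_pack = np.log1p(np.asarray(pack4, float))
        return cls(
            beta0=cfg.beta0,
            beta_tmax7=cfg.beta_tmax7,
            beta_pack4=cfg.beta_pack4,
            tmax7_mean=float(np.mean(tmax7)),
            tmax7_sd=float(np.std(tmax7)) or 1.0,
            pack4_mean=float(np.mean(log_pack)),
            pack4_sd=float(np.std(log_pack)) or 1.0,
        )

    def linear_predictor(self, tmax7, pack4):
        zt = (np.asarray(tmax7, float) - self.tmax7_mean) / self.tmax7_sd
        zp = (np.log1p(np.asarray(pack4, float)) - self.pack4_mean) / self.pack4_sd
        return self.beta0 + self.beta_tmax7 * zt + self.beta_pack4 * zp

    def presence_probability(self, tmax7, pack4):
        return expit(self.linear_predictor(tmax7, pack4))


PLOT_COLUMNS = ["plot_id", "x", "y", "elev_m", "dbh_cm", "present", "source"]


def sample_virtual_species(
    covariates: dict[str, np.ndarray],
    truth: VirtualSpeciesTruth,
    dem: np.ndarray,
    geometry: GridGeometry,
    n_plots: int,
    seed: int,
    adult_fraction: float = 0.85,
    false_absence_fraction: float = 0.10,
    gross_elev_error_fraction: float = 0.02,
) -> pd.DataFrame:
    """Sample survey plots of the virtual species.

    Plots are placed at uniformly random cells (without replacement while
    the grid allows it) with within-cell coordinate jitter.  Presence is
    Bernoulli in the truth envelope probability at the plot's cell.  DBH
    for presences is drawn so that ``adult_fraction`` of them are >= 20 cm
    (sub-adults below); absences carry DBH 0.  A ``false_absence_fraction``
    of the true presences is recorded as absent in the primary inventory
    source while a collocated second-source presence record is appended,
    so the downstream collocation correction has a measurable effect.  A
    small fraction of plots receives a gross elevation measurement error
    (well beyond the 300 m cull) to exercise the elevation filter.

    Returns a DataFrame with the plot schema plus ``attrs``:
    ``n_false_absences`` and ``true_present`` (the latent truth per plot).
    """
    if n_plots < 20:
        raise ValueError("n_plots must be at least 20")
    for key in ("tmax7", "pack4"):
        if key not in covariates:
            raise KeyError(f"covariates must include {key!r}")
    rng = np.random.default_rng([seed, 404])
    n_cells = geometry.rows * geometry.cols
    replace = n_plots > n_cells
    flat = rng.choice(n_cells, size=n_plots, replace=replace)
    row, col = np.unravel_index(flat, geometry.shape)
    x, y = geometry.rowcol_to_xy(row, col)
    x = x + rng.uniform(-0.45, 0.45, n_plots) * geometry.cell_size_m
    y = y + rng.uniform(-0.45, 0.45, n_plots) * geometry.cell_size_m

    p = truth.presence_probability(
        covariates["tmax7"][row, col], covariates["pack4"][row, col]
    )
    present = (rng.random(n_plots) < p).astype(int)
    true_present = present.copy()

    # recorded elevation = DEM value + measurement noise (+ rare gross error)
    elev = dem[row, col] + rng.normal(0.0, 25.0, n_plots)
    gross = rng.random(n_plots) < gross_elev_error_fraction
    elev[gross] += rng.choice([-1.0, 1.0], gross.sum()) * rng.uniform(
        350.0, 900.0, gross.sum()
    )

    dbh = np.zeros(n_plots)
    is_pres = present == 1
    adult = rng.random(n_plots) < adult_fraction
    dbh[is_pres & adult] = rng.uniform(20.0, 80.0, int((is_pres & adult).sum()))
    dbh[is_pres & ~adult] = rng.uniform(5.0, 19.9, int((is_pres & ~adult).sum()))

    records = pd.DataFrame(
        {
            "plot_id": [f"FIA-{i:05d}" for i in range(n_plots)],
            "x": x,
            "y": y,
            "elev_m": elev,
            "dbh_cm": dbh.round(1),
            "present": present,
            "source": "FIA",
        }
    )

    # falsify a fraction of adult presences into FIA absences, each
    # corrected by a collocated second-source presence in the same pixel
    candidates = np.flatnonzero((records["present"] == 1) & (records["dbh_cm"] >= 20.0))
    n_false = int(round(false_absence_fraction * candidates.size))
    falsified = rng.choice(candidates, size=n_false, replace=False) if n_false else []
    extra = []
    for k, i in enumerate(sorted(falsified)):
        records.loc[i, ["present", "dbh_cm"]] = [0, 0.0]
        jx = x[i] + rng.uniform(-0.04, 0.04) * geometry.cell_size_m
        jy = y[i] + rng.uniform(-0.04, 0.04) * geometry.cell_size_m
        extra.append(
            {
                "plot_id": f"WLIS-{k:05d}",
                "x": jx,
                "y": jy,
                "elev_m": dem[row[i], col[i]] + rng.normal(0.0, 25.0),
                "dbh_cm": round(rng.uniform(20.0, 80.0), 1),
                "present": 1,
                "source": "WLIS",
            }
        )
    if extra:
        records = pd.concat([records, pd.DataFrame(extra)], ignore_index=True)
    records.attrs["n_false_absences"] = int(n_false)
    records.attrs["true_present"] = np.concatenate(
        [true_present, np.ones(len(extra), dtype=int)]
    )
    return records


# ---------------------------------------------------------------------------
# pseudo-GCM ensemble


def make_gcm_ensemble(
    base: ClimateCube,
    cfg: SyntheticConfig,
    scenarios: dict[str, ScenarioSpec] | None = None,
) -> dict[str, list[ClimateCube]]:
    """Generate the future pseudo-GCM ensemble per forcing scenario.

    Each member starts from the base-cube monthly climatology and adds a
    member-specific linear temperature trend (drawn around the scenario's
    ensemble-mean trend), an additive monthly precipitation drift, and a
    spatially constant AR(1) interannual anomaly.  Trends are anchored at
    the reference year (first future year minus one) and persist to the
    final year.  Members of the same scenario share the climatology but
    have independent trend draws and noise, mimicking the divergence of a
    down-scaled multi-model ensemble.
    """
    if cfg.n_members < 2:
        raise ValueError("n_members must be at least 2")
    scenarios = scenarios if scenarios is not None else cfg.scenarios
    for name in scenarios:
        if name not in cfg.scenarios:
            raise KeyError(f"unknown scenario {name!r}")
    y0, y1 = cfg.future_years
    n_years = y1 - y0 + 1
    ref_year = y0 - 1
    years_axis = np.arange(y0, y1 + 1)
    decades = (years_axis - ref_year) / 10.0

    clim = {v: base.data[v].mean(axis=0) for v in CLIMATE_VARS}  # (12, r, c)

    out: dict[str, list[ClimateCube]] = {}
    for s_idx, (name, spec) in enumerate(sorted(scenarios.items())):
        members = []
        for m in range(cfg.n_members):
            rng = np.random.default_rng([cfg.seed, 505, s_idx, m])
            trend = rng.normal(spec.temp_trend_c_per_decade, spec.temp_trend_sd)
            drift = rng.normal(spec.ppt_drift_mm_per_decade, spec.ppt_drift_sd)
            t_noise = _ar1(rng, n_years, cfg.interannual_temp_sd_c, cfg.ar1_rho)
            p_noise = 1.0 + _ar1(rng, n_years, cfg.interannual_ppt_cv, cfg.ar1_rho)
            t_anom = trend * decades + t_noise
            p_fact = np.maximum(p_noise, 0.2)

            data = {}
            for v in ("tmin", "tmax", "tmean", "tdew"):
                data[v] = clim[v][None] + t_anom[:, None, None, None]
            ppt = clim["ppt"][None] * p_fact[:, None, None, None] + (
                drift * decades
            )[:, None, None, None]
            data["ppt"] = np.maximum(ppt, 0.0)
            members.append(
                ClimateCube(years=years_axis.copy(), data=data, geometry=base.geometry)
            )
        out[name] = members
    return out


def _ar1(rng, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + rng.normal(0.0, innov_sd)
    return e
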