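"""Run configuration: dataclasses serializable to/from YAML.

A run is reproducible from config + seed alone; every stochastic stage
derives its RNG from the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class ScenarioSpec:
    """Forcing scenario for the pseudo-GCM ensemble.

    ``temp_trend_c_per_decade`` is the ensemble-mean warming rate;
    members draw their own trend from a normal around it with spread
    ``temp_trend_sd``.  Precipitation drifts by ``ppt_drift_mm_per_decade``
    (applied to monthly totals) with member spread ``ppt_drift_sd``.
    """

    temp_trend_c_per_decade: float
    temp_trend_sd: float = 0.08
    ppt_drift_mm_per_decade: float = 0.0
    ppt_drift_sd: float = 1.0


#: ensemble-mean trends loosely following the two standard forcing pathways
#: (moderate stabilisation vs. business-as-usual) over 2010-2099
DEFAULT_SCENARIOS: dict[str, ScenarioSpec] = {
    "rcp45": ScenarioSpec(temp_trend_c_per_decade=0.30, ppt_drift_mm_per_decade=0.5),
    "rcp85": ScenarioSpec(temp_trend_c_per_decade=0.55, ppt_drift_mm_per_decade=0.5),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study system.

    Defaults emulate a Greater-Yellowstone-like mountainous domain on an
    ~800 m grid: elevations 522-4206 m, a -6.5 degC/km lapse rate, a
    latitude of 44.5 degN for day length, and a 9-member pseudo-GCM
    ensemble under two forcing scenarios.
    """

    grid_rows: int = 64
    grid_cols: int = 64
    cell_size_m: float = 800.0
    elev_range_m: tuple[float, float] = (522.0, 4206.0)
    lapse_rate_c_per_km: float = -6.5
    latitude_deg: float = 44.5
    years: tuple[int, int] = (1950, 2010)
    future_years: tuple[int, int] = (2011, 2099)
    n_members: int = 9
    scenarios: dict[str, ScenarioSpec] = field(
        default_factory=lambda: dict(DEFAULT_SCENARIOS)
    )
    # climate generator
    sea_level_mean_temp_c: float = 16.0
    seasonal_amplitude_c: float = 11.0
    diurnal_half_range_c: float = 6.0
    dewpoint_depression_c: float = 5.0
    dewpoint_depression_heterogeneity_c: float = 2.0
    base_ppt_mm_per_month: float = 40.0
    orographic_ppt_mm_per_m: float = 0.015
    ppt_seasonal_amplitude: float = 0.35
    temp_heterogeneity_c: float = 1.5
    winter_lapse_factor: float = 0.4  # winter inversions weaken the lapse
    winter_heterogeneity_multiplier: float = 2.5  # cold-air pooling scatter
    ppt_heterogeneity: float = 0.4
    interannual_temp_sd_c: float = 0.6
    interannual_ppt_cv: float = 0.12
    ar1_rho: float = 0.5
    # terrain
    n_bumps: int = 6
    # soils
    awc_base_mm: float = 220.0
    awc_min_mm: float = 40.0
    # virtual species (logistic envelope on standardized tmax7 / pack4)
    beta0: float = -1.0
    beta_tmax7: float = -3.5
    beta_pack4: float = 3.0
    n_plots: int = 2500
    adult_fraction: float = 0.85
    false_absence_fraction: float = 0.10
    seed: int = 42

    def __post_init__(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid dims must be at least 8x8")
        if self.lapse_rate_c_per_km >= 0:
            raise ValueError("lapse_rate must be negative (cooling with elevation)")
        lo, hi = self.elev_range_m
        if not lo < hi:
            raise ValueError("elev_range_m must be (min, max) with min < max")
        if self.years[0] > self.years[1]:
            raise ValueError("years range is empty")


@dataclass
class WaterBalanceParams:
    """Tunable parameters of the monthly Thornthwaite water balance."""

    t_snow_c: float = -2.0   # all precipitation falls as snow at or below
    t_rain_c: float = 4.0    # all precipitation falls as rain at or above
    melt_coeff_mm_per_c: float = 40.0  # degree-month melt factor
    spinup_years: int = 1
    normals_on_per_year_runs: bool = True  # average WB outputs, not climate

    def __post_init__(self) -> None:
        if self.t_snow_c >= self.t_rain_c:
            raise ValueError("t_snow_c must be below t_rain_c")
        if self.melt_coeff_mm_per_c <= 0:
            raise ValueError("melt_coeff must be positive")


@dataclass
class ModelParams:
    """Random-forest hyperparameters and covariate-selection settings."""

    n_trees: int = 1000
    vars_per_split: int | None = None  # None -> ceil(sqrt(p))
    min_node_size: int = 1
    class_weight: str | None = None  # no class weighting by default
    pca_variance_target: float = 0.95
    r_max: float = 0.75
    dbh_min_cm: float = 20.0
    elev_cull_m: float = 300.0


@dataclass
class ProjectionParams:
    window_years: int = 30
    target_years: tuple[int, ...] = tuple(range(2010, 2100, 10)) + (2099,)
    reference_year: int = 2010
    min_patch_cells: int = 1


@dataclass
class RunConfig:
    """Full pipeline configuration (synthetic study system + analysis)."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    water_balance: WaterBalanceParams = field(default_factory=WaterBalanceParams)
    model: ModelParams = field(default_factory=ModelParams)
    projection: ProjectionParams = field(default_factory=ProjectionParams)
    normals_window: tuple[int, int] = (1950, 1980)
    seed: int = 42

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_as_plain(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        synth = dict(d.get("synthetic", {}))
        for key in ("elev_range_m", "years", "future_years"):
            if key in synth:
                synth[key] = tuple(synth[key])
        if "scenarios" in synth:
            synth["scenarios"] = {
                name: ScenarioSpec(**spec) for name, spec in synth["scenarios"].items()
            }
        proj = dict(d.get("projection", {}))
        if "target_years" in proj:
            proj["target_years"] = tuple(proj["target_years"])
        return cls(
            synthetic=SyntheticConfig(**synth),
            water_balance=WaterBalanceParams(**d.get("water_balance", {})),
            model=ModelParams(**d.get("model", {})),
            projection=ProjectionParams(**proj),
            normals_window=tuple(d.get("normals_window", (1950, 1980))),
            seed=int(d.get("seed", 42)),
        )


def _as_plain(obj):
    """Recursively convert dataclasses/tuples to YAML-safe primitives."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj
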