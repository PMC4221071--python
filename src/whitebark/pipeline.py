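"""End-to-end orchestration: synthetic study system to patch dynamics.

``run_pipeline`` executes the full analysis in memory and returns a
:class:`PipelineResult`; ``write_artifacts`` serializes the tables and
rasters to an output directory together with a manifest of content
hashes, so a rerun under the same config + seed reproduces every
artifact bit-for-bit.

Stage order: synth terrain/climate/soils -> water balance -> virtual
species sampling -> occurrence assembly -> covariate normals and
selection -> envelope fit + diagnostics -> ensemble projection ->
patch dynamics.  Ensemble members are always projected individually
and summarized afterwards; member climates are never averaged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from . import envelope_model as em
from . import occurrence_assembly as occ
from . import patch_dynamics as pd_mod
from . import projection as proj
from . import synthetic_data as synth
from .config import RunConfig, _as_plain
from .containers import ClimateCube, GridGeometry, concat_cubes
from .rasters import write_raster
from .water_balance import WaterBalanceOutput, run_water_balance

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "PipelineError", "run_pipeline", "write_artifacts"]

#: mapping from covariate base-variable names to WaterBalanceOutput fields
WB_FIELDS = {
    "pet": "pet_mm",
    "aet": "aet_mm",
    "soil": "soil_mm",
    "pack": "pack_mm",
    "vpd": "vpd_kpa",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    config: RunConfig
    geometry: GridGeometry
    dem: np.ndarray
    awc: np.ndarray
    truth: synth.VirtualSpeciesTruth
    records: pd.DataFrame
    samples: pd.DataFrame
    matrix: pd.DataFrame
    selected: list[str]
    model: em.EnvelopeModel
    diagnostics: em.ThresholdDiagnostics
    confusion: em.ConfusionMatrix
    importances: pd.DataFrame
    reference_prob: np.ndarray
    reference_area_km2: float
    series: pd.DataFrame
    summary: pd.DataFrame
    patches: pd.DataFrame
    stage_log: list[dict] = field(default_factory=list)


def monthly_stacks(cube: ClimateCube, wb: WaterBalanceOutput) -> dict[str, np.ndarray]:
    """All monthly stacks, climate + water balance, keyed by base name."""
    stacks = dict(cube.data)
    for name, attr in WB_FIELDS.items():
        stacks[name] = getattr(wb, attr)
    return stacks


def run_pipeline(config: RunConfig | None = None) -> PipelineResult:
    config = config or RunConfig()
    scfg = config.synthetic
    log: list[dict] = []

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3), **info})
            logger.info("stage %s done in %.2fs %s", name, time.perf_counter() - t0, info)

        return done

    # --- synthetic terrain, climate, soils -------------------------------
    try:
        done = stage("synth")
        geometry = synth.grid_geometry(scfg)
        dem = synth.make_terrain(scfg)
        climate = synth.make_climate(dem, scfg)
        awc = synth.make_soil(dem, scfg)
        done(years=f"{climate.years[0]}-{climate.years[-1]}")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("synth", e) from e

    # --- water balance over the historical record ------------------------
    try:
        done = stage("water_balance")
        wb = run_water_balance(climate, awc, scfg.latitude_deg, config.water_balance)
        done(closure_max_mm=wb.closure_max_mm)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("water_balance", e) from e

    # --- virtual species + occurrence assembly ---------------------------
    try:
        done = stage("occurrences")
        stacks = monthly_stacks(climate, wb)
        fit_normals = cov.stack_normals(
            stacks, climate.years, config.normals_window, ["tmax7", "pack4"]
        )
        truth = synth.VirtualSpeciesTruth.from_domain(
            scfg, fit_normals["tmax7"], fit_normals["pack4"]
        )
        records = synth.sample_virtual_species(
            fit_normals,
            truth,
            dem,
            geometry,
            scfg.n_plots,
            seed=scfg.seed,
            adult_fraction=scfg.adult_fraction,
            false_absence_fraction=scfg.false_absence_fraction,
        )
        samples = occ.assemble(
            records, dem, geometry, config.model.dbh_min_cm, config.model.elev_cull_m
        )
        done(n_records=len(records), n_samples=len(samples),
             n_presences=int(samples["present"].sum()))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("occurrences", e) from e

    # --- covariates and selection ----------------------------------------
    try:
        done = stage("covariates")
        candidate_names = list(cov.DEFAULT_PRECEDENCE)
        candidate_normals = cov.stack_normals(
            stacks, climate.years, config.normals_window, candidate_names
        )
        matrix = cov.extract_at_pixels(candidate_normals, samples)
        selected = cov.select_covariates(
            matrix, config.model.pca_variance_target, config.model.r_max
        )
        done(selected=",".join(selected))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("covariates", e) from e

    # --- envelope fit + diagnostics --------------------------------------
    try:
        done = stage("fit")
        labels = samples["present"].to_numpy()
        model = em.fit_envelope(
            matrix[selected],
            labels,
            n_trees=config.model.n_trees,
            vars_per_split=config.model.vars_per_split,
            min_node_size=config.model.min_node_size,
            seed=config.seed,
            class_weight=config.model.class_weight,
        )
        diagnostics = em.select_threshold(model.oob_prob, labels)
        confusion = em.oob_confusion(model, threshold=diagnostics.threshold)
        importances = em.permutation_importance(
            model, matrix[selected], n_repeats=5, seed=config.seed
        )
        done(auc=round(diagnostics.auc, 4), threshold=round(diagnostics.threshold, 4))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("fit", e) from e

    # --- reference surface (historical window ending at reference year) --
    try:
        done = stage("reference")
        ref_year = config.projection.reference_year
        window = config.projection.window_years
        ref_cube, _ = proj.moving_window_normals(climate, ref_year, window)
        ref_wb = run_water_balance(ref_cube, awc, scfg.latitude_deg, config.water_balance)
        ref_rasters = cov.stack_normals(
            monthly_stacks(ref_cube, ref_wb),
            ref_cube.years,
            (int(ref_cube.years[0]), int(ref_cube.years[-1])),
            selected,
        )
        reference_prob = proj.predict_surface(model, ref_rasters)
        ref_binary = proj.binary_map(reference_prob, diagnostics.threshold)
        reference_area = proj.suitable_area(ref_binary, geometry.cell_area_km2)
        done(reference_area_km2=reference_area)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("reference", e) from e

    # --- ensemble projection + patches -----------------------------------
    try:
        done = stage("projection")
        ensemble = synth.make_gcm_ensemble(climate, scfg)
        rows = []
        presence_maps: dict[tuple[str, int, int], np.ndarray] = {}
        for scenario, members in ensemble.items():
            for m_idx, member in enumerate(members):
                spliced = concat_cubes(climate, member)
                member_wb = run_water_balance(
                    spliced, awc, scfg.latitude_deg, config.water_balance
                )
                member_stacks = monthly_stacks(spliced, member_wb)
                for year in config.projection.target_years:
                    y0, y1 = year - window + 1, year
                    rasters = cov.stack_normals(
                        member_stacks, spliced.years, (y0, y1), selected
                    )
                    prob = proj.predict_surface(model, rasters)
                    binary = proj.binary_map(prob, diagnostics.threshold)
                    area = proj.suitable_area(binary, geometry.cell_area_km2)
                    mean_e, lo_e, hi_e = proj.elevation_stats(binary, dem)
                    n_p, med_p = pd_mod.patch_summary(
                        pd_mod.label_patches(binary),
                        geometry.cell_area_km2,
                        config.projection.min_patch_cells,
                    )
                    presence_maps[(scenario, m_idx, year)] = binary
                    rows.append(
                        {
                            "scenario": scenario,
                            "member": m_idx,
                            "year": year,
                            "suitable_area_km2": area,
                            "pct_reference_area": proj.percent_reference(
                                area, reference_area
                            ),
                            "mean_elev_m": mean_e,
                            "elev_p2_5_m": lo_e,
                            "elev_p97_5_m": hi_e,
                            "n_patches": n_p,
                            "median_patch_km2": med_p,
                        }
                    )
                del member_wb, member_stacks
        series = pd.DataFrame(rows)
        summary = proj.ensemble_summary(series)
        patches = pd_mod.patch_time_series(
            presence_maps, geometry.cell_area_km2, config.projection.min_patch_cells
        )
        done(n_rows=len(series))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("projection", e) from e

    return PipelineResult(
        config=config,
        geometry=geometry,
        dem=dem,
        awc=awc,
        truth=truth,
        records=records,
        samples=samples,
        matrix=matrix,
        selected=selected,
        model=model,
        diagnostics=diagnostics,
        confusion=confusion,
        importances=importances,
        reference_prob=reference_prob,
        reference_area_km2=reference_area,
        series=series,
        summary=summary,
        patches=patches,
        stage_log=log,
    )


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(_as_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_artifacts(result: PipelineResult, outdir: str | Path) -> dict[str, str]:
    """Write tables, rasters and a hash manifest; returns file hashes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geometry = result.geometry

    result.config.to_yaml(outdir / "config.yaml")
    write_raster(outdir / "dem.asc", result.dem, geometry)
    write_raster(outdir / "awc.asc", result.awc, geometry)
    write_raster(outdir / "reference_probability.asc", result.reference_prob, geometry)
    result.records.to_csv(outdir / "plots.csv", index=False)
    result.samples.to_csv(outdir / "pixel_samples.csv", index=False)
    result.series.to_csv(outdir / "projection_series.csv", index=False)
    result.summary.to_csv(outdir / "ensemble_summary.csv", index=False)
    result.patches.to_csv(outdir / "patch_series.csv", index=False)
    result.importances.to_csv(outdir / "importances.csv")

    d = result.diagnostics
    fit_report = {
        "covariates": result.selected,
        "hyperparams": result.model.hyperparams,
        "seed": result.model.seed,
        "threshold": d.threshold,
        "auc": d.auc,
        "max_kappa": d.max_kappa,
        "max_tss": d.max_tss,
        "oob_error_rate_pct": result.confusion.error_rate_pct,
        "confusion": dataclasses.asdict(result.confusion),
        "reference_area_km2": result.reference_area_km2,
        "n_false_absences_injected": result.records.attrs.get("n_false_absences"),
    }
    (outdir / "fit_report.json").write_text(json.dumps(fit_report, indent=2))
    (outdir / "stage_log.json").write_text(json.dumps(result.stage_log, indent=2))

    hashes = {}
    for f in sorted(outdir.iterdir()):
        # the stage log carries wall times, so it is not content-hashed
        if f.name in ("manifest.json", "stage_log.json") or f.is_dir():
            continue
        hashes[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest = {"config_hash": config_hash(result.config), "files": hashes}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return hashes
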