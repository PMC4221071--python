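"""Shared fixtures: a small synthetic study system built once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from whitebark import covariates as cov
from whitebark import envelope_model as em
from whitebark import occurrence_assembly as occ
from whitebark import synthetic_data as synth
from whitebark.config import SyntheticConfig
from whitebark.pipeline import monthly_stacks
from whitebark.water_balance import run_water_balance


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    return SyntheticConfig(
        grid_rows=32, grid_cols=32, years=(1950, 1980), n_plots=2000, seed=42
    )


@pytest.fixture(scope="session")
def study(small_cfg):
    """Terrain, climate, soils, water balance, normals, species, samples."""
    cfg = small_cfg
    dem = synth.make_terrain(cfg)
    climate = synth.make_climate(dem, cfg)
    awc = synth.make_soil(dem, cfg)
    wb = run_water_balance(climate, awc, cfg.latitude_deg)
    stacks = monthly_stacks(climate, wb)
    normals = cov.stack_normals(
        stacks, climate.years, cfg.years, list(cov.DEFAULT_PRECEDENCE)
    )
    truth = synth.VirtualSpeciesTruth.from_domain(cfg, normals["tmax7"], normals["pack4"])
    geometry = synth.grid_geometry(cfg)
    records = synth.sample_virtual_species(
        normals, truth, dem, geometry, cfg.n_plots, seed=cfg.seed
    )
    samples = occ.assemble(records, dem, geometry)
    matrix = cov.extract_at_pixels(normals, samples)
    return {
        "cfg": cfg,
        "dem": dem,
        "climate": climate,
        "awc": awc,
        "wb": wb,
        "stacks": stacks,
        "normals": normals,
        "truth": truth,
        "geometry": geometry,
        "records": records,
        "samples": samples,
        "matrix": matrix,
        "labels": samples["present"].to_numpy(),
    }


@pytest.fixture(scope="session")
def fitted(study):
    """An envelope model fit on the correlation-filtered candidate set."""
    final = cov.correlation_filter(study["matrix"], list(study["matrix"].columns))
    model = em.fit_envelope(study["matrix"][final], study["labels"], n_trees=300, seed=7)
    return {"model": model, "covariates": final}
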