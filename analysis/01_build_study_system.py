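#!/usr/bin/env python
"""Build the synthetic study system: terrain, climate, soils, surveys.

Generates the mountainous model domain (64x64 cells at 800 m, 522-4206 m
elevation), 61 years of monthly climate with elevation lapse and
winter-inversion heterogeneity, terrain-tied soil water capacity, and a
virtual cold-limited conifer surveyed at 2,500 plots with injected false
absences.  Writes the rasters and the plot table under results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from whitebark import covariates as cov
from whitebark import synthetic_data as synth
from whitebark.config import RunConfig, SyntheticConfig
from whitebark.pipeline import monthly_stacks
from whitebark.rasters import write_raster
from whitebark.water_balance import run_water_balance


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    config = RunConfig(synthetic=SyntheticConfig(seed=args.seed), seed=args.seed)
    scfg = config.synthetic
    geometry = synth.grid_geometry(scfg)
    dem = synth.make_terrain(scfg)
    climate = synth.make_climate(dem, scfg)
    awc = synth.make_soil(dem, scfg)

    wb = run_water_balance(climate, awc, scfg.latitude_deg, config.water_balance)
    normals = cov.stack_normals(
        monthly_stacks(climate, wb), climate.years, config.normals_window,
        ["tmax7", "pack4"],
    )
    truth = synth.VirtualSpeciesTruth.from_domain(
        scfg, normals["tmax7"], normals["pack4"]
    )
    records = synth.sample_virtual_species(
        normals, truth, dem, geometry, scfg.n_plots, seed=scfg.seed,
        adult_fraction=scfg.adult_fraction,
        false_absence_fraction=scfg.false_absence_fraction,
    )

    write_raster(out / "dem.asc", dem, geometry)
    write_raster(out / "awc.asc", awc, geometry)
    write_raster(out / "normal_tmax7.asc", normals["tmax7"], geometry)
    write_raster(out / "normal_pack4.asc", normals["pack4"], geometry)
    records.to_csv(out / "plots.csv", index=False)
    (out / "species_truth.json").write_text(
        json.dumps(
            {k: getattr(truth, k) for k in (
                "beta0", "beta_tmax7", "beta_pack4",
                "tmax7_mean", "tmax7_sd", "pack4_mean", "pack4_sd",
            )},
            indent=2,
        )
    )

    print(f"domain: {geometry.rows}x{geometry.cols} cells at {geometry.cell_size_m:.0f} m, "
          f"elevation {dem.min():.0f}-{dem.max():.0f} m")
    print(f"climate: {climate.years[0]}-{climate.years[-1]}, "
          f"July tmax normal {normals['tmax7'].min():.1f}-{normals['tmax7'].max():.1f} degC")
    print(f"April SWE normal: median {np.median(normals['pack4']):.0f} mm, "
          f"snow-covered fraction {(normals['pack4'] > 1).mean():.2f}")
    print(f"surveys: {len(records)} records, "
          f"{int(records.present.sum())} presences, "
          f"{records.attrs['n_false_absences']} false absences injected")
    print(f"wrote rasters and plots to {out}/")


if __name__ == "__main__":
    main()
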