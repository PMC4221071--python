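#!/usr/bin/env python
"""Summarize habitat fragmentation from the projected patch series.

Reads the patch time series written by 04_project_ensemble.py (8-connected
patch count and median patch size per scenario, member, and year) and
reports the fragmentation trajectory: how patch numbers and median sizes
evolve as suitable habitat contracts upslope.
"""

import argparse
from pathlib import Path

import pandas as pd


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    series_path = args.out / "projection" / "patch_series.csv"
    if not series_path.exists():
        raise SystemExit(
            f"{series_path} not found - run analysis/04_project_ensemble.py first"
        )

    patches = pd.read_csv(series_path)
    ensemble = patches[patches.member == -1]
    step_years = [2010, 2040, 2070, 2099]
    table = (
        ensemble[ensemble.year.isin(step_years)]
        .pivot(index="year", columns="scenario",
               values=["n_patches", "median_patch_km2"])
        .round(2)
    )
    print("ensemble-mean patch count and median patch size (km2):")
    print(table.to_string())

    for scenario, group in ensemble.groupby("scenario"):
        g = group.sort_values("year")
        peak = g.loc[g.n_patches.idxmax()]
        start, end = g.iloc[0], g.iloc[-1]
        print(f"\n{scenario}: patch count peaks at {peak.n_patches:.1f} in "
              f"{int(peak.year)}; median size moves "
              f"{start.median_patch_km2:.2f} -> {end.median_patch_km2:.2f} km2 "
              f"over {int(start.year)}-{int(end.year)}")

    summary = ensemble[ensemble.year.isin(step_years)]
    summary.to_csv(args.out / "patch_summary_steps.csv", index=False)
    print(f"\nwrote step-year patch summary to {args.out}/patch_summary_steps.csv")


if __name__ == "__main__":
    main()
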