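#!/usr/bin/env python
"""Assemble occurrences, select covariates, and fit the envelope model.

Applies the survey quality filters (adult DBH >= 20 cm, 300 m elevation
cull, one record per pixel with presence overriding absence), selects a
low-collinearity covariate set (PCA proxies, then the 0.75 correlation
filter in physiological precedence order), fits the bagged-tree
classifier, and reports the out-of-bag diagnostics: AUC, the
sensitivity = specificity threshold, Kappa/TSS maxima, the confusion
matrix, and permutation importances.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from whitebark import covariates as cov
from whitebark import envelope_model as em
from whitebark import occurrence_assembly as occ
from whitebark import synthetic_data as synth
from whitebark.config import ModelParams, RunConfig, SyntheticConfig
from whitebark.pipeline import monthly_stacks
from whitebark.water_balance import run_water_balance


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--n-trees", type=int, default=300)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    config = RunConfig(
        synthetic=SyntheticConfig(seed=args.seed),
        model=ModelParams(n_trees=args.n_trees),
        seed=args.seed,
    )
    scfg = config.synthetic
    geometry = synth.grid_geometry(scfg)
    dem = synth.make_terrain(scfg)
    climate = synth.make_climate(dem, scfg)
    awc = synth.make_soil(dem, scfg)
    wb = run_water_balance(climate, awc, scfg.latitude_deg, config.water_balance)
    stacks = monthly_stacks(climate, wb)
    normals = cov.stack_normals(
        stacks, climate.years, config.normals_window, list(cov.DEFAULT_PRECEDENCE)
    )
    truth = synth.VirtualSpeciesTruth.from_domain(
        scfg, normals["tmax7"], normals["pack4"]
    )
    records = synth.sample_virtual_species(
        normals, truth, dem, geometry, scfg.n_plots, seed=scfg.seed,
        adult_fraction=scfg.adult_fraction,
        false_absence_fraction=scfg.false_absence_fraction,
    )

    samples = occ.assemble(records, dem, geometry,
                           config.model.dbh_min_cm, config.model.elev_cull_m)
    print(f"occurrence assembly: {len(records)} records -> {len(samples)} pixel "
          f"samples ({int(samples.present.sum())} presences)")

    matrix = cov.extract_at_pixels(normals, samples)
    selected = cov.select_covariates(
        matrix, config.model.pca_variance_target, config.model.r_max
    )
    print(f"selected covariates: {', '.join(selected)}")

    labels = samples["present"].to_numpy()
    model = em.fit_envelope(matrix[selected], labels,
                            n_trees=config.model.n_trees, seed=config.seed)
    diag = em.select_threshold(model.oob_prob, labels)
    confusion = em.oob_confusion(model, threshold=diag.threshold)
    importances = em.permutation_importance(model, matrix[selected],
                                            n_repeats=5, seed=config.seed)

    print(f"OOB AUC {diag.auc:.3f}; threshold (sens = spec) {diag.threshold:.3f}; "
          f"max Kappa {diag.max_kappa:.3f}; max TSS {diag.max_tss:.3f}")
    print(f"OOB error rate {confusion.error_rate_pct:.1f}% "
          f"(tp {confusion.tp}, fp {confusion.fp}, fn {confusion.fn}, tn {confusion.tn})")
    print("permutation importances (mean OOB accuracy drop):")
    for name, row in importances.iterrows():
        print(f"  {name:6s} {row.importance:+.3f} (sd {row.sd:.3f})")

    samples.to_csv(out / "pixel_samples.csv", index=False)
    matrix.assign(present=labels).to_csv(out / "covariate_matrix.csv", index=False)
    importances.to_csv(out / "importances.csv")
    curves = pd.DataFrame({
        "threshold": diag.grid, "tpr": diag.tpr, "tnr": diag.tnr,
        "kappa": diag.kappa, "tss": diag.tss,
    })
    curves.to_csv(out / "threshold_curves.csv", index=False)
    (out / "fit_report.json").write_text(json.dumps({
        "covariates": selected,
        "n_samples": len(samples),
        "auc": diag.auc,
        "threshold": diag.threshold,
        "max_kappa": diag.max_kappa,
        "max_tss": diag.max_tss,
        "oob_error_rate_pct": confusion.error_rate_pct,
        "confusion": {"tp": confusion.tp, "fp": confusion.fp,
                      "fn": confusion.fn, "tn": confusion.tn},
    }, indent=2))
    print(f"wrote fit tables to {out}/")


if __name__ == "__main__":
    main()
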