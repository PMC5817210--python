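"""Evolve a symbolic-regression model of dQTc and evaluate it.

Runs the GP engine on a mechanistic-mode population restricted to the
eight equation inputs, picks the final model by the multivariate
criterion (generalization error band, then complexity, then constant
count), refits its constants, and scores it with leave-one-inhibitor-out
cross-validation plus the noised-data stability check.  Desk-scale budget;
the published cluster runs used orders of magnitude more evaluations.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from qtgp import gp_engine as gp
from qtgp.evaluation import cv_evaluate
from qtgp.gp_engine import GPConfig
from qtgp.preprocessing import add_noise, fit_scaler, make_loio_folds
from qtgp.qt_model import equation_variables
from qtgp.virtual_population import make_design, sample_population

SEED = 20240904
ROOT = Path(__file__).resolve().parents[1]


def main():
    table = sample_population(design=make_design(total_records=3000), seed=SEED,
                              mode="mechanistic")
    scaler = fit_scaler()
    scaled = scaler.transform(table)
    folds = make_loio_folds(table["arm"])
    variables = tuple(equation_variables())
    y = table["dQTc"].to_numpy(float)

    cfg = GPConfig(population_size=100, evaluation_budget=30_000, size_limit=32,
                   variables=variables, elite_cadence_factor=100)
    archive = gp.evolve(scaled[list(variables)], y, cfg, seed=SEED + 1, folds=folds)
    final = gp.select_final(archive)
    print(f"archive: {len(archive)} non-dominated models")
    print(f"final model: {gp.to_prefix(final.tree)}")
    print(f"  constants: {np.round(final.constants, 5).tolist()}")
    print(f"  complexity {final.complexity}, training RMSE {final.fitness:.4f} ms, "
          f"cv RMSE {final.cv_error:.4f} ms")

    def fit(train):
        tr = scaler.transform(train)
        cols = {v: tr[v].to_numpy(float) for v in variables}
        consts = final.constants
        if final.n_constants > 0:
            consts, _ = gp.optimize_constants(final.tree, cols,
                                              train["dQTc"].to_numpy(float),
                                              seed=SEED + 2, n_starts=2,
                                              init=final.constants)

        def predictor(tbl):
            sc = scaler.transform(tbl)
            return np.asarray(gp.evaluate(final.tree, consts,
                                          {v: sc[v].to_numpy(float) for v in variables}))
        return predictor

    noised = add_noise(table, 0.05, 2, seed=SEED + 3)
    report = cv_evaluate(fit, table, folds, noised_table=noised)
    out = ROOT / "results" / "gp_cv_report.csv"
    out.parent.mkdir(exist_ok=True)
    report.fold_scores.to_csv(out, index=False, float_format="%.6g")
    print("\nper-fold held-out scores:")
    print(report.fold_scores.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print(f"pooled NRMSE {report.pooled_nrmse:.3f}%, mean-over-folds "
          f"{report.mean_nrmse:.3f}%, noised-set {report.noised_nrmse:.3f}%")
    print(f"cv report -> {out}")


if __name__ == "__main__":
    sys.exit(main())
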