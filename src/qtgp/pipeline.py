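"""End-to-end orchestration of the analysis.

One config drives the whole chain — generate a virtual population,
preprocess (noise replicas, <0.1;0.9> scaling, leave-one-inhibitor-out
folds), rank features, evolve a symbolic-regression model, refit its
constants, evaluate it under grouped cross-validation, and run the
response and channel analyses of the white-box equation.  Every stage
draws its seed from an independent substream of the root seed, so stages
are individually reproducible, and the run emits a manifest with a
checksum for every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, feature_ranking, gp_engine, preprocessing, qt_model, reference, virtual_population

__all__ = ["RunConfig", "run", "load_config"]

_STAGES = ("generate", "preprocess", "rank", "evolve", "evaluate", "respond", "channels")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    The defaults describe a desk-scale demonstration run (2,000 records,
    small evolution budget); the published trial dimensions are available
    via ``total_records=10360``.
    """

    seed: int
    total_records: int = 2000
    n_patients: int = reference.N_PATIENTS
    mode: str = "mechanistic"  # dQTc generation mode
    noise_amplitude: float = 0.05
    noise_copies: int = 2
    cutoff_threshold: float = 0.05
    ranking_repeats: int = 3
    gp_population_size: int = 100
    gp_budget: int = 20_000
    gp_size_limit: int = 32
    gp_selection: str = "afc_pareto"
    gp_elite_cadence_factor: int = 50
    constants_override: tuple[float, float, float, float] | None = None
    n_response_points: int = 100

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("config must set an explicit seed")

    def stage_seed(self, stage: str) -> int:
        """Independent per-stage substream of the root seed."""
        idx = _STAGES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(_STAGES))[idx]
        return int(child.generate_state(1)[0] % (2**31 - 1))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "constants_override" in raw and raw["constants_override"] is not None:
        raw["constants_override"] = tuple(raw["constants_override"])
    return RunConfig(**raw)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _ols_learner(train: pd.DataFrame, covariates: list[str], output: str):
    """Least-squares linear predictor used as the built-in ranking learner."""
    X = np.column_stack([train[c].to_numpy(float) for c in covariates] + [np.ones(len(train))])
    beta, *_ = np.linalg.lstsq(X, train[output].to_numpy(float), rcond=None)

    def predictor(table: pd.DataFrame) -> np.ndarray:
        Xt = np.column_stack([table[c].to_numpy(float) for c in covariates] + [np.ones(len(table))])
        return Xt @ beta

    return predictor


def run(config: RunConfig, outdir) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}, "artifacts": {}}

    def save(name: str, df: pd.DataFrame) -> Path:
        path = outdir / name
        _write_csv(df, path)
        manifest["artifacts"][name] = _sha256(path)
        return path

    stage = "generate"
    try:
        design = virtual_population.make_design(config.n_patients, config.total_records)
        table = virtual_population.sample_population(
            design=design, seed=config.stage_seed(stage), mode=config.mode
        )
        save("population.csv", table)
        manifest["stages"][stage] = {"n_records": len(table), "n_patients": config.n_patients}

        stage = "preprocess"
        scaler = preprocessing.fit_scaler()
        noised = preprocessing.add_noise(
            table, config.noise_amplitude, config.noise_copies, seed=config.stage_seed(stage)
        )
        folds = preprocessing.make_loio_folds(table["arm"])
        scaled = scaler.transform(table)
        save("scaled.csv", scaled)
        save("folds.csv", folds.to_frame(table["arm"]))
        manifest["stages"][stage] = {"n_noised": len(noised), "n_folds": len(folds)}

        stage = "rank"
        output = reference.OUTPUT_SUMMARY.name
        covariates = [c for c in reference.variable_names()
                      if reference.get_spec(c).vclass != "constant"]
        predictor = _ols_learner(scaled, covariates, output)
        report = feature_ranking.permutation_importance(
            predictor, scaled[covariates], scaled[output].to_numpy(float),
            repeats=config.ranking_repeats, seed=config.stage_seed(stage), learner="ols",
        )
        ranking = feature_ranking.scale_and_aggregate([report])
        selected = feature_ranking.apply_cutoff(ranking, config.cutoff_threshold)
        save("ranking.csv", ranking.rename("importance").rename_axis("variable").reset_index())
        manifest["stages"][stage] = {"n_selected": len(selected), "selected": selected}

        stage = "evolve"
        gp_vars = tuple(selected)
        cfg = gp_engine.GPConfig(
            population_size=config.gp_population_size,
            evaluation_budget=config.gp_budget,
            size_limit=config.gp_size_limit,
            variables=gp_vars,
            selection=config.gp_selection,
            elite_cadence_factor=config.gp_elite_cadence_factor,
        )
        # inputs on the <0.1;0.9> scale for sane sin/exp magnitudes; raw-ms target
        gp_table = scaled[list(gp_vars)].copy()
        gp_y = table[output].to_numpy(float)
        archive = gp_engine.evolve(gp_table, gp_y, cfg, seed=config.stage_seed(stage), folds=folds)
        arch_df = pd.DataFrame({
            "expression": [gp_engine.to_prefix(i.tree) for i in archive],
            "constants": [";".join(f"{c:.10g}" for c in i.constants) for i in archive],
            "fitness": [i.fitness for i in archive],
            "cv_error": [i.cv_error for i in archive],
            "complexity": [i.complexity for i in archive],
            "age": [i.age for i in archive],
        })
        save("archive.csv", arch_df)
        final = gp_engine.select_final(archive)
        manifest["stages"][stage] = {
            "archive_size": len(archive),
            "final_expression": gp_engine.to_prefix(final.tree),
            "final_constants": [float(c) for c in final.constants],
            "final_fitness": final.fitness,
            "final_cv_error": final.cv_error,
        }

        stage = "evaluate"
        eval_seed = config.stage_seed(stage)

        def fit(train: pd.DataFrame):
            tr = scaler.transform(train)
            cols = {v: tr[v].to_numpy(float) for v in gp_vars}
            if final.n_constants > 0:
                consts, _ = gp_engine.optimize_constants(
                    final.tree, cols, train[output].to_numpy(float),
                    seed=eval_seed, n_starts=2, init=final.constants,
                )
            else:
                consts = final.constants

            def predictor(tbl: pd.DataFrame) -> np.ndarray:
                sc = scaler.transform(tbl)
                return np.asarray(gp_engine.evaluate(
                    final.tree, consts, {v: sc[v].to_numpy(float) for v in gp_vars}
                ))

            return predictor

        report_cv = evaluation.cv_evaluate(fit, table, folds, noised_table=noised)
        save("cv_report.csv", report_cv.fold_scores)
        manifest["stages"][stage] = {
            "pooled_nrmse": report_cv.pooled_nrmse,
            "mean_nrmse": report_cv.mean_nrmse,
            "noised_nrmse": report_cv.noised_nrmse,
        }

        stage = "respond"
        constants = (qt_model.ModelConstants(*config.constants_override)
                     if config.constants_override else qt_model.PUBLISHED_CONSTANTS)
        curves = []
        for scenario in reference.RESPONSE_SCENARIOS:
            for variable in qt_model.equation_variables():
                c = qt_model.response_sweep(variable, scenario, constants,
                                            n_points=config.n_response_points)
                c = c.rename(columns={variable: "value"})
                c.insert(0, "variable", variable)
                c.insert(0, "scenario", scenario)
                curves.append(c)
        save("response_curves.csv", pd.concat(curves, ignore_index=True))
        manifest["stages"][stage] = {"n_curves": len(curves)}

        stage = "channels"
        cmp = qt_model.channel_comparison(constants)
        save("channel_curve.csv", cmp.curve)
        manifest["stages"][stage] = {
            "slope": cmp.slope, "intercept": cmp.intercept, "r_squared": cmp.r_squared,
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
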