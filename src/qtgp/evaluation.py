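"""Goodness-of-fit metrics and grouped cross-validated evaluation.

The headline metric is the normalized root mean squared error

    NRMSE = sqrt( sum_i (pred_i - obs_i)^2 / n ) / (Xmax - Xmin) * 100

where Xmax and Xmin are the maximum and minimum *observed* dQTc of the
evaluation split (a config option pins them to the published global range
instead, for cross-fold comparability).  R^2 is the ordinary coefficient
of determination 1 - SS_res/SS_tot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import reference
from .preprocessing import FoldAssignment

__all__ = ["nrmse", "r_squared", "cv_evaluate", "CVReport", "GLOBAL_OUTPUT_RANGE"]

#: Published observed range of the dQTc output (ms).
GLOBAL_OUTPUT_RANGE = (reference.OUTPUT_SUMMARY.vmin, reference.OUTPUT_SUMMARY.vmax)


def _check_pair(obs, pred):
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted vectors differ in length")
    if obs.size < 2:
        raise ValueError("need at least 2 records")
    return obs, pred


def nrmse(obs, pred, output_range: tuple[float, float] | None = None) -> float:
    """Normalized RMSE in percent.

    Normalization uses the observed range of ``obs`` unless an explicit
    ``output_range`` (e.g. the published global dQTc range) is given.
    """
    obs, pred = _check_pair(obs, pred)
    if output_range is None:
        xmax, xmin = float(obs.max()), float(obs.min())
    else:
        xmin, xmax = map(float, output_range)
    if xmax <= xmin:
        raise ValueError("normalization undefined: observed range is zero")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    return rmse / (xmax - xmin) * 100.0


def r_squared(obs, pred) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    obs, pred = _check_pair(obs, pred)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for a constant observed vector")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class CVReport:
    """Per-fold and pooled scores of a grouped cross-validation."""

    fold_scores: pd.DataFrame  # columns: arm, n_test, nrmse, r_squared
    pooled_nrmse: float
    mean_nrmse: float
    noised_nrmse: float | None = None
    predictions: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_folds(self) -> int:
        return len(self.fold_scores)


def cv_evaluate(
    fit: Callable[[pd.DataFrame], Callable[[pd.DataFrame], np.ndarray]],
    table: pd.DataFrame,
    folds: FoldAssignment,
    output: str = reference.OUTPUT_SUMMARY.name,
    output_range: tuple[float, float] | None = None,
    noised_table: pd.DataFrame | None = None,
) -> CVReport:
    """Leave-one-arm-out evaluation of a model-fitting procedure.

    ``fit`` consumes a training table and returns a predictor mapping a
    table to a prediction vector.  Every fold trains with one arm held out
    and scores NRMSE / R^2 on that arm; the pooled NRMSE is computed over
    the concatenated held-out predictions (both the pooled and the
    mean-over-folds summary are reported).  If ``noised_table`` is given, a
    model fitted on the full table is additionally scored on it as a
    stability check.
    """
    obs_all = table[output].to_numpy(float)
    rows, pooled_obs, pooled_pred, pred_rows = [], [], [], []
    for arm, train_idx, test_idx in folds:
        if len(test_idx) < 2:
            raise ValueError(f"fold {arm!r} has fewer than 2 test records")
        predictor = fit(table.iloc[train_idx])
        pred = np.asarray(predictor(table.iloc[test_idx]), float)
        obs = obs_all[test_idx]
        rows.append({
            "arm": arm,
            "n_test": len(test_idx),
            "nrmse": nrmse(obs, pred, output_range),
            "r_squared": r_squared(obs, pred),
        })
        pooled_obs.append(obs)
        pooled_pred.append(pred)
        pred_rows.append(pd.DataFrame({"record": test_idx, "arm": arm, "obs": obs, "pred": pred}))
    obs_cat = np.concatenate(pooled_obs)
    pred_cat = np.concatenate(pooled_pred)
    fold_scores = pd.DataFrame(rows)

    noised_score = None
    if noised_table is not None:
        predictor = fit(table)
        noised_score = nrmse(
            noised_table[output].to_numpy(float),
            np.asarray(predictor(noised_table), float),
            output_range,
        )
    return CVReport(
        fold_scores=fold_scores,
        pooled_nrmse=nrmse(obs_cat, pred_cat, output_range),
        mean_nrmse=float(fold_scores["nrmse"].mean()),
        noised_nrmse=noised_score,
        predictions=pd.concat(pred_rows, ignore_index=True),
    )
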