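"""Feature ranking by performance-weighted importance aggregation.

The original screening stage ran a zoo of regression learners, scaled each
learner's variable-importance vector by its global error, summed the scaled
vectors into a single ranking, and cut the ranking where the importance
drops by more than 5% of its total sum.  This module implements that
aggregation arithmetic together with one built-in, model-agnostic
importance estimator (permutation importance), so the stage runs
self-contained with any predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "ImportanceReport",
    "permutation_importance",
    "scale_and_aggregate",
    "apply_cutoff",
    "cutoff_candidates",
]


@dataclass
class ImportanceReport:
    """One learner's raw importances and its global error."""

    learner: str
    importances: pd.Series  # non-negative, indexed by variable name
    error: float  # global RMSE (or MSE) of the learner

    def validate(self) -> None:
        if (self.importances < 0).any():
            raise ValueError(f"{self.learner}: negative importances")
        if not self.error > 0:
            raise ValueError(f"{self.learner}: global error must be > 0")


def permutation_importance(
    predictor: Callable[[pd.DataFrame], np.ndarray],
    table: pd.DataFrame,
    y,
    metric: str = "rmse",
    repeats: int = 5,
    seed: int | None = None,
    learner: str = "predictor",
) -> ImportanceReport:
    """Permutation importance of every column of ``table``.

    The importance of a variable is the mean increase of the error metric
    after shuffling that column (``repeats`` independent shuffles);
    negative averages are clipped to zero.  The report carries the
    predictor's unpermuted global error for performance weighting.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible permutations")
    y = np.asarray(y, float)
    if np.all(y == y[0]):
        raise ValueError("metric undefined on a constant observed vector")

    def err(pred):
        se = np.mean((np.asarray(pred, float) - y) ** 2)
        return float(np.sqrt(se)) if metric == "rmse" else float(se)

    if metric not in ("rmse", "mse"):
        raise ValueError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(seed)
    base = err(predictor(table))
    rows = {}
    for col in table.columns:
        deltas = []
        for _ in range(repeats):
            shuffled = table.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            deltas.append(err(predictor(shuffled)) - base)
        rows[col] = max(0.0, float(np.mean(deltas)))
    return ImportanceReport(learner=learner, importances=pd.Series(rows), error=max(base, 1e-12))


def scale_and_aggregate(
    reports: list[ImportanceReport],
    weighting: str = "inverse_error",
) -> pd.Series:
    """Aggregate per-learner importances into one ranking.

    Each learner's importance vector is normalized to sum 1 (making the
    aggregation invariant to that learner's raw scale), weighted by the
    inverse of its global error so better learners count more, summed
    across learners, and sorted descending.  All-zero importance vectors
    are excluded with a warning.
    """
    if not reports:
        raise ValueError("need at least one importance report")
    if weighting != "inverse_error":
        raise ValueError(f"unknown weighting {weighting!r}")
    total = None
    for rep in reports:
        rep.validate()
        s = rep.importances.sum()
        if s == 0:
            warnings.warn(f"learner {rep.learner!r} has an all-zero importance vector; excluded")
            continue
        contrib = rep.importances / s / rep.error
        total = contrib if total is None else total.add(contrib, fill_value=0.0)
    if total is None:
        raise ValueError("all importance reports were all-zero")
    return total.sort_values(ascending=False)


def _drop_positions(ranking: pd.Series, threshold: float) -> list[int]:
    vals = ranking.to_numpy(float)
    total = float(vals.sum())
    drops = vals[:-1] - vals[1:]
    return [i + 1 for i, d in enumerate(drops) if d > threshold * total]


def apply_cutoff(ranking: pd.Series, threshold: float = 0.05, mode: str = "drop") -> list[str]:
    """Cut the ranking where the importance falls off.

    ``mode="drop"`` (default): a cut point is any position where the
    consecutive importance drop exceeds ``threshold`` times the total
    importance sum; the selection keeps everything above the *last* such
    drop, i.e. discards the tail that follows the final large fall-off.
    With no qualifying drop all variables are kept.  ``mode="share"``
    keeps the variables whose importance share is at least ``threshold``.
    """
    if len(ranking) == 0:
        raise ValueError("empty ranking")
    if not ranking.is_monotonic_decreasing:
        ranking = ranking.sort_values(ascending=False)
    if mode == "share":
        total = float(ranking.sum())
        keep = ranking[ranking / total >= threshold]
        return list(keep.index) if len(keep) else [ranking.index[0]]
    if mode != "drop":
        raise ValueError(f"unknown cutoff mode {mode!r}")
    positions = _drop_positions(ranking, threshold)
    if not positions:
        return list(ranking.index)
    return list(ranking.index[: positions[-1]])


def cutoff_candidates(ranking: pd.Series, threshold: float = 0.05) -> list[list[str]]:
    """All candidate prefixes, one per qualifying drop.

    The original screening produced several nested input vectors (one per
    cut point); this returns each prefix ending just above a drop larger
    than ``threshold`` times the total sum, shortest first.
    """
    if len(ranking) == 0:
        raise ValueError("empty ranking")
    if not ranking.is_monotonic_decreasing:
        ranking = ranking.sort_values(ascending=False)
    positions = _drop_positions(ranking, threshold)
    if not positions:
        return [list(ranking.index)]
    return [list(ranking.index[:p]) for p in positions]
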