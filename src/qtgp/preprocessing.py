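"""Preprocessing: linear <0.1; 0.9> scaling, noise augmentation, and the
leave-one-inhibitor-out 8-fold split.

The three steps mirror the preparation applied to the virtual-trial data
before modeling: each variable is mapped affinely so that its raw min/max
land on 0.1/0.9 (out-of-range inputs extrapolate linearly, which the
channel sweeps rely on), noised replicas with a bounded +/-5% multiplicative
band are produced for stability testing, and cross-validation folds hold
out one whole trial arm at a time so a model must extrapolate to an unseen
drug-drug combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .reference import SCALE_LO, SCALE_HI, VariableSpec

__all__ = ["ScalingSpec", "FoldAssignment", "fit_scaler", "add_noise", "make_loio_folds"]

#: Columns that are identifiers, not measurements.
ID_COLUMNS = ("patient_id", "arm")


@dataclass
class ScalingSpec:
    """Per-variable affine map between the raw scale and [lo, hi].

    ``bounds`` maps variable name -> (raw_min, raw_max); variables in
    ``constant`` are identically zero in the data and pass through
    unchanged.  The dQTc output carries its own entry so scaled-target
    model fits are possible, but :meth:`transform` leaves it alone unless
    asked.
    """

    bounds: dict[str, tuple[float, float]]
    constant: frozenset = field(default_factory=frozenset)
    lo: float = SCALE_LO
    hi: float = SCALE_HI

    def scale_value(self, name: str, x):
        """Scale raw values of one variable (vectorized, extrapolating)."""
        if name in self.constant:
            return x
        raw_min, raw_max = self.bounds[name]
        return self.lo + (self.hi - self.lo) * (np.asarray(x, float) - raw_min) / (raw_max - raw_min)

    def unscale_value(self, name: str, y):
        if name in self.constant:
            return y
        raw_min, raw_max = self.bounds[name]
        return raw_min + (np.asarray(y, float) - self.lo) * (raw_max - raw_min) / (self.hi - self.lo)

    def transform(self, table: pd.DataFrame, include_output: bool = False) -> pd.DataFrame:
        """Return a copy of ``table`` with every known column scaled."""
        out = table.copy()
        for name in out.columns:
            if name in ID_COLUMNS or name in self.constant:
                continue
            if name == reference.OUTPUT_SUMMARY.name and not include_output:
                continue
            if name in self.bounds:
                out[name] = self.scale_value(name, out[name].to_numpy())
        return out

    def inverse_transform(self, table: pd.DataFrame, include_output: bool = False) -> pd.DataFrame:
        out = table.copy()
        for name in out.columns:
            if name in ID_COLUMNS or name in self.constant:
                continue
            if name == reference.OUTPUT_SUMMARY.name and not include_output:
                continue
            if name in self.bounds:
                out[name] = self.unscale_value(name, out[name].to_numpy())
        return out


def fit_scaler(
    specs: list[VariableSpec] | None = None,
    data: pd.DataFrame | None = None,
    source: str = "table1_bounds",
) -> ScalingSpec:
    """Build the <0.1; 0.9> scaler.

    ``source="table1_bounds"`` (default) takes raw min/max from the
    published per-variable summaries — reproducible and independent of any
    particular sample.  ``source="empirical"`` takes them from ``data``.
    Constant-class variables (identically zero) are exempt and passed
    through; a zero raw range on any other variable is an error.
    """
    bounds: dict[str, tuple[float, float]] = {}
    constant: set[str] = set()
    if source == "table1_bounds":
        if specs is None:
            specs = list(reference.VARIABLE_SUMMARIES) + [reference.OUTPUT_SUMMARY]
        for spec in specs:
            if spec.vclass == "constant":
                constant.add(spec.name)
                continue
            if spec.vmax == spec.vmin:
                raise ValueError(f"degenerate raw range for variable {spec.name!r}")
            bounds[spec.name] = (spec.vmin, spec.vmax)
    elif source == "empirical":
        if data is None:
            raise ValueError("empirical source requires data")
        for name in data.columns:
            if name in ID_COLUMNS:
                continue
            col = data[name].to_numpy(float)
            vmin, vmax = float(np.min(col)), float(np.max(col))
            if vmax == vmin:
                if vmin == 0.0:
                    constant.add(name)
                    continue
                raise ValueError(f"degenerate raw range for variable {name!r}")
            bounds[name] = (vmin, vmax)
    else:
        raise ValueError(f"unknown scaler source {source!r}")
    return ScalingSpec(bounds=bounds, constant=frozenset(constant))


def add_noise(
    table: pd.DataFrame,
    amplitude: float = 0.05,
    copies: int = 2,
    seed: int | None = None,
    noise_output: bool = True,
) -> pd.DataFrame:
    """Produce ``copies`` noised replicas of every record.

    Each numeric cell x is replaced by x*(1+u) with u ~ Uniform(-amplitude,
    +amplitude) drawn independently per cell, so every noised value stays
    within the +/-amplitude band of its source and zero-valued cells remain
    zero.  Identifier columns are preserved.  ``noise_output=False`` exempts
    the dQTc column.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if copies < 1:
        raise ValueError("copies must be >= 1")
    if seed is None:
        raise ValueError("seed is required for reproducible noise augmentation")
    rng = np.random.default_rng(seed)
    noise_cols = [
        c for c in table.columns
        if c not in ID_COLUMNS
        and pd.api.types.is_numeric_dtype(table[c])
        and (noise_output or c != reference.OUTPUT_SUMMARY.name)
    ]
    replicas = []
    for _ in range(copies):
        rep = table.copy()
        for c in noise_cols:
            x = rep[c].to_numpy(float)
            rep[c] = x * (1.0 + rng.uniform(-amplitude, amplitude, size=len(x)))
        replicas.append(rep)
    return pd.concat(replicas, ignore_index=True)


@dataclass
class FoldAssignment:
    """Leave-one-arm-out folds: one (train, test) index pair per held-out arm."""

    folds: list[tuple[str, np.ndarray, np.ndarray]]

    def __len__(self) -> int:
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)

    def to_frame(self, arm_labels: pd.Series) -> pd.DataFrame:
        """Serialize as (record index, arm, fold id) rows."""
        rows = []
        for fold_id, (arm, _train, test) in enumerate(self.folds):
            for idx in test:
                rows.append((int(idx), arm, fold_id))
        return pd.DataFrame(rows, columns=["record", "arm", "fold"])


def make_loio_folds(arm_labels, expected_arms: int = 8, allow_other: bool = False) -> FoldAssignment:
    """Leave-one-inhibitor-out folds from a vector of per-record arm labels.

    Fold k tests on every record of arm k and trains on the rest, so each
    fold predicts a drug-drug combination absent from its training data.
    Folds are keyed by label (canonical arm order where applicable), making
    the assignment invariant to row order.
    """
    labels = pd.Series(list(arm_labels)).reset_index(drop=True)
    distinct = set(labels)
    if len(distinct) != expected_arms and not allow_other:
        raise ValueError(
            f"expected {expected_arms} distinct arms, found {len(distinct)}; "
            "pass allow_other=True to override"
        )
    canonical = [a for a in reference.ARM_LABELS if a in distinct]
    ordered = canonical + sorted(distinct - set(canonical))
    all_idx = np.arange(len(labels))
    folds = []
    for arm in ordered:
        test = all_idx[(labels == arm).to_numpy()]
        train = all_idx[(labels != arm).to_numpy()]
        folds.append((arm, train, test))
    return FoldAssignment(folds)
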