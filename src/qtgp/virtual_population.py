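"""Synthetic virtual-trial population generator.

The original analysis ran on 10,360 records of 63 virtual patients dosed
with terfenadine alone or together with one of seven metabolic inhibitors,
produced by proprietary PBPK and cardiomyocyte simulators.  That data set
was never deposited; only its per-variable six-number summary survives.
This module generates a statistical stand-in: each of the 48 covariates is
drawn from a piecewise-linear inverse CDF anchored at the published
quantile knots (min, Q25, median, Q75, max), so the marginal distributions
of a large sample converge to the published summary.  Joint structure is
not published and is not invented: covariates are sampled independently by
default, with an optional Gaussian-copula hook for user-supplied rank
correlations.

The dQTc output can either be drawn from its own marginal ("marginal"
mode) or computed from the sampled covariates through the white-box
equation ("mechanistic" mode), which makes the generated table an exact
oracle for downstream model-fitting machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .reference import ARM_LABELS, N_PATIENTS, TOTAL_RECORDS, VariableSpec

__all__ = [
    "QuantileSampler",
    "TrialDesign",
    "load_reference_specs",
    "build_sampler",
    "make_design",
    "default_design",
    "sample_population",
]

#: Cumulative probabilities of the five summary knots.
KNOT_PROBS = (0.0, 0.25, 0.5, 0.75, 1.0)


def load_reference_specs() -> list[VariableSpec]:
    """The published per-variable summaries: 48 covariates plus dQTc.

    Values are returned exactly as published, including the internally
    inconsistent Gut_CYP2C9 row (its printed minimum exceeds its printed
    Q25); see :func:`build_sampler` for how sampling handles it.
    """
    return list(reference.VARIABLE_SUMMARIES) + [reference.OUTPUT_SUMMARY]


@dataclass(frozen=True)
class QuantileSampler:
    """Sampler for one covariate, anchored to its summary knots.

    Continuous variables use the piecewise-linear inverse CDF through the
    probability knots (0, .25, .5, .75, 1); constant-class variables are
    degenerate at zero; the binary sex code is Bernoulli with success
    probability equal to the published mean.
    """

    spec: VariableSpec
    knots: tuple[float, ...]

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.spec.vclass == "constant":
            return np.zeros(n)
        if self.spec.vclass == "binary":
            return (rng.random(n) < self.spec.mean).astype(float)
        return self.ppf(rng.random(n))

    def ppf(self, u) -> np.ndarray:
        """Piecewise-linear inverse CDF at probabilities ``u``."""
        return np.interp(np.asarray(u, float), KNOT_PROBS, self.knots)

    def cdf(self, x) -> np.ndarray:
        """CDF of the piecewise-linear quantile model (continuous knots)."""
        return np.interp(np.asarray(x, float), self.knots, KNOT_PROBS)


def build_sampler(spec: VariableSpec, repair_nonmonotone: bool = False) -> QuantileSampler:
    """Build the marginal sampler for one covariate.

    Non-monotone quantile knots are a validation error by default; with
    ``repair_nonmonotone=True`` the five knots are sorted instead, the
    minimal repair for a summary row whose printed values cannot all be
    order statistics of the same distribution (the published Gut_CYP2C9
    row needs it).
    """
    knots = spec.knots
    if spec.vclass == "continuous" and not spec.monotone:
        if not repair_nonmonotone:
            raise ValueError(
                f"{spec.name}: non-monotone quantile knots {knots}; "
                "pass repair_nonmonotone=True to sort them"
            )
        knots = tuple(sorted(knots))
    elif spec.vclass != "continuous":
        spec.validate()
    return QuantileSampler(spec=spec, knots=knots)


@dataclass(frozen=True)
class TrialDesign:
    """Arms, patient count and per-patient-per-arm record allocation."""

    arms: tuple[str, ...]
    n_patients: int
    total_records: int
    allocation: np.ndarray = field(repr=False)  # shape (n_patients, n_arms)

    def validate(self) -> None:
        if self.allocation.shape != (self.n_patients, len(self.arms)):
            raise ValueError("allocation shape does not match design")
        if int(self.allocation.sum()) != self.total_records:
            raise ValueError("allocation does not sum to total_records")
        if len(set(self.arms)) != len(self.arms):
            raise ValueError("duplicate arm labels")
        if np.any(self.allocation.sum(axis=1) < 1):
            raise ValueError("every patient must contribute at least one record")


def make_design(
    n_patients: int = N_PATIENTS,
    total_records: int = TOTAL_RECORDS,
    arms: tuple[str, ...] = ARM_LABELS,
) -> TrialDesign:
    """A trial design with deterministic near-equal allocation.

    Each patient receives floor(total/n_patients) records with the
    remainder going to the lowest patient ids, and each patient's records
    are spread near-equally over the arms in the same way.
    """
    n_arms = len(arms)
    if total_records < n_patients:
        raise ValueError("need at least one record per patient")
    per_patient = np.full(n_patients, total_records // n_patients, dtype=int)
    per_patient[: total_records - per_patient.sum()] += 1
    allocation = np.zeros((n_patients, n_arms), dtype=int)
    for p in range(n_patients):
        base = per_patient[p] // n_arms
        allocation[p, :] = base
        allocation[p, : per_patient[p] - base * n_arms] += 1
    design = TrialDesign(
        arms=tuple(arms),
        n_patients=n_patients,
        total_records=total_records,
        allocation=allocation,
    )
    design.validate()
    return design


def default_design() -> TrialDesign:
    """The published trial dimensions: 63 patients, 8 arms (terfenadine
    alone plus seven inhibitors), 10,360 records.  The per-patient
    breakdown is not published, so records are allocated near-equally and
    deterministically (see :func:`make_design`)."""
    return make_design()


def _copula_uniforms(rng, n, names, rank_corr: pd.DataFrame):
    """Correlated uniforms via a Gaussian copula on the listed variables."""
    corr = rank_corr.loc[names, names].to_numpy(float)
    # Spearman rank correlation -> Gaussian copula parameter.
    rho = 2.0 * np.sin(np.pi * corr / 6.0)
    np.fill_diagonal(rho, 1.0)
    z = rng.multivariate_normal(np.zeros(len(names)), rho, size=n, method="cholesky")
    return {name: stats.norm.cdf(z[:, j]) for j, name in enumerate(names)}


def sample_population(
    specs: list[VariableSpec] | None = None,
    design: TrialDesign | None = None,
    seed: int | None = None,
    mode: str = "marginal",
    rank_corr: pd.DataFrame | None = None,
    arm_inhibition_shift: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Generate a full virtual-trial table.

    Parameters
    ----------
    specs
        Variable summaries (default: the published ones, covariates + dQTc).
    design
        Trial design (default: :func:`default_design`).
    seed
        Required; the generator refuses to run without an explicit seed.
    mode
        "marginal" draws dQTc from its own published marginal; in
        "mechanistic" mode dQTc is computed from the sampled covariates by
        the white-box equation with its published constants.
    rank_corr
        Optional Spearman rank-correlation matrix (DataFrame indexed by
        variable names) imposed on the listed continuous covariates through
        a Gaussian copula.  Default: independent sampling.
    arm_inhibition_shift
        Optional per-arm multiplicative factors on the four channel
        inhibition columns, e.g. ``{"ketoconazole": {"IKr_inhibition": 1.5}}``.
        Default: no shift (published marginals apply to every arm).

    Returns a DataFrame with ``patient_id``, ``arm``, the 48 covariates in
    published column order, and ``dQTc``.
    """
    if seed is None:
        raise ValueError("seed is required: population generation must be reproducible")
    if mode not in ("marginal", "mechanistic"):
        raise ValueError(f"unknown mode {mode!r}")
    if specs is None:
        specs = load_reference_specs()
    if design is None:
        design = default_design()
    design.validate()

    rng = np.random.default_rng(seed)
    n = design.total_records
    output_name = reference.OUTPUT_SUMMARY.name
    covariate_specs = [s for s in specs if s.name != output_name]
    output_spec = next((s for s in specs if s.name == output_name), None)

    patient_id = np.repeat(
        np.arange(design.n_patients), design.allocation.sum(axis=1)
    )
    arm = np.concatenate([
        np.repeat(np.array(design.arms, dtype=object), design.allocation[p])
        for p in range(design.n_patients)
    ])

    samplers = {s.name: build_sampler(s, repair_nonmonotone=True) for s in covariate_specs}

    uniforms: dict[str, np.ndarray] = {}
    if rank_corr is not None:
        corr_names = [s.name for s in covariate_specs
                      if s.name in rank_corr.index and s.vclass == "continuous"]
        uniforms = _copula_uniforms(rng, n, corr_names, rank_corr)

    columns: dict[str, np.ndarray] = {"patient_id": patient_id, "arm": arm}
    for s in covariate_specs:
        sampler = samplers[s.name]
        if s.name in uniforms:
            columns[s.name] = sampler.ppf(uniforms[s.name])
        else:
            columns[s.name] = sampler.draw(rng, n)

    if arm_inhibition_shift:
        for arm_label, shifts in arm_inhibition_shift.items():
            mask = arm == arm_label
            for col, factor in shifts.items():
                columns[col] = np.where(mask, columns[col] * factor, columns[col])

    table = pd.DataFrame(columns)

    if mode == "marginal":
        if output_spec is None:
            raise ValueError("marginal mode requires the output summary spec")
        table[output_name] = build_sampler(output_spec).draw(rng, n)
    else:
        from .qt_model import predict

        table[output_name] = np.asarray(predict(table))
    return table
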