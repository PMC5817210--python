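"""The white-box dQTc model and its response analyses.

The model is a single symbolic-regression equation mapping eight inputs —
body surface area (X6), plasma potassium (X8), sodium (X9) and calcium
(X10) concentrations, and the fractional inhibition of the IKr (X11), IKs
(X12), INa (X13) and ICaL (X14) cardiac currents — to the change in
Fridericia-corrected QT interval (dQTc, ms).  Under the packaged canonical
reading the equation is

    dQTc = sin(X14)*X9 + C2*X13*X14*X8*sin(X6) + X14*X8
         + sin(C1*X12*X14^2) + X11*X14
         + sin(e^(C4*X14)*X9 + X11*e^(e^X11))
         + C3*X11 + 2*sin(X10)^2

with fitted constants C1..C4 and every input on its natural raw scale
(ion concentrations in mM, BSA in m^2, inhibitions as fractions in [0, 1]).

The printed form of the equation lost its parentheses and does not state
the input scale, so the grouping and convention above are a reconstruction.
It is the reading that reproduces the published model behaviour: the
IKr-versus-ICaL comparison is almost perfectly linear (R^2 = 0.995) with an
ICaL effect roughly twice the IKr effect, and the prediction at the
median-covariate record (6.0 ms) sits next to the observed dQTc median
(6.591 ms).  All alternative groupings, and the variant in which inputs
enter on the <0.1; 0.9> training scale, are retained as first-class
candidates (:func:`parse_candidates`) and can be scored against those
behavioural criteria with :func:`select_parse`.

The module also implements the two published model interrogations: the
quantile response sweeps (one input swept over its observed range with the
others pinned at a joint quantile scenario) and the IKr-versus-ICaL channel
comparison (matched inhibition grids 0..1, ordinary least squares on the
paired predictions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import reference
from .preprocessing import ScalingSpec, fit_scaler
from .reference import EQUATION_INPUTS, MODEL_CONSTANTS, RESPONSE_SCENARIOS

__all__ = [
    "ModelConstants",
    "PUBLISHED_CONSTANTS",
    "ParseVariant",
    "CANONICAL_PARSE",
    "eval_dqtc",
    "predict",
    "response_sweep",
    "channel_comparison",
    "parse_candidates",
    "ParseCriteria",
    "score_parse",
    "select_parse",
    "equation_variables",
    "equation_tree",
]

_EXP_CLAMP = 50.0


def _pexp(x):
    """Protected exponential: argument clamped to [-50, 50]."""
    return np.exp(np.clip(x, -_EXP_CLAMP, _EXP_CLAMP))


@dataclass(frozen=True)
class ModelConstants:
    """The four adjustable parameters of the equation."""

    C1: float = MODEL_CONSTANTS[0]
    C2: float = MODEL_CONSTANTS[1]
    C3: float = MODEL_CONSTANTS[2]
    C4: float = MODEL_CONSTANTS[3]

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.C1, self.C2, self.C3, self.C4)


PUBLISHED_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class ParseVariant:
    """One resolution of the equation's typographic ambiguities.

    Four local grouping choices plus the input-scale convention:

    * ``sin14``: leading term read as "sin(X14)*X9" (operator precedence)
      or "sin(X14*X9)".
    * ``ca``: calcium term "2*sin(X10)^2" or "2*sin(X10^2)".
    * ``exp_term``: exponential factor inside the long sine read as
      "e^(C4*X14)*X9", "e^(C4*X14*X9)" or "e^(C4)*X14*X9".
    * ``c3``: "C3*X11" outside or inside the preceding sine.
    * ``input_scale``: inputs consumed on their raw scales ("raw") or on
      the <0.1; 0.9> training scale ("scaled").
    """

    sin14: str = "sin_x14_times_x9"    # sin_x14_times_x9 | sin_of_product
    ca: str = "sin_squared"            # sin_squared | sin_of_square
    exp_term: str = "exp_c4x14_times_x9"  # exp_c4x14_times_x9 | exp_c4x14x9 | expc4_times_x14x9
    c3: str = "outside"                # outside | inside
    input_scale: str = "raw"           # raw | scaled

    @property
    def label(self) -> str:
        return f"{self.sin14}|{self.ca}|{self.exp_term}|c3_{self.c3}|{self.input_scale}"


CANONICAL_PARSE = ParseVariant()


def _extract(record, name):
    x = np.asarray(record[name], dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite value in input {name!r}")
    return x


def eval_dqtc(
    record: Mapping[str, object] | pd.DataFrame,
    constants: ModelConstants = PUBLISHED_CONSTANTS,
    variant: ParseVariant = CANONICAL_PARSE,
):
    """Evaluate the equation on model-scale inputs.

    ``record`` maps the eight covariate names (BSA, K, Na, Ca2 and the four
    channel-inhibition fractions) to scalars or aligned arrays, already on
    the scale the parse variant expects (raw for the canonical parse).
    Returns dQTc in ms, scalar or array matching the input shape.  Use
    :func:`predict` to go from raw covariates under any variant.
    """
    c1, c2, c3, c4 = constants.as_tuple()
    x6 = _extract(record, EQUATION_INPUTS["X6"])
    x8 = _extract(record, EQUATION_INPUTS["X8"])
    x9 = _extract(record, EQUATION_INPUTS["X9"])
    x10 = _extract(record, EQUATION_INPUTS["X10"])
    x11 = _extract(record, EQUATION_INPUTS["X11"])
    x12 = _extract(record, EQUATION_INPUTS["X12"])
    x13 = _extract(record, EQUATION_INPUTS["X13"])
    x14 = _extract(record, EQUATION_INPUTS["X14"])

    if variant.sin14 == "sin_x14_times_x9":
        t1 = np.sin(x14) * x9
    elif variant.sin14 == "sin_of_product":
        t1 = np.sin(x14 * x9)
    else:
        raise ValueError(variant.sin14)

    t2 = c2 * x13 * x14 * x8 * np.sin(x6)
    t3 = x14 * x8
    t4 = np.sin(c1 * x12 * x14**2)
    t5 = x11 * x14

    if variant.exp_term == "exp_c4x14_times_x9":
        e = _pexp(c4 * x14) * x9
    elif variant.exp_term == "exp_c4x14x9":
        e = _pexp(c4 * x14 * x9)
    elif variant.exp_term == "expc4_times_x14x9":
        e = _pexp(np.full_like(x14, c4)) * x14 * x9
    else:
        raise ValueError(variant.exp_term)

    inner = e + x11 * _pexp(_pexp(x11))
    if variant.c3 == "inside":
        t6 = np.sin(inner + c3 * x11)
        t7 = 0.0
    elif variant.c3 == "outside":
        t6 = np.sin(inner)
        t7 = c3 * x11
    else:
        raise ValueError(variant.c3)

    if variant.ca == "sin_squared":
        t8 = 2.0 * np.sin(x10) ** 2
    elif variant.ca == "sin_of_square":
        t8 = 2.0 * np.sin(x10**2)
    else:
        raise ValueError(variant.ca)

    out = t1 + t2 + t3 + t4 + t5 + t6 + t7 + t8
    return out if out.shape else float(out)


def equation_variables() -> list[str]:
    """The eight distinct covariates referenced by the equation."""
    return [EQUATION_INPUTS[x] for x in ("X6", "X8", "X9", "X10", "X11", "X12", "X13", "X14")]


def predict(
    raw_record: Mapping[str, object] | pd.DataFrame,
    constants: ModelConstants = PUBLISHED_CONSTANTS,
    scaler: ScalingSpec | None = None,
    variant: ParseVariant = CANONICAL_PARSE,
):
    """Evaluate the equation on raw-scale covariates.

    For the canonical (raw-input) parse this is direct evaluation; for a
    "scaled" variant the eight inputs are first mapped to <0.1; 0.9>
    through ``scaler`` (default: published min/max bounds, extrapolating
    outside the observed range).  Returns dQTc in ms.
    """
    if variant.input_scale == "raw":
        record = raw_record
    elif variant.input_scale == "scaled":
        if scaler is None:
            scaler = fit_scaler()
        record = {name: scaler.scale_value(name, raw_record[name]) for name in equation_variables()}
    else:
        raise ValueError(variant.input_scale)
    return eval_dqtc(record, constants, variant)


def response_sweep(
    variable: str,
    scenario: str | Mapping[str, float],
    constants: ModelConstants = PUBLISHED_CONSTANTS,
    n_points: int = 100,
    scaler: ScalingSpec | None = None,
    variant: ParseVariant = CANONICAL_PARSE,
) -> pd.DataFrame:
    """Sweep one equation input over its observed raw range.

    The chosen variable runs from its observed minimum to maximum in
    ``n_points`` steps while the remaining seven inputs are pinned at the
    scenario's raw values (``scenario`` is a quantile label "Q1".."Q5" or
    an explicit mapping).  Returns a (raw value, dQTc) table.
    """
    if variable not in equation_variables():
        raise ValueError(f"{variable!r} is not an equation input")
    fixed = RESPONSE_SCENARIOS[scenario] if isinstance(scenario, str) else dict(scenario)
    spec = reference.get_spec(variable)
    grid = np.linspace(spec.vmin, spec.vmax, n_points)
    record = {name: np.full(n_points, fixed[name]) for name in equation_variables()}
    record[variable] = grid
    dqtc = predict(record, constants, scaler, variant)
    return pd.DataFrame({variable: grid, "dQTc": dqtc})


@dataclass
class ChannelComparison:
    """Paired IKr/ICaL sweep with its least-squares summary."""

    slope: float
    intercept: float
    r_squared: float
    curve: pd.DataFrame = field(repr=False)


def channel_comparison(
    constants: ModelConstants = PUBLISHED_CONSTANTS,
    grid_step: float = 0.01,
    scaler: ScalingSpec | None = None,
    variant: ParseVariant = CANONICAL_PARSE,
) -> ChannelComparison:
    """Compare the dQTc effect of IKr versus ICaL inhibition.

    Both inhibitions are swept over the raw grid 0..1 (step ``grid_step``)
    with every other input held at its observed median; under a scaled
    variant the ICaL sweep exceeds the observed ICaL maximum, so the scaler
    extrapolates by design.  The paired predictions at matched grid
    positions are summarized by an ordinary-least-squares fit of the
    ICaL-sweep values on the IKr-sweep values.
    """
    import statsmodels.api as sm

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    medians = {name: reference.get_spec(name).median for name in equation_variables()}

    def sweep(channel):
        record = {name: np.full(len(grid), medians[name]) for name in equation_variables()}
        record[channel] = grid
        return predict(record, constants, scaler, variant)

    y_ikr = np.asarray(sweep("IKr_inhibition"))
    y_ica = np.asarray(sweep("ICa_inhibition"))
    fit = sm.OLS(y_ica, sm.add_constant(y_ikr)).fit()
    curve = pd.DataFrame({"inhibition": grid, "dQTc_IKr": y_ikr, "dQTc_ICa": y_ica})
    return ChannelComparison(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        curve=curve,
    )


def parse_candidates() -> list[ParseVariant]:
    """All documented readings of the equation.

    Enumerates every combination of the four grouping ambiguities and the
    two input-scale conventions (48 candidates); the canonical parse is
    listed first.
    """
    variants = [CANONICAL_PARSE]
    for input_scale in ("raw", "scaled"):
        for sin14 in ("sin_x14_times_x9", "sin_of_product"):
            for ca in ("sin_squared", "sin_of_square"):
                for exp_term in ("exp_c4x14_times_x9", "exp_c4x14x9", "expc4_times_x14x9"):
                    for c3 in ("outside", "inside"):
                        v = ParseVariant(sin14, ca, exp_term, c3, input_scale)
                        if v != CANONICAL_PARSE:
                            variants.append(v)
    return variants


@dataclass(frozen=True)
class ParseCriteria:
    """Behavioural screen for a parse reading.

    A plausible reading should reproduce the published model behaviour:
    near-linear channel comparison, an ICaL/IKr effect ratio of roughly
    two, and predictions overlapping the observed dQTc range.
    """

    min_r_squared: float = 0.95
    slope_band: tuple[float, float] = (1.5, 2.5)
    output_range: tuple[float, float] = (
        reference.OUTPUT_SUMMARY.vmin,
        reference.OUTPUT_SUMMARY.vmax,
    )


def score_parse(variant: ParseVariant, criteria: ParseCriteria = ParseCriteria()) -> dict:
    """Score one parse candidate against the behavioural criteria."""
    cmp = channel_comparison(variant=variant)
    lo, hi = criteria.output_range
    pred_lo = float(min(cmp.curve["dQTc_IKr"].min(), cmp.curve["dQTc_ICa"].min()))
    pred_hi = float(max(cmp.curve["dQTc_IKr"].max(), cmp.curve["dQTc_ICa"].max()))
    ok_r2 = cmp.r_squared > criteria.min_r_squared
    ok_slope = criteria.slope_band[0] <= abs(cmp.slope) <= criteria.slope_band[1]
    ok_range = pred_hi > lo and pred_lo < hi
    return {
        "variant": variant.label,
        "slope": cmp.slope,
        "r_squared": cmp.r_squared,
        "pred_min": pred_lo,
        "pred_max": pred_hi,
        "ok_r_squared": ok_r2,
        "ok_slope": ok_slope,
        "ok_range": ok_range,
        "n_criteria": int(ok_r2) + int(ok_slope) + int(ok_range),
    }


def equation_tree(variant: ParseVariant = CANONICAL_PARSE):
    """The equation as a genetic-programming expression tree.

    Returns ``(tree, constants)`` in the tree grammar of
    :mod:`qtgp.gp_engine`, with constant slots numbered depth-first (so the
    constants vector is ordered C2, C1, C4, C3 for the canonical term
    order).  Evaluating the tree on a record reproduces :func:`eval_dqtc`
    exactly; it is also the starting genotype for constant-refitting
    experiments.
    """
    v = {x: ("var", name) for x, name in EQUATION_INPUTS.items()}

    def mul(*ts):
        out = ts[0]
        for t in ts[1:]:
            out = ("mul", out, t)
        return out

    def add(*ts):
        out = ts[0]
        for t in ts[1:]:
            out = ("add", out, t)
        return out

    if variant.sin14 == "sin_x14_times_x9":
        t1 = mul(("sin", v["X14"]), v["X9"])
    else:
        t1 = ("sin", mul(v["X14"], v["X9"]))
    c2, c1, c4, c3 = ("const", 0), ("const", 1), ("const", 2), ("const", 3)
    t2 = mul(c2, v["X13"], v["X14"], v["X8"], ("sin", v["X6"]))
    t3 = mul(v["X14"], v["X8"])
    t4 = ("sin", mul(c1, v["X12"], v["X14"], v["X14"]))
    t5 = mul(v["X11"], v["X14"])
    if variant.exp_term == "exp_c4x14_times_x9":
        e = mul(("exp", mul(c4, v["X14"])), v["X9"])
    elif variant.exp_term == "exp_c4x14x9":
        e = ("exp", mul(c4, v["X14"], v["X9"]))
    else:
        e = mul(("exp", c4), v["X14"], v["X9"])
    inner = add(e, mul(v["X11"], ("exp", ("exp", v["X11"]))))
    if variant.c3 == "inside":
        t6 = ("sin", add(inner, mul(c3, v["X11"])))
        tail = []
    else:
        t6 = ("sin", inner)
        tail = [mul(c3, v["X11"])]
    s10 = ("sin", v["X10"]) if variant.ca == "sin_squared" else ("sin", mul(v["X10"], v["X10"]))
    if variant.ca == "sin_squared":
        t8 = add(mul(s10, s10), mul(s10, s10))
    else:
        t8 = add(s10, s10)
    tree = add(t1, t2, t3, t4, t5, t6, *tail, t8)
    constants = np.array([PUBLISHED_CONSTANTS.C2, PUBLISHED_CONSTANTS.C1,
                          PUBLISHED_CONSTANTS.C4, PUBLISHED_CONSTANTS.C3])
    return tree, constants


def select_parse(criteria: ParseCriteria = ParseCriteria()) -> tuple[ParseVariant, pd.DataFrame]:
    """Score every candidate reading and pick the best.

    Candidates are ranked by the number of criteria satisfied; ties resolve
    to the earliest candidate in :func:`parse_candidates` order, so the
    canonical parse wins any tie it is part of.  Returns the selected
    variant and the full score table.
    """
    cands = parse_candidates()
    scores = [score_parse(v, criteria) for v in cands]
    table = pd.DataFrame(scores)
    best_idx = int(table["n_criteria"].to_numpy().argmax())
    return cands[best_idx], table
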