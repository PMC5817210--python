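"""White-box dQTc equation: parse semantics, sweeps, channel comparison."""

import math

import numpy as np
import pytest

from qtgp import reference
from qtgp.qt_model import (
    CANONICAL_PARSE,
    PUBLISHED_CONSTANTS,
    ModelConstants,
    ParseVariant,
    channel_comparison,
    equation_variables,
    eval_dqtc,
    parse_candidates,
    predict,
    response_sweep,
    score_parse,
    select_parse,
)

VARS = equation_variables()


def record(**overrides):
    rec = {name: 0.0 for name in VARS}
    rec.update(overrides)
    return rec


class TestEvalDqtc:
    def test_all_zero_record_gives_zero(self):
        assert eval_dqtc(record()) == pytest.approx(0.0)

    def test_zero_record_value_per_candidate(self):
        # term-by-term: every additive term vanishes at zero except the long
        # sine under the e^(C4*X14*X9) grouping, where e^0 = 1 leaves sin(1)
        for variant in parse_candidates():
            value = eval_dqtc(record(), variant=variant)
            expected = math.sin(1.0) if variant.exp_term == "exp_c4x14x9" else 0.0
            assert value == pytest.approx(expected, abs=1e-12), variant.label

    def test_isolated_calcium_term(self):
        # only 2*sin(X10)^2 survives; at X10 = pi/2 it equals 2
        assert eval_dqtc(record(Ca2=math.pi / 2)) == pytest.approx(2.0)

    def test_isolated_ikr_terms_match_independent_arithmetic(self):
        x11 = 0.5
        expected = (PUBLISHED_CONSTANTS.C3 * x11
                    + math.sin(x11 * math.exp(math.exp(x11))))
        assert eval_dqtc(record(IKr_inhibition=x11)) == pytest.approx(expected, abs=1e-12)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        recs = {n: rng.uniform(0, 1, 50) for n in VARS}
        vec = np.asarray(eval_dqtc(recs))
        for i in (0, 17, 49):
            scalar = eval_dqtc({n: recs[n][i] for n in VARS})
            assert vec[i] == pytest.approx(scalar, abs=1e-12)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            eval_dqtc(record(K=float("nan")))

    def test_eight_distinct_inputs(self):
        assert len(VARS) == 8
        assert set(VARS) == {"BSA", "K", "Na", "Ca2", "IKr_inhibition",
                             "IKs_inhibition", "INa_inhibition", "ICa_inhibition"}


class TestPredict:
    def test_canonical_predict_is_raw_evaluation(self):
        med = {n: reference.get_spec(n).median for n in VARS}
        assert predict(med) == pytest.approx(eval_dqtc(med))

    def test_scaled_variant_composition(self, table1_scaler):
        variant = ParseVariant(input_scale="scaled")
        minima = {n: reference.get_spec(n).vmin for n in VARS}
        via_predict = predict(minima, variant=variant)
        all_tenth = {n: 0.1 for n in VARS}
        assert via_predict == pytest.approx(eval_dqtc(all_tenth, variant=variant))

    def test_deterministic(self):
        med = {n: reference.get_spec(n).median for n in VARS}
        assert predict(med) == predict(med)

    def test_monotone_in_ikr_at_medians(self):
        grid = np.linspace(0.0047, 1.0, 500)
        med = {n: np.full(len(grid), reference.get_spec(n).median) for n in VARS}
        med["IKr_inhibition"] = grid
        y = np.asarray(predict(med))
        assert np.all(np.diff(y) > 0)

    def test_median_record_prediction_near_observed_median(self):
        # behavioural anchor of the parse reconstruction
        med = {n: reference.get_spec(n).median for n in VARS}
        assert abs(predict(med) - reference.OUTPUT_SUMMARY.median) < 1.0


class TestResponseSweep:
    def test_q3_scenario_values(self):
        q3 = reference.RESPONSE_SCENARIOS["Q3"]
        assert q3 == {"BSA": 1.937, "K": 4.268, "Na": 140.445, "Ca2": 2.388,
                      "IKr_inhibition": 0.117, "IKs_inhibition": 0.0,
                      "INa_inhibition": 0.001, "ICa_inhibition": 0.002}

    def test_sweep_endpoints_match_observed_range(self):
        curve = response_sweep("K", "Q3", n_points=50)
        spec = reference.get_spec("K")
        assert curve["K"].iloc[0] == pytest.approx(spec.vmin)
        assert curve["K"].iloc[-1] == pytest.approx(spec.vmax)
        assert len(curve) == 50

    def test_structural_zero_gives_flat_curve(self):
        # every INa term carries a factor of ICa inhibition, which is 0 at Q1
        curve = response_sweep("INa_inhibition", "Q1")
        assert curve["dQTc"].std() == pytest.approx(0.0, abs=1e-12)

    def test_calcium_sweep_bounded_by_two_ms(self):
        # Ca2 enters only through 2*sin^2, bounded in [0, 2]
        curve = response_sweep("Ca2", "Q3")
        assert curve["dQTc"].max() - curve["dQTc"].min() <= 2.0 + 1e-12

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError):
            response_sweep("Age", "Q3")

    def test_fifth_quantile_scenario_dominates(self):
        # the largest dQTc changes occur with covariates at their joint
        # maximum (Q5); lower scenarios differ only by bounded sine terms
        mids = {}
        for scenario in ("Q1", "Q2", "Q3", "Q4", "Q5"):
            curve = response_sweep("IKr_inhibition", scenario, n_points=11)
            mids[scenario] = curve["dQTc"].iloc[5]
        assert mids["Q5"] > max(mids[s] for s in ("Q1", "Q2", "Q3", "Q4")) + 20.0


class TestChannelComparison:
    def test_grid_has_101_matched_points(self):
        cmp = channel_comparison()
        assert len(cmp.curve) == 101
        assert cmp.curve["inhibition"].iloc[0] == 0.0
        assert cmp.curve["inhibition"].iloc[-1] == pytest.approx(1.0)

    def test_self_comparison_is_identity(self):
        import statsmodels.api as sm

        cmp = channel_comparison()
        y = cmp.curve["dQTc_IKr"].to_numpy()
        fit = sm.OLS(y, sm.add_constant(y)).fit()
        assert fit.params[1] == pytest.approx(1.0)
        assert fit.rsquared == pytest.approx(1.0)

    def test_strong_linearity_and_ica_dominance(self):
        """The reconstruction reproduces the published qualitative finding:
        a near-linear relation with the ICaL effect roughly twice the IKr
        effect per unit inhibition."""
        cmp = channel_comparison()
        assert cmp.r_squared > 0.95
        assert abs(cmp.slope) > 1.5

    def test_slope_invariant_under_affine_output_rescaling(self):
        import statsmodels.api as sm

        cmp = channel_comparison()
        x = cmp.curve["dQTc_IKr"].to_numpy()
        y = cmp.curve["dQTc_ICa"].to_numpy()
        fit = sm.OLS(2.5 * y + 7, sm.add_constant(2.5 * x + 7)).fit()
        assert fit.params[1] == pytest.approx(cmp.slope)


class TestParseCandidates:
    def test_canonical_is_listed_first_and_unique(self):
        cands = parse_candidates()
        assert cands[0] == CANONICAL_PARSE
        assert len(cands) == 48
        assert len(set(cands)) == 48

    def test_selection_is_deterministic_and_canonical_wins(self):
        v1, table1 = select_parse()
        v2, _ = select_parse()
        assert v1 == v2 == CANONICAL_PARSE
        assert len(table1) == 48

    def test_canonical_outscores_scaled_reading(self):
        canonical = score_parse(CANONICAL_PARSE)
        scaled = score_parse(ParseVariant(sin14="sin_of_product", input_scale="scaled"))
        assert canonical["r_squared"] > 0.95
        assert canonical["n_criteria"] >= scaled["n_criteria"]

    def test_constants_override(self):
        doubled = ModelConstants(C1=PUBLISHED_CONSTANTS.C1, C2=PUBLISHED_CONSTANTS.C2,
                                 C3=2 * PUBLISHED_CONSTANTS.C3, C4=PUBLISHED_CONSTANTS.C4)
        x11 = 0.3
        base = eval_dqtc(record(IKr_inhibition=x11))
        up = eval_dqtc(record(IKr_inhibition=x11), constants=doubled)
        assert up - base == pytest.approx(PUBLISHED_CONSTANTS.C3 * x11)
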