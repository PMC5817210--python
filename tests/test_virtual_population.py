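"""Virtual-population generator: calibration, determinism, validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from qtgp import reference
from qtgp.reference import VariableSpec
from qtgp.virtual_population import (
    QuantileSampler,
    build_sampler,
    default_design,
    load_reference_specs,
    make_design,
    sample_population,
)


class TestReferenceSpecs:
    def test_counts(self):
        specs = load_reference_specs()
        assert len(specs) == 49
        assert sum(s.name != "dQTc" for s in specs) == 48

    def test_potassium_row(self):
        k = reference.get_spec("K")
        assert (k.vmin, k.q25, k.median, k.mean, k.q75, k.vmax) == (
            3.053, 4.079, 4.268, 4.261, 4.451, 5.363)
        assert k.units == "mM"

    def test_constant_class_rows_are_zero(self):
        cyp2a6 = reference.get_spec("CYP2A6")
        assert cyp2a6.vclass == "constant"
        assert cyp2a6.knots == (0, 0, 0, 0, 0) and cyp2a6.mean == 0
        n_constant = sum(s.vclass == "constant" for s in reference.VARIABLE_SUMMARIES)
        assert n_constant == 7

    def test_sex_code_is_binary(self):
        sex = reference.get_spec("Sex_Code")
        assert sex.vclass == "binary" and sex.mean == 0.7718

    def test_only_gut_cyp2c9_is_nonmonotone(self):
        bad = [s.name for s in reference.VARIABLE_SUMMARIES
               if s.vclass == "continuous" and not s.monotone]
        assert bad == ["Gut_CYP2C9"]


class TestBuildSampler:
    def test_nonmonotone_rejected_then_repaired(self):
        spec = reference.get_spec("Gut_CYP2C9")
        with pytest.raises(ValueError, match="non-monotone"):
            build_sampler(spec)
        sampler = build_sampler(spec, repair_nonmonotone=True)
        assert sampler.knots == tuple(sorted(spec.knots))

    def test_constant_spec_degenerate_at_zero(self):
        sampler = build_sampler(reference.get_spec("CYP2A6"))
        draws = sampler.draw(np.random.default_rng(0), 1000)
        assert np.all(draws == 0.0)

    def test_symmetric_knots_median(self):
        spec = VariableSpec("x", "", 0, 1, 2, 2, 3, 4)
        sampler = build_sampler(spec)
        draws = sampler.draw(np.random.default_rng(1), 100_000)
        assert abs(np.median(draws) - 2.0) < 0.02

    def test_potassium_median(self):
        sampler = build_sampler(reference.get_spec("K"))
        draws = sampler.draw(np.random.default_rng(2), 100_000)
        assert abs(np.median(draws) - 4.268) < 0.01

    def test_binary_sampler_mean(self):
        sampler = build_sampler(reference.get_spec("Sex_Code"))
        draws = sampler.draw(np.random.default_rng(3), 100_000)
        assert set(np.unique(draws)) <= {0.0, 1.0}
        assert abs(draws.mean() - 0.7718) < 0.01

    @pytest.mark.parametrize("name", ["K", "BSA", "Age", "Cardiac_Output"])
    def test_ks_distance_to_quantile_model(self, name):
        """Large samples track the piecewise-linear CDF to KS < 0.01."""
        from scipy import stats

        sampler = build_sampler(reference.get_spec(name))
        draws = sampler.draw(np.random.default_rng(4), 100_000)
        ks = stats.ks_1samp(draws, sampler.cdf)
        assert ks.statistic < 0.01

    @given(knots=st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=5).map(sorted),
           seed=st.integers(0, 2**31 - 1))
    def test_draws_stay_within_observed_range(self, knots, seed):
        spec = VariableSpec("x", "", knots[0], knots[1], knots[2],
                            knots[2], knots[3], knots[4])
        sampler = build_sampler(spec)
        draws = sampler.draw(np.random.default_rng(seed), 500)
        assert np.all(draws >= knots[0]) and np.all(draws <= knots[4])


class TestDesign:
    def test_default_dimensions(self):
        design = default_design()
        assert design.n_patients == 63
        assert design.total_records == 10360
        assert len(design.arms) == 8
        assert int(design.allocation.sum()) == 10360
        assert np.all(design.allocation.sum(axis=1) >= 1)

    def test_allocation_is_near_equal(self):
        design = default_design()
        per_patient = design.allocation.sum(axis=1)
        assert per_patient.min() >= 10360 // 63
        assert per_patient.max() <= 10360 // 63 + 1

    def test_scaled_design(self):
        design = make_design(total_records=2000)
        assert design.total_records == 2000
        with pytest.raises(ValueError):
            make_design(n_patients=63, total_records=10)


class TestSamplePopulation:
    def test_default_row_count_and_schema(self):
        table = sample_population(seed=7)
        assert len(table) == 10360
        expected = ["patient_id", "arm"] + reference.variable_names() + ["dQTc"]
        assert list(table.columns) == expected
        assert not table.isna().any().any()

    def test_constant_columns_identically_zero(self):
        table = sample_population(design=make_design(total_records=500), seed=7)
        for spec in reference.VARIABLE_SUMMARIES:
            if spec.vclass == "constant":
                assert (table[spec.name] == 0).all()

    def test_sex_code_mean(self):
        table = sample_population(seed=8)
        assert abs(table["Sex_Code"].mean() - 0.7718) < 0.02

    def test_seed_reproducibility(self):
        d = make_design(total_records=400)
        a = sample_population(design=d, seed=5)
        b = sample_population(design=d, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = sample_population(design=d, seed=6)
        assert list(c.columns) == list(a.columns)
        assert not np.allclose(a["K"], c["K"])

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            sample_population()

    def test_mechanistic_mode_matches_equation(self, table1_scaler):
        from qtgp.qt_model import predict

        d = make_design(total_records=300)
        table = sample_population(design=d, seed=9, mode="mechanistic")
        expected = np.asarray(predict(table))
        assert np.allclose(table["dQTc"].to_numpy(), expected)

    def test_copula_hook_imposes_rank_correlation(self):
        names = ["Weight", "BSA"]
        corr = pd.DataFrame([[1.0, 0.8], [0.8, 1.0]], index=names, columns=names)
        d = make_design(total_records=4000)
        table = sample_population(design=d, seed=10, rank_corr=corr)
        rho = table[names].corr(method="spearman").iloc[0, 1]
        assert rho > 0.6
        # marginals unchanged
        assert abs(table["BSA"].median() - 1.937) < 0.02

    def test_arm_shift_factors(self):
        d = make_design(total_records=2000)
        shift = {"ketoconazole": {"IKr_inhibition": 2.0}}
        table = sample_population(design=d, seed=11, arm_inhibition_shift=shift)
        plain = sample_population(design=d, seed=11)
        keto = table["arm"] == "ketoconazole"
        assert np.allclose(table.loc[keto, "IKr_inhibition"],
                           2.0 * plain.loc[keto, "IKr_inhibition"])
        assert np.allclose(table.loc[~keto, "IKr_inhibition"],
                           plain.loc[~keto, "IKr_inhibition"])
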