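"""Factor coding, Box-Cox scan, OLS fits, effect screening, prediction."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emulstab import doe, synthetic
from emulstab.errors import AliasingError, InputError

in_range_formulations = st.builds(
    doe.Formulation,
    oil_pct=st.floats(10, 20),
    starch_pct=st.floats(0, 1.5),
    caseinate_pct=st.floats(0, 2),
    stir_rpm=st.floats(10000, 20000),
    stir_min=st.floats(5, 20),
)


class TestCoding:
    def test_center_point_codes_to_zero(self):
        f = doe.Formulation(15, 0.75, 1.0, 15000, 12.5)
        assert doe.code_factors(f) == pytest.approx(
            {"A": 0, "B": 0, "C": 0, "D": 0, "E": 0}
        )

    def test_endpoints(self):
        lo = doe.Formulation(10, 0, 0, 10000, 5)
        hi = doe.Formulation(20, 1.5, 2, 20000, 20)
        assert all(v == -1 for v in doe.code_factors(lo).values())
        assert all(v == +1 for v in doe.code_factors(hi).values())

    def test_interior_value(self):
        f = doe.Formulation(15, 1.125, 1.0, 15000, 12.5)
        assert doe.code_factors(f)["B"] == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            doe.code_factors(doe.Formulation(25, 0, 0, 10000, 5))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(in_range_formulations)
    def test_coding_involution(self, f):
        back = doe.decode_factors(doe.code_factors(f))
        for name in ("oil_pct", "starch_pct", "caseinate_pct", "stir_rpm", "stir_min"):
            assert getattr(back, name) == pytest.approx(getattr(f, name), abs=1e-9)


class TestBuiltinDesign:
    def test_run_codes(self):
        design = doe.builtin_design().set_index("run")
        assert design.loc[24, ["A", "B", "C", "D", "E"]].tolist() == [1, 1, 1, 1, 1]
        assert design.loc[1, ["A", "B", "C", "D", "E"]].tolist() == [-1, -1, -1, 1, -1]
        assert design.loc[24, "block"] == 3
        assert design.loc[1, "block"] == 1

    def test_center_runs_and_blocks(self):
        design = doe.builtin_design()
        centers = design[design[["A", "B", "C", "D", "E"]].abs().sum(axis=1) == 0]
        assert centers.run.tolist() == [2, 9, 16]
        assert sorted(design.block.unique()) == [1, 2, 3]

    def test_label_decoding(self):
        design = doe.builtin_design().set_index("run")
        assert doe.code_labels(design.loc[11]) == "M/m/m/M/M"
        assert doe.code_labels(design.loc[2]) == "a/a/a/a/a"


class TestBoxCox:
    def test_log_generated_data_selects_log(self, study_table):
        beta = {"const": 1.3, "B": -0.07, "D": -0.21, "E": -0.07}
        y = synthetic.generate_doe_responses(
            study_table, beta, transform="log10", noise_sd=0.03, seed=2
        )
        X = doe.model_matrix(study_table, ["B", "D", "E"])
        scan = doe.boxcox_scan(y, X)
        assert scan.transform == "log10"
        assert abs(scan.lambda_best) <= 0.25

    def test_linear_data_selects_identity(self, study_table):
        beta = {"const": 20.0, "D": -5.0, "B": -2.0}
        y = synthetic.generate_doe_responses(
            study_table, beta, transform="identity", noise_sd=0.3, seed=3
        )
        X = doe.model_matrix(study_table, ["B", "D"])
        scan = doe.boxcox_scan(y, X)
        assert scan.transform == "identity"

    def test_objective_continuous_at_zero(self, study_table):
        y = doe.response_vector(study_table, "s0")
        X = doe.model_matrix(study_table, list(doe.FACTOR_NAMES))
        grid = np.array([-2.0, -1e-6, 0.0, 1e-6, 2.0])
        scan = doe.boxcox_scan(y, X, lambdas=grid)
        sse = dict(zip(scan.lambdas, scan.sse))
        assert sse[-1e-6] == pytest.approx(sse[0.0], rel=1e-4)
        assert sse[1e-6] == pytest.approx(sse[0.0], rel=1e-4)

    def test_nonpositive_response_rejected(self, study_table):
        X = doe.model_matrix(study_table, ["A"])
        with pytest.raises(InputError):
            doe.boxcox_scan(np.linspace(-1, 1, 24), X)

    def test_grid_must_cover_default_range(self, study_table):
        X = doe.model_matrix(study_table, ["A"])
        with pytest.raises(InputError):
            doe.boxcox_scan(np.ones(24) + np.arange(24), X, lambdas=np.array([0.0, 1.0]))


class TestFit:
    def test_noiseless_perfect_fit(self, study_table):
        beta = {"const": 2.0, "A": 0.5, "BC": -0.25}
        y = synthetic.generate_doe_responses(study_table, beta, noise_sd=0.0)
        fit = doe.fit_linear_model(study_table, y, ["A", "BC"])
        assert fit.r2_raw == pytest.approx(1.0, abs=1e-12)
        assert fit.coefficients["BC"] == pytest.approx(-0.25, abs=1e-10)

    def test_matches_normal_equations_oracle(self, study_table):
        rng = np.random.default_rng(42)
        y = rng.normal(size=len(study_table))
        terms = ["A", "B", "D", "AB", "DE"]
        fit = doe.fit_linear_model(study_table, y, terms)
        X = doe.model_matrix(study_table, terms).to_numpy()
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.coefficients.to_numpy(), beta_oracle, atol=1e-8)

    def test_press_matches_explicit_leave_one_out(self, study_table):
        rng = np.random.default_rng(7)
        y = rng.normal(size=len(study_table))
        terms = ["A", "B", "C"]
        fit = doe.fit_linear_model(study_table, y, terms)
        X = doe.model_matrix(study_table, terms).to_numpy()
        press = 0.0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            beta = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
            press += (y[i] - X[i] @ beta) ** 2
        assert fit.press == pytest.approx(press, abs=1e-8)

    def test_r2_predicted_below_r2_raw(self, study_table):
        y = doe.response_vector(study_table, "s0")
        fit = doe.fit_linear_model(study_table, np.log10(y), doe.DEFAULT_TERMS["s0"])
        assert fit.r2_predicted <= fit.r2_raw
        assert fit.r2_adjusted <= fit.r2_raw

    def test_aliased_terms_reported(self):
        coded = pd.DataFrame(
            {
                "A": [-1, 1, -1, 1, -1, 1],
                "B": [-1, -1, 1, 1, -1, 1],
                "C": [-1, 1, -1, 1, -1, 1],  # aliased with A
                "D": [1, -1, -1, 1, 1, -1],
                "E": [1, 1, 1, -1, -1, -1],
            },
            dtype=float,
        )
        with pytest.raises(AliasingError) as err:
            doe.fit_linear_model(coded, np.arange(6.0), ["A", "C"])
        assert "C" in err.value.aliased_terms

    def test_hierarchy_enforcement(self):
        assert doe.enforce_hierarchy(["AB", "C"]) == ["A", "B", "AB", "C"]
        assert doe.enforce_hierarchy(["A", "B", "AB"]) == ["A", "B", "AB"]


class TestPareto:
    def test_bonferroni_at_least_t_limit(self, study_table):
        fit = doe.fit_response(study_table, response="s0")
        pareto = doe.effect_pareto(fit, alpha=0.05)
        assert pareto.bonferroni_limit > pareto.t_limit
        single = doe.effect_pareto(fit, alpha=0.05, m_effects=1)
        assert single.bonferroni_limit == pytest.approx(single.t_limit)

    def test_null_response_rarely_exceeds_bonferroni(self, study_table):
        exceed = 0
        n_sims = 60
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=len(study_table))
            fit = doe.fit_linear_model(study_table, y, doe.DEFAULT_TERMS["s0"])
            pareto = doe.effect_pareto(fit, alpha=0.05)
            exceed += int((pareto.table.flag == "highly-significant").any())
        # familywise error should be near alpha; generous margin for 60 sims
        assert exceed / n_sims <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sims)

    def test_study_screens_reproduce_dominant_effects(self, study_table):
        # size at T0: exactly five effects clear the Bonferroni limit,
        # stirring velocity (D) dominating
        fit0 = doe.fit_response(study_table, response="s0")
        pareto0 = doe.effect_pareto(fit0)
        top = pareto0.table[pareto0.table.flag == "highly-significant"]
        assert set(top.term) == {"D", "AE", "E", "BC", "B"}
        assert pareto0.table.term.iloc[0] == "D"
        # variation rate: every main effect reduces the rate (negative
        # coefficients); caseinate (C) and stirring time (E) are the
        # strongest screens
        fitv = doe.fit_response(study_table, response="var")
        paretov = doe.effect_pareto(fitv)
        tabv = paretov.table.set_index("term")
        assert all(tabv.coefficient[f] < 0 for f in ["A", "B", "C", "D", "E"])
        assert tabv.flag["C"] == "highly-significant"
        assert tabv.flag["E"] == "highly-significant"

    def test_zero_residual_df_rejected(self, study_table):
        sub = study_table.head(8)
        y = doe.response_vector(sub, "s0")
        fit = doe.fit_linear_model(sub, y, list(doe.FACTOR_NAMES), include_blocks=False)
        # 8 obs, 6 params -> df 2: fine; now exhaust df
        full = doe.fit_linear_model(
            sub, y, ["A", "B", "C", "D", "E", "AB"], include_blocks=False
        )
        assert full.df_resid == 1
        exhausted = doe.fit_linear_model(
            sub, y, ["A", "B", "C", "D", "E", "AB", "AC"], include_blocks=False
        )
        with pytest.raises(InputError):
            doe.effect_pareto(exhausted)
        assert fit.df_resid == 2


class TestPredict:
    def test_center_prediction_back_transforms_constant(self, study_table):
        fit = doe.fit_response(study_table, response="s0")
        center = {f: 0.0 for f in doe.FACTOR_NAMES}
        pred = doe.predict_response(fit, center)
        assert pred == pytest.approx(10 ** fit.coefficients["const"], rel=1e-12)
        # the published constant of 1.34 puts the center near 22 um
        assert pred == pytest.approx(10**1.34, rel=0.02)

    def test_identity_round_trip_on_noiseless_data(self, study_table):
        beta = {"const": 5.0, "A": 1.0, "D": -2.0}
        y = synthetic.generate_doe_responses(study_table, beta, noise_sd=0.0)
        fit = doe.fit_linear_model(
            study_table, y, ["A", "D"], transform="identity"
        )
        coded = doe.coded_columns(study_table)
        for i in [0, 5, 23]:
            point = {f: coded[f].iloc[i] for f in doe.FACTOR_NAMES}
            assert doe.predict_response(fit, point) == pytest.approx(y[i], abs=1e-9)

    def test_domain_error_for_negative_root_predictor(self, study_table):
        # a fit whose transformed-scale prediction is negative cannot be
        # back-transformed through the square
        fit = doe.fit_linear_model(
            study_table, -np.ones(len(study_table)), ["A"], transform="sqrt"
        )
        with pytest.raises(InputError):
            doe.predict_response(fit, {"A": 0.0})

    def test_out_of_range_point_rejected(self, study_table):
        fit = doe.fit_response(study_table, response="s0")
        with pytest.raises(InputError):
            doe.predict_response(fit, {"A": 1.5})


class TestStudyData:
    def test_log_size_model_matches_published_fit(self, study_table):
        fit = doe.fit_response(study_table, response="s0")
        assert fit.r2_raw == pytest.approx(0.96, abs=0.02)
        assert fit.r2_adjusted == pytest.approx(0.93, abs=0.02)
        assert fit.r2_predicted == pytest.approx(0.85, abs=0.02)
        assert fit.coefficients["const"] == pytest.approx(1.34, abs=0.01)
        assert fit.coefficients["D"] == pytest.approx(-0.21, abs=0.005)

    def test_sqrt_family_for_t5_and_variation(self, study_table):
        assert doe.scan_response(study_table, "s5").transform == "sqrt"
        assert doe.scan_response(study_table, "var").transform == "sqrt"

    def test_inverse_sqrt_for_creaming_class(self, study_table):
        assert doe.scan_response(study_table, "class").transform == "inverse-sqrt"
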