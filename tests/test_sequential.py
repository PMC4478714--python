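import numpy as np
import pandas as pd
import pytest

from surveyfuse import FusionSpec, SchemaError, SurveyDataError, SurveyTable, VariableSchema
from surveyfuse.imputers import SequentialRegression, SubmodelSpec


@pytest.fixture
def linear_toy():
    """10-row single-outcome fixture with a known design matrix."""
    rng = np.random.default_rng(1)
    x1 = np.arange(10, dtype=float)
    x2 = rng.normal(0, 1, 10)
    y = 2.0 + 0.5 * x1 - 1.2 * x2 + rng.normal(0, 0.3, 10)
    schema = [
        VariableSchema("x1", "common", "continuous"),
        VariableSchema("x2", "common", "continuous"),
        VariableSchema("y", "specific", "continuous"),
    ]
    df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
    return SurveyTable(df, schema), FusionSpec(("x1", "x2"), ("y",))


class TestFitting:
    def test_ols_matches_normal_equations(self, linear_toy):
        donor, spec = linear_toy
        model = SequentialRegression(
            donor, spec, scheme=[SubmodelSpec("y", ("x1", "x2"))],
            selection=False, min_rows_per_param=2,
        )
        res = model.fit()
        fitted = res.submodels_["y"]
        X = np.column_stack(
            [np.ones(10), donor.df["x1"], donor.df["x2"]]
        )
        y = donor.df["y"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # independent oracle
        np.testing.assert_allclose(fitted.params, beta, rtol=1e-10)
        resid = y - X @ beta
        sigma = np.sqrt(resid @ resid / (10 - 3))
        assert fitted.sigma == pytest.approx(sigma, rel=1e-10)

    def test_backward_elimination_drops_noise_keeps_forced(self, small_scenario):
        donor = small_scenario["donor"]
        spec = small_scenario["spec"]
        scheme = [SubmodelSpec(name, ("sr_height", "sr_weight", "alcohol"),
                               forced=("alcohol",) if name == "height" else ())
                  for name in ("height",)]
        scheme += [SubmodelSpec(n, ("sr_weight", "age"))
                   for n in spec.specific_names if n != "height"]
        res = SequentialRegression(
            donor, spec, scheme=scheme, min_rows_per_param=2
        ).fit()
        # alcohol carries no information about height but is forced in
        assert "alcohol" in res.submodels_["height"].terms
        assert "sr_height" in res.submodels_["height"].terms

    def test_degenerate_categorical_outcome(self, toy_schema, toy_spec):
        df = pd.DataFrame(
            {
                "gender": ["Female", "Male"] * 10,
                "age": np.linspace(20, 60, 20),
                "bp": np.linspace(110, 150, 20),
                "status": ["No"] * 20,
            }
        )
        donor = SurveyTable(df, toy_schema)
        model = SequentialRegression(
            donor, toy_spec, scheme=[
                SubmodelSpec("bp", ("age",)), SubmodelSpec("status", ("age",)),
            ], min_rows_per_param=2,
        )
        with pytest.raises(SurveyDataError, match="single observed level"):
            model.fit()

    def test_chain_order_violation(self, toy_donor, toy_spec):
        scheme = [
            SubmodelSpec("bp", ("age", "status")),  # status not yet imputed
            SubmodelSpec("status", ("age",)),
        ]
        with pytest.raises(SchemaError, match="chain-order"):
            SequentialRegression(toy_donor, toy_spec, scheme=scheme)

    def test_rows_per_parameter_guard(self, linear_toy):
        donor, spec = linear_toy
        with pytest.raises(ValueError, match="guard"):
            SequentialRegression(
                donor, spec, scheme=[SubmodelSpec("y", ("x1", "x2"))],
                selection=False, min_rows_per_param=10,
            ).fit()

    def test_summary_mentions_every_submodel(self, linear_toy):
        donor, spec = linear_toy
        res = SequentialRegression(
            donor, spec, scheme=[SubmodelSpec("y", ("x1",))],
            selection=False, min_rows_per_param=2,
        ).fit()
        assert "y" in res.summary()


class TestImputation:
    def test_zero_noise_limit_is_conditional_mean(self, linear_toy):
        donor, spec = linear_toy
        res = SequentialRegression(
            donor, spec, scheme=[SubmodelSpec("y", ("x1", "x2"))],
            selection=False, min_rows_per_param=2,
        ).fit()
        fitted = res.submodels_["y"]
        fitted.sigma = 0.0
        masked = SurveyTable(
            donor.df.assign(y=np.nan), donor.schema, check=False
        )
        out = res.impute(masked, seed=0)
        X = np.column_stack([np.ones(10), donor.df["x1"], donor.df["x2"]])
        np.testing.assert_allclose(out.df["y"], X @ fitted.params)

    def test_derived_bmi_consistent_with_drawn_values(self, small_scenario):
        donor, spec = small_scenario["donor"], small_scenario["spec"]
        from surveyfuse.health import build_clinical_scheme
        from surveyfuse.synthetic import default_fusion_spec

        scheme = [s for s in build_clinical_scheme(default_fusion_spec())
                  if s.name in spec.specific_names]
        res = SequentialRegression(
            donor, spec, scheme=scheme, min_rows_per_param=2
        ).fit()
        recipient = small_scenario["recipient"].take(
            small_scenario["recipient"].df.index[:50]
        )
        out = res.impute(recipient, seed=4)
        expected = out.df["weight"] / (out.df["height"] / 100.0) ** 2
        np.testing.assert_allclose(out.df["bmi"], expected)

    def test_repeated_draws_center_on_fitted_mean(self, linear_toy):
        donor, spec = linear_toy
        res = SequentialRegression(
            donor, spec, scheme=[SubmodelSpec("y", ("x1", "x2"))],
            selection=False, min_rows_per_param=2,
        ).fit()
        fitted = res.submodels_["y"]
        one_row = SurveyTable(
            donor.df.iloc[[3]].assign(y=np.nan), donor.schema, check=False
        )
        draws = np.array(
            [res.impute(one_row, seed=s).df["y"].iloc[0] for s in range(1000)]
        )
        X = np.array([1.0, donor.df["x1"].iloc[3], donor.df["x2"].iloc[3]])
        mean = X @ fitted.params
        mc_se = fitted.sigma / np.sqrt(len(draws))
        assert abs(draws.mean() - mean) < 3 * mc_se

    def test_seed_contract(self, small_scenario):
        donor, spec = small_scenario["donor"], small_scenario["spec"]
        from surveyfuse.health import build_clinical_scheme
        from surveyfuse.synthetic import default_fusion_spec

        scheme = [s for s in build_clinical_scheme(default_fusion_spec())
                  if s.name in spec.specific_names]
        res = SequentialRegression(
            donor, spec, scheme=scheme, min_rows_per_param=2
        ).fit()
        recipient = small_scenario["recipient"].take(
            small_scenario["recipient"].df.index[:30]
        )
        a = res.impute(recipient, seed=8).df
        b = res.impute(recipient, seed=8).df
        c = res.impute(recipient, seed=9).df
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_parameter_draws_add_between_variation(self, linear_toy):
        donor, spec = linear_toy
        res = SequentialRegression(
            donor, spec, scheme=[SubmodelSpec("y", ("x1", "x2"))],
            selection=False, min_rows_per_param=2,
        ).fit()
        masked = SurveyTable(donor.df.assign(y=np.nan), donor.schema, check=False)
        plain = [res.impute(masked, seed=s).df["y"].mean() for s in range(30)]
        proper = [
            res.impute(masked, seed=s, draw_parameters=True).df["y"].mean()
            for s in range(30)
        ]
        assert np.var(proper) > np.var(plain)
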