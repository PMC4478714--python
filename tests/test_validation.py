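import numpy as np
import pandas as pd
import pytest
from scipy import stats

from surveyfuse import (
    FusionSpec,
    SurveyTable,
    ValidationReport,
    VariableSchema,
    predictive_relevance,
    validate_fusion,
)
from surveyfuse.validation import (
    STAT_ORDER,
    correlation_discrepancy,
    distribution_similarity,
    imputation_accuracy,
    marginal_asl,
    multivariate_congruence,
    residual_randomness,
)


def numeric_tables(obs_y, imp_y, x=None, extra_y=None):
    """Build paired observed/imputed tables from raw arrays."""
    n = len(obs_y)
    x = np.arange(n, dtype=float) if x is None else np.asarray(x, float)
    schema = [
        VariableSchema("x", "common", "continuous"),
        VariableSchema("y", "specific", "continuous"),
    ]
    obs = {"x": x, "y": np.asarray(obs_y, float)}
    imp = {"x": x, "y": np.asarray(imp_y, float)}
    if extra_y is not None:
        schema.append(VariableSchema("y2", "specific", "continuous"))
        obs["y2"], imp["y2"] = extra_y
        spec = FusionSpec(("x",), ("y", "y2"))
    else:
        spec = FusionSpec(("x",), ("y",))
    return SurveyTable(pd.DataFrame(obs), schema), SurveyTable(pd.DataFrame(imp), schema), spec


class TestPerfectImputationFixedPoint:
    def test_full_report_ideal_values(self, small_scenario):
        donor, spec = small_scenario["donor"], small_scenario["spec"]
        report = validate_fusion(donor, donor.copy(), spec)
        s = report.statistics
        assert s["ASLm"] == 1.0 and s["ASLs"] == 1.0
        assert s["ACDi"] == 0.0 and s["ACDe"] == 0.0
        assert s["WC"] == pytest.approx(1.0)
        assert s["ASD"] == 0.0
        assert s["TAU"] == 1.0
        assert s["RndRes"] == 1.0 and "RndRes" in report.degenerate

    def test_report_serialization_roundtrip(self, small_scenario):
        donor, spec = small_scenario["donor"], small_scenario["spec"]
        report = validate_fusion(donor, donor.copy(), spec)
        back = ValidationReport.from_json(report.to_json())
        assert back.statistics == report.statistics
        assert back.orientation == report.orientation


class TestMarginalASL:
    def test_single_variable_equals_its_p(self):
        rng = np.random.default_rng(0)
        obs, imp, spec = numeric_tables(rng.normal(0, 1, 200), rng.normal(0, 1, 200))
        aslm, asls, detail = marginal_asl(obs, imp, spec)
        assert aslm == pytest.approx(detail["y"]["p_mean"])
        assert asls == pytest.approx(detail["y"]["p_sd"])

    def test_shifted_variable_detected_and_matches_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(5, 1, 1000)  # five-SD shift
        obs, imp, spec = numeric_tables(a, b)
        aslm, _, detail = marginal_asl(obs, imp, spec)
        assert aslm < 1e-6
        oracle = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert detail["y"]["p_mean"] == pytest.approx(oracle, rel=1e-6, abs=1e-12)

    def test_inflated_spread_detected(self):
        rng = np.random.default_rng(2)
        obs, imp, spec = numeric_tables(
            rng.normal(0, 1, 800), rng.normal(0, 3, 800)
        )
        _, asls, _ = marginal_asl(obs, imp, spec)
        assert asls < 1e-4


class TestCorrelationDiscrepancy:
    def test_hand_computed_difference(self):
        # y2 = y in observed (corr 1); imputed y2 independent of y
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 400)
        y_imp = rng.normal(0, 1, 400)
        obs, imp, spec = numeric_tables(
            y, y, extra_y=(y.copy(), rng.normal(0, 1, 400))
        )
        acdi, acde, detail = correlation_discrepancy(obs, imp, spec)
        pair = detail["internal"]["y~y2"]
        r_obs = np.corrcoef(obs.df["y"], obs.df["y2"])[0, 1]
        r_imp = np.corrcoef(imp.df["y"], imp.df["y2"])[0, 1]
        assert pair["observed"] == pytest.approx(r_obs)
        assert pair["imputed"] == pytest.approx(r_imp)
        assert acdi == pytest.approx(abs(r_obs - r_imp))

    def test_row_permutation_breaks_links_not_marginals(self, small_scenario):
        donor, spec = small_scenario["donor"], small_scenario["spec"]
        rng = np.random.default_rng(4)
        perm = rng.permutation(donor.n)
        shuffled = donor.df.copy()
        shuffled[list(spec.specific_names)] = (
            donor.df[list(spec.specific_names)].to_numpy()[perm]
        )
        imputed = SurveyTable(shuffled, donor.schema, check=False)
        asd, _ = distribution_similarity(donor, imputed, spec)
        _, acde, _ = correlation_discrepancy(donor, imputed, spec)
        tau, _ = imputation_accuracy(donor, imputed, spec)
        assert asd == 0.0           # marginals untouched
        assert acde > 0.02          # donor-common links destroyed
        assert tau < 0.1            # accuracy gone


class TestMultivariateCongruence:
    def test_sign_flip_matches_closed_form(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 300)
        y2 = 0.8 * y + 0.6 * rng.normal(0, 1, 300)
        obs, imp, spec = numeric_tables(y, y, extra_y=(y2, -y2))
        wc = multivariate_congruence(obs, imp, spec)
        # independent closed form from the two scatter matrices
        Z1 = np.column_stack([obs.df["x"], obs.df["y"], obs.df["y2"]])
        Z2 = np.column_stack([imp.df["x"], imp.df["y"], imp.df["y2"]])
        Z1 = Z1 - Z1.mean(0)
        Z2 = Z2 - Z2.mean(0)
        S1, S2 = Z1.T @ Z1, Z2.T @ Z2
        expected = (S1 * S2).sum() / (np.linalg.norm(S1) * np.linalg.norm(S2))
        assert wc == pytest.approx(expected, rel=1e-12)

    def test_degenerate_block_rejected(self):
        obs, imp, spec = numeric_tables(np.zeros(10), np.zeros(10),
                                        x=np.zeros(10))
        with pytest.raises(ValueError, match="degenerate"):
            multivariate_congruence(obs, imp, spec)


class TestDistributionSimilarity:
    def test_total_variation_example(self):
        schema = [
            VariableSchema("x", "common", "continuous"),
            VariableSchema("c", "specific", "categorical", ("A", "B")),
        ]
        spec = FusionSpec(("x",), ("c",))
        obs = SurveyTable(
            pd.DataFrame({"x": np.arange(10.0), "c": ["A"] * 5 + ["B"] * 5}), schema
        )
        imp = SurveyTable(
            pd.DataFrame({"x": np.arange(10.0), "c": ["A"] * 7 + ["B"] * 3}), schema
        )
        asd, detail = distribution_similarity(obs, imp, spec)
        assert detail["c"] == pytest.approx(0.2)

    def test_continuous_uses_ks_statistic(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 400), rng.normal(0.8, 1, 400)
        obs, imp, spec = numeric_tables(a, b)
        asd, _ = distribution_similarity(obs, imp, spec)
        assert asd == pytest.approx(stats.ks_2samp(a, b).statistic)


class TestImputationAccuracy:
    def test_kappa_from_printed_table(self):
        schema = [
            VariableSchema("x", "common", "continuous"),
            VariableSchema("c", "specific", "categorical", ("A", "B")),
        ]
        spec = FusionSpec(("x",), ("c",))
        obs_vals = ["A"] * 50 + ["B"] * 50
        imp_vals = ["A"] * 40 + ["B"] * 10 + ["A"] * 10 + ["B"] * 40
        obs = SurveyTable(pd.DataFrame({"x": np.arange(100.0), "c": obs_vals}), schema)
        imp = SurveyTable(pd.DataFrame({"x": np.arange(100.0), "c": imp_vals}), schema)
        tau, detail = imputation_accuracy(obs, imp, spec)
        # closed form: po=0.8, pe=0.5 -> kappa = 0.6
        assert detail["c"] == pytest.approx(0.6)

    def test_permutation_null_near_zero(self):
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, 3000)
        obs, imp, spec = numeric_tables(y, rng.permutation(y))
        tau, detail = imputation_accuracy(obs, imp, spec, floor=-10.0)
        # error variance ~ 2x observed variance -> raw value near -1
        assert detail["y"] == pytest.approx(-1.0, abs=0.15)
        tau_floored, _ = imputation_accuracy(obs, imp, spec)
        assert tau_floored == 0.0


class TestResidualRandomness:
    def test_residual_equal_to_common_is_structure(self):
        x = np.linspace(-2, 2, 200)
        y = np.random.default_rng(8).normal(0, 1, 200)
        obs, imp, spec = numeric_tables(y + x, y, x=x)  # residual == x
        rnd, detail, degenerate = residual_randomness(obs, imp, spec)
        assert not degenerate
        assert rnd < 1e-6

    def test_hand_computed_correlation_p(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        obs_y = np.array([2.0, 1.5, 3.0, 2.5, 4.0, 3.5, 5.0, 4.5])
        imp_y = np.zeros(8)
        obs, imp, spec = numeric_tables(obs_y, imp_y, x=x)
        _, detail, _ = residual_randomness(obs, imp, spec)
        oracle = stats.pearsonr(x, obs_y - imp_y).pvalue
        assert detail["y"]["x"] == pytest.approx(oracle, rel=1e-9)

    def test_null_p_values_average_one_half(self):
        rng = np.random.default_rng(9)
        vals = []
        for _ in range(60):
            y = rng.normal(0, 1, 300)
            resid = rng.normal(0, 1, 300)
            obs, imp, spec = numeric_tables(y, y - resid, x=rng.normal(0, 1, 300))
            rnd, _, _ = residual_randomness(obs, imp, spec)
            vals.append(rnd)
        se = np.sqrt(1 / 12 / len(vals))
        assert abs(np.mean(vals) - 0.5) < 3 * se


class TestPredictiveRelevance:
    def test_exact_linear_function_has_full_power(self):
        x = np.linspace(0, 10, 50)
        obs, _, spec = numeric_tables(2 * x + 1, 2 * x + 1, x=x)
        report = predictive_relevance(obs, spec)
        assert report.loc["y", "power"] == pytest.approx(1.0)

    def test_independent_outcome_has_no_power(self):
        rng = np.random.default_rng(10)
        obs, _, spec = numeric_tables(
            rng.normal(0, 1, 2000), rng.normal(0, 1, 2000), x=rng.normal(0, 1, 2000)
        )
        report = predictive_relevance(obs, spec)
        assert report.loc["y", "power"] < 0.01
        assert bool(report.loc["y", "weak"])


class TestInvariances:
    def test_row_and_column_order_invariance(self, small_scenario):
        donor, spec = small_scenario["donor"], small_scenario["spec"]
        rng = np.random.default_rng(11)
        noisy = donor.df.copy()
        cont = [n for n in spec.specific_names
                if not donor.variable(n).is_categorical]
        noisy[cont] = noisy[cont] + rng.normal(0, 1, (donor.n, len(cont)))
        imputed = SurveyTable(noisy, donor.schema, check=False)
        base = validate_fusion(donor, imputed, spec).as_series()
        perm = rng.permutation(donor.n)
        shuffled = SurveyTable(imputed.df.iloc[perm], donor.schema, check=False)
        again = validate_fusion(donor, shuffled, spec).as_series()
        pd.testing.assert_series_equal(base, again)
        spec_reordered = FusionSpec(
            tuple(reversed(spec.common_names)), tuple(reversed(spec.specific_names))
        )
        reordered = validate_fusion(donor, imputed, spec_reordered).as_series()
        np.testing.assert_allclose(base.to_numpy(), reordered.to_numpy(), atol=1e-12)
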