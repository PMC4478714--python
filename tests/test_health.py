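import numpy as np
import pandas as pd
import pytest

from surveyfuse import (
    ConditionThresholds,
    MultiImputation,
    SurveyTable,
    build_clinical_scheme,
    classify_alcohol,
    classify_conditions,
    compute_bmi,
    estimate_prevalence,
    multiply_impute,
)
from surveyfuse.synthetic import default_fusion_spec


def record(**overrides):
    base = {
        "glucose": [100.0], "bp_sys": [120.0], "bp_dia": [75.0],
        "cholesterol": [190.0], "bmi": [24.0], "waist": [85.0],
        "gender": ["Male"],
    }
    base.update({k: [v] for k, v in overrides.items()})
    return pd.DataFrame(base)


class TestComputeBmi:
    def test_printed_example(self):
        assert compute_bmi(81.0, 1.80) == pytest.approx(25.0)

    @pytest.mark.parametrize("h,c", [(1.6, 20.0), (1.85, 31.5)])
    def test_algebraic_identity(self, h, c):
        assert compute_bmi(h * h * c, h) == pytest.approx(c)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            compute_bmi(70.0, 0.0)


class TestClassifyConditions:
    def test_glucose_threshold_inclusive(self):
        flags = classify_conditions(record(glucose=126.0))
        assert bool(flags["hyperglycemia"].iloc[0])
        assert not classify_conditions(record(glucose=125.9))["hyperglycemia"].iloc[0]

    def test_diabetes_medication_clause(self):
        df = record(glucose=90.0)
        df["declared_diab"] = ["Diab with treat"]
        assert bool(classify_conditions(df)["hyperglycemia"].iloc[0])

    def test_diabetic_bp_thresholds(self):
        healthy = classify_conditions(record(bp_sys=136.0, bp_dia=80.0))
        assert not bool(healthy["hypertension"].iloc[0])
        diabetic = classify_conditions(
            record(bp_sys=136.0, bp_dia=80.0, glucose=130.0)
        )
        assert bool(diabetic["hypertension"].iloc[0])

    def test_bp_medication_clause(self):
        df = record(bp_sys=110.0)
        df["declared_bp"] = ["BP with treat"]
        assert bool(classify_conditions(df)["hypertension"].iloc[0])

    def test_bmi_threshold_strict(self):
        assert not bool(classify_conditions(record(bmi=25.0))["obesity"].iloc[0])
        assert bool(classify_conditions(record(bmi=25.01))["obesity"].iloc[0])

    def test_waist_threshold_by_gender(self):
        m = classify_conditions(record(waist=102.5, gender="Male"))
        f = classify_conditions(record(waist=88.5, gender="Female"))
        f_not = classify_conditions(record(waist=88.0, gender="Female"))
        assert bool(m["abdominal_obesity"].iloc[0])
        assert bool(f["abdominal_obesity"].iloc[0])
        assert not bool(f_not["abdominal_obesity"].iloc[0])

    def test_monotone_in_measurements(self):
        rng = np.random.default_rng(0)
        base = pd.concat([record() for _ in range(20)], ignore_index=True)
        base["glucose"] = rng.uniform(80, 200, 20)
        raised = base.copy()
        raised["glucose"] += 30.0
        f0 = classify_conditions(base)["hyperglycemia"]
        f1 = classify_conditions(raised)["hyperglycemia"]
        assert (f1 | ~f0).all()  # raising glucose never clears the flag

    def test_missing_field_and_bad_gender(self):
        with pytest.raises(KeyError):
            classify_conditions(record().drop(columns=["waist"]))
        with pytest.raises(ValueError, match="gender"):
            classify_conditions(record(gender="Other"))

    def test_threshold_invariants(self):
        with pytest.raises(ValueError):
            ConditionThresholds(bp_sys_diab=150.0)
        with pytest.raises(ValueError):
            ConditionThresholds(chol_high=-1.0)


class TestClassifyAlcohol:
    @pytest.mark.parametrize(
        "grams,gender,expected",
        [
            (0.0, "Male", "Non drinker"),
            (279.9, "Male", "Moderate drinker"),
            (280.0, "Male", "Risk drinker"),
            (170.0, "Female", "Risk drinker"),
            (169.9, "Female", "Moderate drinker"),
        ],
    )
    def test_boundaries(self, grams, gender, expected):
        assert classify_alcohol(grams, gender) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_alcohol(-1.0, "Male")


class TestClinicalScheme:
    def test_default_chain_structure(self):
        spec = default_fusion_spec()
        scheme = build_clinical_scheme(spec)
        names = [s.name for s in scheme]
        assert names.index("height") < names.index("weight") < names.index("bmi")
        assert names[-2:] == ["cvd", "diabetes"]
        bmi = next(s for s in scheme if s.name == "bmi")
        assert bmi.kind == "derived"
        stochastic = [s for s in scheme if s.kind != "derived"]
        assert len(stochastic) == len(scheme) - 1

    def test_order_violation_raises(self):
        from surveyfuse.imputers import SequentialRegression

        spec = default_fusion_spec()
        scheme = build_clinical_scheme(spec, candidates={"height": ("bmi",)})
        donor = None
        with pytest.raises(Exception, match="chain-order|bmi"):
            # bmi cited before it exists in the chain
            from surveyfuse.synthetic import PopulationParams, generate_population

            donor, _ = generate_population(PopulationParams(n=100), seed=0)
            SequentialRegression(donor, spec, scheme=scheme)

    def test_empty_candidates_rejected(self):
        spec = default_fusion_spec()
        with pytest.raises(ValueError, match="height"):
            build_clinical_scheme(spec, candidates={"height": ()})


class TestEstimatePrevalence:
    def make_multi(self, recipient, tables):
        return MultiImputation(tables, "knn", 0, tuple(range(len(tables))))

    def test_all_positive_gives_unit_prevalence(self, small_scenario):
        donor, spec = small_scenario["donor"], small_scenario["spec"]
        donor_df = donor.df.copy()
        donor_df["hyperglycemia"] = "Yes"
        donor_pos = SurveyTable(donor_df, donor.schema, check=False)
        rec = small_scenario["recipient"].take(
            small_scenario["recipient"].df.index[:30]
        )
        rec_df = rec.df.copy()
        rec_df[list(spec.specific_names)] = 0.0
        rec_df["hyperglycemia"] = "Yes"
        completed = SurveyTable(rec_df, rec.schema, check=False)
        multi = self.make_multi(rec, [completed, completed.copy()])
        table = estimate_prevalence(donor_pos, multi, "hyperglycemia").frame
        g = table.iloc[0]
        assert g.donor_rate == 1.0 and g.fused_rate == 1.0 and g.B == 0.0

    def test_sd_ratio_is_donor_over_fused(self, small_scenario):
        donor, spec = small_scenario["donor"], small_scenario["spec"]
        rec = small_scenario["recipient"].take(
            small_scenario["recipient"].df.index[:80]
        )
        multi = multiply_impute("knn", donor, rec, spec, m=3, seed=2)
        table = estimate_prevalence(donor, multi, "hyperglycemia",
                                    ("gender",)).frame
        g = table[table.subgroup == "global"].iloc[0]
        assert g.sd_ratio == pytest.approx(g.donor_sd / g.fused_sd)
        assert set(table.subgroup) == {"global", "Female", "Male"}

    def test_empty_subgroup_marked_unavailable(self, small_scenario):
        donor, spec = small_scenario["donor"], small_scenario["spec"]
        rec = small_scenario["recipient"].take(
            small_scenario["recipient"].df.index[:40]
        )
        multi = multiply_impute("knn", donor, rec, spec, m=2, seed=3)
        # age_group level '75+' may be present; drop it from the donor to
        # force an empty donor cell
        donor_df = donor.df[donor.df["age_group"] != "75+"]
        donor_cut = SurveyTable(donor_df, donor.schema, check=False)
        table = estimate_prevalence(donor_cut, multi, "hyperglycemia",
                                    ("age_group",)).frame
        row = table[table.subgroup == "75+"].iloc[0]
        assert not row["available"]

    def test_donor_only_when_recipient_empty(self, small_scenario):
        donor, spec = small_scenario["donor"], small_scenario["spec"]
        empty_df = small_scenario["recipient"].df.iloc[:0]
        empty = SurveyTable(empty_df, donor.schema, check=False)
        multi = self.make_multi(empty, [empty, empty.copy()])
        table = estimate_prevalence(donor, multi, "hyperglycemia").frame
        g = table.iloc[0]
        assert g.fused_rate == pytest.approx(g.donor_rate)
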