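"""Application layer: clinical risk factors, condition rules and prevalence.

Builds the sequential-regression scheme used to impute the clinical block
(height -> weight -> BMI -> waist -> blood pressure -> cholesterol ->
glucose) with terminal logistic models for cardiovascular disease and
diabetes, applies standard clinical thresholds to classify risk-factor
conditions, and estimates condition prevalences — from the donor file alone
and from the fused file (donors plus multiply imputed recipients) — with
their standard deviations and the donor/fused SD ratio.  An SD ratio above
one means the fusion bought precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mi import MultiImputation, PooledEstimate, pool_estimates
from .imputers.sequential import SubmodelSpec
from .schema import FusionSpec, SurveyTable


@dataclass(frozen=True)
class ConditionThresholds:
    """Clinical classification thresholds (units in field names' docs).

    Defaults follow the standard epidemiological rules: hyperglycemia at
    fasting glucose >= 126 mg/dL (inclusive); hypertension at systolic > 140
    or diastolic > 90 mmHg, tightened to 135/85 for diabetic persons;
    cholesterolemia above 250 mg/dL; obesity at BMI above 25 kg/m2;
    abdominal obesity above 102 cm (men) / 88 cm (women); risk drinking at
    or above 280 g (men) / 170 g (women) of pure alcohol per week.
    """

    glucose_hyper: float = 126.0
    bp_sys: float = 140.0
    bp_dia: float = 90.0
    bp_sys_diab: float = 135.0
    bp_dia_diab: float = 85.0
    chol_high: float = 250.0
    bmi_obese: float = 25.0
    waist_male: float = 102.0
    waist_female: float = 88.0
    alcohol_male: float = 280.0
    alcohol_female: float = 170.0

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be > 0")
        if self.bp_sys_diab > self.bp_sys or self.bp_dia_diab > self.bp_dia:
            raise ValueError("diabetic BP thresholds cannot exceed the general ones")


def compute_bmi(weight_kg, height_m):
    """Body-mass index: weight [kg] divided by squared height [m]."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    if (weight_kg <= 0).any() or (height_m <= 0).any():
        raise ValueError("weight and height must be positive")
    return weight_kg / height_m**2


def classify_alcohol(weekly_grams: float, gender: str,
                     thresholds: ConditionThresholds = ConditionThresholds()) -> str:
    """Weekly pure-alcohol intake -> non-drinker / moderate / risk.

    Moderate drinking is strictly below the gender bound; intake at or above
    it is risk drinking.
    """
    if weekly_grams < 0:
        raise ValueError("negative alcohol intake")
    if weekly_grams == 0:
        return "Non drinker"
    bound = (thresholds.alcohol_male if gender == "Male"
             else thresholds.alcohol_female)
    return "Moderate drinker" if weekly_grams < bound else "Risk drinker"


def classify_conditions(
    record: pd.DataFrame | dict,
    thresholds: ConditionThresholds = ConditionThresholds(),
) -> pd.DataFrame:
    """Clinical condition flags from measurements and treatment status.

    ``record`` needs glucose, bp_sys, bp_dia, cholesterol, bmi, waist,
    gender, and optionally the declared statuses ``declared_diab`` /
    ``declared_bp`` whose 'with treat' level activates the medication
    clauses.  Rules (all monotone in the measurements):

    * hyperglycemia: glucose >= 126 (inclusive) OR on diabetes medication
    * hypertension: sys > 140 OR dia > 90 (135/85 for diabetic persons)
      OR on blood-pressure medication
    * cholesterolemia: cholesterol > 250
    * obesity: BMI > 25
    * abdominal obesity: waist > 102 (men) / > 88 (women)
    """
    df = pd.DataFrame(record) if not isinstance(record, pd.DataFrame) else record
    required = ("glucose", "bp_sys", "bp_dia", "cholesterol", "bmi", "waist", "gender")
    for name in required:
        if name not in df.columns:
            raise KeyError(f"required field {name!r} missing")
    male = df["gender"] == "Male"
    female = df["gender"] == "Female"
    if not (male | female).all():
        bad = df.loc[~(male | female), "gender"].iloc[0]
        raise ValueError(f"unknown gender level {bad!r}")
    t = thresholds
    diab_med = (
        df["declared_diab"].eq("Diab with treat")
        if "declared_diab" in df.columns
        else pd.Series(False, index=df.index)
    )
    bp_med = (
        df["declared_bp"].eq("BP with treat")
        if "declared_bp" in df.columns
        else pd.Series(False, index=df.index)
    )
    hyperglycemia = (df["glucose"] >= t.glucose_hyper) | diab_med
    diabetic = hyperglycemia
    sys_cut = np.where(diabetic, t.bp_sys_diab, t.bp_sys)
    dia_cut = np.where(diabetic, t.bp_dia_diab, t.bp_dia)
    hypertension = (df["bp_sys"] > sys_cut) | (df["bp_dia"] > dia_cut) | bp_med
    out = pd.DataFrame(
        {
            "hyperglycemia": hyperglycemia,
            "hypertension": hypertension,
            "cholesterolemia": df["cholesterol"] > t.chol_high,
            "obesity": df["bmi"] > t.bmi_obese,
            "abdominal_obesity": np.where(
                male, df["waist"] > t.waist_male, df["waist"] > t.waist_female
            ),
        },
        index=df.index,
    )
    return out.astype(bool)


def _bmi_from_cm(df: pd.DataFrame) -> np.ndarray:
    return compute_bmi(df["weight"].to_numpy(float), df["height"].to_numpy(float) / 100.0)


def build_clinical_scheme(
    spec: FusionSpec, candidates: dict[str, tuple[str, ...]] | None = None
) -> list[SubmodelSpec]:
    """The default sequential-regression chain for the clinical block.

    Clinical height is predicted from self-reported height and weight plus
    gender-by-age-group interactions; clinical weight from imputed height
    and self-reported weight; BMI is derived by formula; then abdominal
    perimeter, blood pressure, cholesterol and glucose are modelled the same
    way; finally cardiovascular disease and diabetes get logistic submodels
    on the standard risk factors.  ``candidates`` overrides the per-submodel
    candidate sets; every candidate must be a common variable or an earlier
    outcome (chain order is checked by the engine).
    """
    default: dict[str, tuple[str, ...]] = {
        "height": ("sr_height", "sr_weight", "gender", "age_group",
                   "gender:age_group"),
        "weight": ("height", "sr_weight", "gender", "age"),
        "waist": ("weight", "bmi", "sr_weight", "gender", "age",
                  "declared_diab", "declared_bp", "declared_chol"),
        "bp_sys": ("age", "weight", "bmi", "gender", "declared_bp", "waist",
                   "declared_diab", "declared_chol"),
        "bp_dia": ("bp_sys", "weight", "age", "declared_bp"),
        "cholesterol": ("age", "gender", "declared_chol", "weight", "bmi",
                        "declared_diab", "declared_bp"),
        "glucose": ("age", "weight", "bmi", "waist", "declared_diab", "gender",
                    "declared_bp", "declared_chol"),
        "hyperglycemia": ("glucose", "declared_diab", "age", "bmi"),
        "cvd": ("declared_cvd", "gender", "age", "bmi", "cholesterol",
                "activity", "waist", "bp_sys", "education", "smoking"),
        "diabetes": ("declared_diab", "gender", "age", "bmi", "glucose",
                     "activity", "waist", "education"),
    }
    # predictors every epidemiologist would keep regardless of a marginal
    # p-value — the selection rule is medical sense AND significance, so
    # these are exempt from backward elimination
    forced: dict[str, tuple[str, ...]] = {
        "height": ("sr_height",),
        "weight": ("sr_weight", "height"),
        "waist": ("weight", "declared_diab"),
        "bp_sys": ("age", "weight", "declared_bp"),
        "bp_dia": ("bp_sys",),
        "cholesterol": ("age", "declared_chol"),
        "glucose": ("age", "weight", "declared_diab"),
        "hyperglycemia": ("glucose", "declared_diab"),
        "cvd": ("declared_cvd", "gender", "age"),
        "diabetes": ("declared_diab", "age", "glucose"),
    }
    if candidates:
        default.update(candidates)
    order = ["height", "weight", "bmi", "waist", "bp_sys", "bp_dia",
             "cholesterol", "glucose", "hyperglycemia", "cvd", "diabetes"]
    scheme: list[SubmodelSpec] = []
    for name in order:
        if name not in spec.specific_names:
            continue
        if name == "bmi":
            scheme.append(SubmodelSpec("bmi", derive=_bmi_from_cm))
            continue
        cands = default.get(name)
        if not cands:
            raise ValueError(f"submodel {name!r} has an empty candidate set")
        keep = tuple(t for t in forced.get(name, ()) if t in cands)
        scheme.append(SubmodelSpec(name, cands, forced=keep))
    return scheme


@dataclass
class PrevalenceTable:
    """Prevalence per (condition, subgroup) from donor-only and fused data."""

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def estimate_prevalence(
    donor: SurveyTable,
    fused: MultiImputation,
    condition: str,
    subgroup_vars: tuple[str, ...] = (),
    positive_level: str = "Yes",
) -> PrevalenceTable:
    """Prevalence with SD from donors alone vs the fused file.

    The donor entry is the sample proportion with binomial SD on n0 rows.
    The fused entry pools, across the m completed recipient tables, the
    proportion over donor + recipient rows (binomial within-variance on the
    combined size) via the within/between decomposition.  The SD ratio
    donor/fused measures the precision gained by the fusion.  Empty
    subgroup cells are marked unavailable rather than fabricated.
    """
    if condition not in donor.df.columns:
        raise KeyError(f"condition {condition!r} missing from donor")
    rows = []
    donor_vals = donor.df[condition]

    def cell(label_var: str, label: str, donor_mask, rec_masks) -> None:
        d = donor_vals[donor_mask]
        n0 = len(d)
        estimates, variances = [], []
        for t, rmask in zip(fused.tables, rec_masks):
            vals = pd.concat([d, t.df.loc[rmask, condition]])
            n = len(vals)
            if n == 0:
                continue
            p = float((vals == positive_level).mean())
            estimates.append(p)
            variances.append(p * (1 - p) / n)
        if n0 == 0 or not estimates:
            rows.append(
                {"condition": condition, "subgroup_var": label_var,
                 "subgroup": label, "available": False}
            )
            return
        p0 = float((d == positive_level).mean())
        sd0 = float(np.sqrt(p0 * (1 - p0) / n0))
        pooled = pool_estimates(estimates, variances)
        rows.append(
            {
                "condition": condition,
                "subgroup_var": label_var,
                "subgroup": label,
                "available": True,
                "n_donor": n0,
                "n_fused": n0 + int(rec_masks[0].sum()),
                "donor_rate": p0,
                "donor_sd": sd0,
                "fused_rate": pooled.qbar,
                "fused_sd": pooled.sd,
                "W": pooled.W,
                "B": pooled.B,
                "sd_ratio": sd0 / pooled.sd if pooled.sd > 0 else np.nan,
            }
        )

    all_donor = pd.Series(True, index=donor.df.index)
    all_rec = [pd.Series(True, index=t.df.index) for t in fused.tables]
    cell("global", "global", all_donor, all_rec)
    for var in subgroup_vars:
        levels = donor.variable(var).levels or sorted(donor.df[var].unique())
        for lev in levels:
            dmask = donor.df[var] == lev
            rmasks = [t.df[var] == lev for t in fused.tables]
            cell(var, lev, dmask, rmasks)
    return PrevalenceTable(pd.DataFrame(rows))
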