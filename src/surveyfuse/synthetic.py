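"""Synthetic health-survey populations with known ground truth.

Emulates the structure of a large interview survey (self-reported
demographics and behaviour) containing a small clinical-examination
subsample: a chain of linear models generates the clinical block
(height -> weight -> waist -> blood pressure -> cholesterol -> glucose),
self-reports are the clinical values plus reporting error, declared
condition statuses are noisy discretisations of the clinical values, and
two condition flags (cardiovascular disease, diabetes) follow logistic
models on the standard risk factors.  Because the generating chain matches
the order in which the sequential-regression imputer works, parameter
recovery on these data is a fair test of that engine.

All default magnitudes are plausible for an adult European population but
are fixtures chosen for testing — they are not estimates of any real
population.  Glucose carries a right-skewed (gamma) residual, as fasting
glucose does in real data; every other continuous residual is normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .schema import (
    KIND_CATEGORICAL,
    KIND_CONTINUOUS,
    ROLE_COMMON,
    ROLE_SPECIFIC,
    FusionSpec,
    SurveyTable,
    VariableSchema,
)

AGE_GROUPS = ("18:29", "30:44", "45:59", "60:74", "75+")
AGE_EDGES = (18.0, 30.0, 45.0, 60.0, 75.0, np.inf)

SMOKING_LEVELS = ("Non smoker", "Ex-smoker", "Occasional smoker", "Regular smoker")
ACTIVITY_LEVELS = ("Sedentary", "Light", "Moderate", "Vigorous")
ALCOHOL_LEVELS = ("Non drinker", "Moderate drinker", "Risk drinker")
EDUCATION_LEVELS = ("Primary", "Secondary", "University")
BP_DECL_LEVELS = ("No high BP", "BP without treat", "BP with treat")
DIAB_DECL_LEVELS = ("No Diab", "Diab without treat", "Diab with treat")
CHOL_DECL_LEVELS = ("No high Chol", "Chol without treat", "Chol with treat")
YESNO = ("No", "Yes")


@dataclass(frozen=True)
class LinearSubmodel:
    """y = intercept + sum(coef[term] * term) + residual.

    Terms are continuous column names, ``"col=Level"`` indicator terms, or
    ``"*"``-joined products of those (interactions); all on the raw scale so
    fitted regression coefficients are directly comparable to these
    generating values.
    """

    intercept: float
    coef: tuple[tuple[str, float], ...]
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("residual standard deviation must be >= 0")

    @staticmethod
    def _factor(df: pd.DataFrame, part: str) -> np.ndarray:
        if "=" in part:
            col, lev = part.split("=", 1)
            return (df[col].to_numpy() == lev).astype(float)
        return df[part].to_numpy(dtype=float)

    def linpred(self, df: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(df), self.intercept, dtype=float)
        for term, beta in self.coef:
            val = np.ones(len(df))
            for part in term.split("*"):
                val = val * self._factor(df, part)
            eta += beta * val
        return eta


@dataclass(frozen=True)
class PopulationParams:
    """Generating parameters for one synthetic population."""

    n: int = 11614
    p_male: float = 0.485
    age_range: tuple[float, float] = (18.0, 90.0)
    age_beta: tuple[float, float] = (1.05, 1.30)

    height: LinearSubmodel = LinearSubmodel(
        164.5,
        (("gender=Male", 15.4), ("age", -0.06), ("gender=Male*age", -0.05)),
        6.5,
    )
    weight: LinearSubmodel = LinearSubmodel(
        -58.0, (("height", 0.72), ("age", 0.09), ("gender=Male", 2.5)), 0.0
    )
    # gamma residual for weight (body weight is right-skewed);
    # sd = sqrt(shape)*scale = 9.0
    weight_resid_shape: float = 4.0
    weight_resid_scale: float = 4.5
    waist: LinearSubmodel = LinearSubmodel(
        42.0, (("weight", 0.55), ("gender=Male", 6.0), ("age", 0.12)), 7.0
    )
    bp_sys: LinearSubmodel = LinearSubmodel(
        74.0, (("age", 0.52), ("weight", 0.38), ("gender=Male", 3.0)), 11.0
    )
    bp_dia: LinearSubmodel = LinearSubmodel(
        18.0, (("bp_sys", 0.42), ("weight", 0.06)), 7.5
    )
    cholesterol: LinearSubmodel = LinearSubmodel(
        142.0, (("age", 0.75), ("weight", 0.20), ("gender=Male", -4.0)), 30.0
    )
    glucose: LinearSubmodel = LinearSubmodel(
        63.0, (("age", 0.30), ("weight", 0.22)), 0.0
    )
    # gamma residual for glucose (right skew); sd = sqrt(shape)*scale
    glucose_resid_shape: float = 2.0
    glucose_resid_scale: float = 10.0

    # latent "metabolic" factor: a standard-normal individual trait loading
    # on several clinical residuals, inducing the residual correlations real
    # risk factors show beyond their measured predictors
    latent_loadings: tuple[tuple[str, float], ...] = (
        ("waist", 4.0),
        ("bp_sys", 6.0),
        ("cholesterol", 18.0),
        ("glucose", 7.0),
    )

    # reporting error linking clinical to self-reported height/weight
    sr_height_bias: float = 0.7
    sr_height_sd: float = 1.6
    sr_weight_bias: float = -1.0
    sr_weight_sd: float = 2.0

    # terminal-digit preference, as in real clinical records: manual blood
    # pressure readings heap on multiples of 10 and 5, anthropometry and
    # self-reports heap on multiples of 5 / whole units
    measurement_rounding: bool = True

    # behavioural category probabilities
    p_smoking: tuple[float, ...] = (0.52, 0.20, 0.05, 0.23)
    p_activity: tuple[float, ...] = (0.35, 0.25, 0.25, 0.15)
    p_education: tuple[float, ...] = (0.35, 0.40, 0.25)
    p_drinker: float = 0.65  # share with non-zero weekly alcohol intake
    alcohol_log_mean: float = 4.0
    alcohol_log_sd: float = 0.95

    # declared-status discretisations (latent = clinical + noise)
    decl_bp_noise_sd: float = 9.0
    decl_bp_cut: float = 138.0
    decl_bp_p_treat: float = 0.6
    decl_chol_noise_sd: float = 25.0
    decl_chol_cut: float = 240.0
    decl_chol_p_treat: float = 0.55

    # diagnosis awareness: most people with a condition know about it, so
    # the declared statuses derive from the true condition with a
    # sensitivity below one and a small false-positive rate
    diab_diagnosed: float = 0.75
    diab_decl_p_treat: float = 0.8
    diab_decl_fp: float = 0.01
    cvd_declared_sens: float = 0.80
    cvd_declared_fp: float = 0.02

    # repeat-measurement variability separating the hyperglycemia flag
    # (fasting state on examination day) from the recorded glucose value
    hyper_repeat_sd: float = 8.0
    hyper_cut: float = 126.0

    # condition logistic models (raw scale; dummy terms relative to the
    # first level of each factor)
    cvd: LinearSubmodel = LinearSubmodel(
        -9.01,
        (
            ("age", 0.055),
            ("bmi", 0.06),
            ("bp_sys", 0.012),
            ("cholesterol", 0.004),
            ("gender=Male", 0.25),
            ("activity=Light", -0.25),
            ("activity=Moderate", -0.40),
            ("activity=Vigorous", -0.65),
            ("smoking=Ex-smoker", 0.15),
            ("smoking=Occasional smoker", 0.20),
            ("smoking=Regular smoker", 0.45),
            ("education=Secondary", -0.10),
            ("education=University", -0.25),
        ),
        0.0,
    )
    diabetes: LinearSubmodel = LinearSubmodel(
        -15.55,
        (
            ("glucose", 0.08),
            ("age", 0.05),
            ("bmi", 0.07),
            ("gender=Male", 0.25),
            ("activity=Light", -0.20),
            ("activity=Moderate", -0.30),
            ("activity=Vigorous", -0.50),
            ("education=Secondary", -0.10),
            ("education=University", -0.20),
        ),
        0.0,
    )

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("population size must be >= 0")
        for name in ("p_smoking", "p_activity", "p_education"):
            p = np.asarray(getattr(self, name))
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name}: probabilities must be >= 0 and sum to 1")
        for name in (
            "glucose_resid_scale",
            "sr_height_sd",
            "sr_weight_sd",
            "decl_bp_noise_sd",
            "decl_chol_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def without_cross_links(self) -> "PopulationParams":
        """Null variant: clinical block independent of everything observable.

        Every clinical submodel keeps its marginal location/spread but loses
        its predictors; self-reports become pure noise around the population
        means.  Under this null no imputation method can systematically beat
        the marginal predictor.
        """
        def cut(m: LinearSubmodel, mean_shift: float) -> LinearSubmodel:
            return LinearSubmodel(m.intercept + mean_shift, (), m.sd)

        return replace(
            self,
            latent_loadings=(),
            height=cut(self.height, 15.4 * 0.485 - 0.085 * 50),
            weight=cut(self.weight, 0.72 * 168 + 0.09 * 50),
            waist=cut(self.waist, 0.55 * 70 + 6 * 0.485 + 0.12 * 50),
            bp_sys=cut(self.bp_sys, 0.52 * 50 + 0.38 * 70),
            bp_dia=cut(self.bp_dia, 0.42 * 125 + 0.06 * 70),
            cholesterol=cut(self.cholesterol, 0.75 * 50 + 0.20 * 70),
            glucose=cut(self.glucose, 0.30 * 50 + 0.22 * 70),
            sr_height_sd=8.0,
            sr_height_bias=0.0,
            sr_weight_sd=12.0,
            sr_weight_bias=0.0,
            decl_bp_noise_sd=1e6,
            decl_chol_noise_sd=1e6,
            diab_diagnosed=0.01,
            cvd_declared_sens=0.02,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters plus true condition prevalences."""

    params: PopulationParams
    prevalence: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {cond!r} outside [0, 1]")


def band_age(age: np.ndarray) -> np.ndarray:
    idx = np.digitize(age, AGE_EDGES[1:-1])
    return np.asarray(AGE_GROUPS, dtype=object)[idx]


def classify_alcohol_grams(grams: np.ndarray, male: np.ndarray) -> np.ndarray:
    """Weekly pure-alcohol grams -> {non, moderate, risk} drinker.

    Moderate means strictly below 280 g/week for men and 170 g/week for
    women; intake at or above the bound is risk drinking.
    """
    grams = np.asarray(grams, dtype=float)
    if (grams < 0).any():
        raise ValueError("negative alcohol intake")
    bound = np.where(male, 280.0, 170.0)
    out = np.where(grams == 0, ALCOHOL_LEVELS[0],
                   np.where(grams < bound, ALCOHOL_LEVELS[1], ALCOHOL_LEVELS[2]))
    return out.astype(object)


def _three_level_declaration(
    rng: np.random.Generator,
    clinical: np.ndarray,
    noise_sd: float,
    cut: float,
    p_treat: float,
    levels: tuple[str, str, str],
) -> np.ndarray:
    latent = clinical + rng.normal(0.0, noise_sd, size=clinical.shape)
    high = latent > cut
    treat = rng.random(clinical.shape) < p_treat
    out = np.full(clinical.shape, levels[0], dtype=object)
    out[high & ~treat] = levels[1]
    out[high & treat] = levels[2]
    return out


def _draw_frame(params: PopulationParams, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Sample n individuals from the generating chain (complete data)."""
    p = params
    male = rng.random(n) < p.p_male
    lo, hi = p.age_range
    age = lo + (hi - lo) * rng.beta(*p.age_beta, size=n)

    df = pd.DataFrame(index=pd.RangeIndex(n))
    df["gender"] = np.where(male, "Male", "Female").astype(object)
    df["age"] = age
    df["age_group"] = band_age(age)

    df["height"] = p.height.linpred(df) + rng.normal(0, p.height.sd, n)
    w_resid = (
        rng.gamma(p.weight_resid_shape, p.weight_resid_scale, n)
        - p.weight_resid_shape * p.weight_resid_scale
    ) + rng.normal(0, p.weight.sd, n)
    df["weight"] = p.weight.linpred(df) + w_resid
    df["bmi"] = df["weight"] / (df["height"] / 100.0) ** 2
    latent = rng.normal(0.0, 1.0, n)
    load = dict(p.latent_loadings)
    df["waist"] = (
        p.waist.linpred(df) + load.get("waist", 0.0) * latent
        + rng.normal(0, p.waist.sd, n)
    )
    df["bp_sys"] = (
        p.bp_sys.linpred(df) + load.get("bp_sys", 0.0) * latent
        + rng.normal(0, p.bp_sys.sd, n)
    )
    df["bp_dia"] = p.bp_dia.linpred(df) + rng.normal(0, p.bp_dia.sd, n)
    df["cholesterol"] = (
        p.cholesterol.linpred(df) + load.get("cholesterol", 0.0) * latent
        + rng.normal(0, p.cholesterol.sd, n)
    )
    g_resid = (
        rng.gamma(p.glucose_resid_shape, p.glucose_resid_scale, n)
        - p.glucose_resid_shape * p.glucose_resid_scale
    )
    df["glucose"] = p.glucose.linpred(df) + load.get("glucose", 0.0) * latent + g_resid

    df["sr_height"] = df["height"] + rng.normal(p.sr_height_bias, p.sr_height_sd, n)
    df["sr_weight"] = df["weight"] + rng.normal(p.sr_weight_bias, p.sr_weight_sd, n)

    if p.measurement_rounding:
        def heap(x, p_coarse, coarse, base):
            coarse_mask = rng.random(n) < p_coarse
            return np.where(
                coarse_mask,
                np.round(x / coarse) * coarse,
                np.round(x / base) * base,
            )

        # manual sphygmomanometry: strong terminal-digit-0/5 preference
        for col in ("bp_sys", "bp_dia"):
            u = rng.random(n)
            x = df[col].to_numpy()
            df[col] = np.where(
                u < 0.45, np.round(x / 10) * 10,
                np.where(u < 0.70, np.round(x / 5) * 5, np.round(x / 2) * 2),
            )
        df["height"] = np.round(df["height"])
        df["weight"] = np.round(df["weight"] * 2) / 2
        df["waist"] = heap(df["waist"].to_numpy(), 0.30, 5.0, 1.0)
        df["cholesterol"] = np.round(df["cholesterol"])
        df["glucose"] = np.round(df["glucose"])
        df["sr_height"] = heap(df["sr_height"].to_numpy(), 0.35, 5.0, 1.0)
        df["sr_weight"] = heap(df["sr_weight"].to_numpy(), 0.30, 5.0, 1.0)
        df["bmi"] = df["weight"] / (df["height"] / 100.0) ** 2

    df["smoking"] = rng.choice(np.asarray(SMOKING_LEVELS, object), n, p=p.p_smoking)
    df["activity"] = rng.choice(np.asarray(ACTIVITY_LEVELS, object), n, p=p.p_activity)
    df["education"] = rng.choice(np.asarray(EDUCATION_LEVELS, object), n, p=p.p_education)
    grams = np.where(
        rng.random(n) < p.p_drinker,
        rng.lognormal(p.alcohol_log_mean, p.alcohol_log_sd, n),
        0.0,
    )
    df["alcohol"] = classify_alcohol_grams(grams, male)

    hyper_latent = df["glucose"].to_numpy() + rng.normal(0.0, p.hyper_repeat_sd, n)
    df["declared_bp"] = _three_level_declaration(
        rng, df["bp_sys"].to_numpy(), p.decl_bp_noise_sd, p.decl_bp_cut,
        p.decl_bp_p_treat, BP_DECL_LEVELS)
    df["declared_chol"] = _three_level_declaration(
        rng, df["cholesterol"].to_numpy(), p.decl_chol_noise_sd, p.decl_chol_cut,
        p.decl_chol_p_treat, CHOL_DECL_LEVELS)

    df["hyperglycemia"] = np.where(
        hyper_latent >= p.hyper_cut, "Yes", "No"
    ).astype(object)

    for cond in ("cvd", "diabetes"):
        model: LinearSubmodel = getattr(p, cond)
        with np.errstate(over="ignore"):
            prob = 1.0 / (1.0 + np.exp(-model.linpred(df)))
        df[cond] = np.where(rng.random(n) < prob, "Yes", "No").astype(object)

    # self-reported conditions: diagnosed cases declare their status
    diab = df["diabetes"].to_numpy() == "Yes"
    known = rng.random(n) < np.where(diab, p.diab_diagnosed, p.diab_decl_fp)
    treat = rng.random(n) < p.diab_decl_p_treat
    decl = np.full(n, DIAB_DECL_LEVELS[0], dtype=object)
    decl[known & ~treat] = DIAB_DECL_LEVELS[1]
    decl[known & treat] = DIAB_DECL_LEVELS[2]
    df["declared_diab"] = decl
    cvd = df["cvd"].to_numpy() == "Yes"
    said = rng.random(n) < np.where(cvd, p.cvd_declared_sens, p.cvd_declared_fp)
    df["declared_cvd"] = np.where(said, "Yes", "No").astype(object)
    return df


def default_schema() -> list[VariableSchema]:
    def cat(name, levels, role=ROLE_COMMON, ordered=False, units=""):
        return VariableSchema(name, role, KIND_CATEGORICAL, tuple(levels),
                              ordered=ordered, units=units)

    def cont(name, role=ROLE_COMMON, units=""):
        return VariableSchema(name, role, KIND_CONTINUOUS, units=units)

    return [
        cat("gender", ("Female", "Male")),
        cont("age", units="years"),
        cat("age_group", AGE_GROUPS, ordered=True),
        cont("sr_height", units="cm"),
        cont("sr_weight", units="kg"),
        cat("smoking", SMOKING_LEVELS, ordered=True),
        cat("activity", ACTIVITY_LEVELS, ordered=True),
        cat("alcohol", ALCOHOL_LEVELS, ordered=True),
        cat("education", EDUCATION_LEVELS, ordered=True),
        cat("declared_bp", BP_DECL_LEVELS, ordered=True),
        cat("declared_diab", DIAB_DECL_LEVELS, ordered=True),
        cat("declared_chol", CHOL_DECL_LEVELS, ordered=True),
        cat("declared_cvd", YESNO),
        cont("height", ROLE_SPECIFIC, units="cm"),
        cont("weight", ROLE_SPECIFIC, units="kg"),
        cont("bmi", ROLE_SPECIFIC, units="kg/m2"),
        cont("waist", ROLE_SPECIFIC, units="cm"),
        cont("bp_sys", ROLE_SPECIFIC, units="mmHg"),
        cont("bp_dia", ROLE_SPECIFIC, units="mmHg"),
        cont("cholesterol", ROLE_SPECIFIC, units="mg/dL"),
        cont("glucose", ROLE_SPECIFIC, units="mg/dL"),
        cat("hyperglycemia", YESNO, ROLE_SPECIFIC),
        cat("cvd", YESNO, ROLE_SPECIFIC),
        cat("diabetes", YESNO, ROLE_SPECIFIC),
    ]


def default_fusion_spec() -> FusionSpec:
    schema = default_schema()
    return FusionSpec(
        tuple(v.name for v in schema if v.role == ROLE_COMMON),
        tuple(v.name for v in schema if v.role == ROLE_SPECIFIC),
    )


def clinical_fusion_spec() -> FusionSpec:
    """X/Y partition with the clinical block only as specifics.

    This is the fusion problem proper: transfer the measured risk factors.
    The condition flags are application-layer outcomes, imputed afterwards
    by the terminal logistic submodels of the clinical chain."""
    schema = default_schema()
    continuous_clinical = (
        "height", "weight", "bmi", "waist", "bp_sys", "bp_dia",
        "cholesterol", "glucose", "hyperglycemia",
    )
    return FusionSpec(
        tuple(v.name for v in schema if v.role == ROLE_COMMON),
        continuous_clinical,
    )


def generate_population(
    params: PopulationParams, seed: int = 0
) -> tuple[SurveyTable, GroundTruth]:
    """Draw a fully observed population (clinical and self-reported blocks).

    Deterministic given ``seed``.  The returned :class:`GroundTruth` carries
    the generating parameters; true prevalences are computed separately by
    :func:`true_prevalence` (Monte-Carlo) so that repeated population draws
    stay cheap.
    """
    rng = np.random.default_rng(seed)
    df = _draw_frame(params, params.n, rng)
    table = SurveyTable(df, default_schema(), check=params.n > 0)
    return table, GroundTruth(params=params)


def true_prevalence(
    params: PopulationParams,
    conditions: tuple[str, ...] = ("cvd", "diabetes"),
    n_mc: int = 200_000,
    seed: int = 12345,
) -> dict[str, float]:
    """Monte-Carlo population prevalence of each condition under ``params``."""
    rng = np.random.default_rng(seed)
    df = _draw_frame(params, n_mc, rng)
    return {c: float((df[c] == "Yes").mean()) for c in conditions}


def make_fusion_scenario(
    population: SurveyTable,
    donor_fraction: float = 1508 / 11614,
    seed: int = 0,
) -> tuple[SurveyTable, SurveyTable, SurveyTable]:
    """Split a complete population into (donor, recipient, hidden_truth).

    Donors are sampled without replacement; the recipient table has the
    clinical (specific) block removed while ``hidden_truth`` keeps the full
    recipient rows for evaluation.  Mirrors a design where a small
    examination subsample sits inside a large interview survey.
    """
    if not 0.0 < donor_fraction < 1.0:
        raise ValueError("donor_fraction must be in (0, 1)")
    n = population.n
    n0 = int(round(donor_fraction * n))
    if n0 < 2:
        raise ValueError("donor fraction yields fewer than 2 donors")
    if n0 >= n:
        raise ValueError("donor fraction leaves an empty recipient file")
    rng = np.random.default_rng(seed)
    donor_idx = np.sort(rng.choice(n, size=n0, replace=False))
    mask = np.zeros(n, dtype=bool)
    mask[donor_idx] = True
    donor = population.take(population.df.index[mask])
    hidden = population.take(population.df.index[~mask])
    rec_df = hidden.df.copy()
    rec_df[population.specific_names] = np.nan
    recipient = SurveyTable(rec_df, population.schema, check=False)
    return donor, recipient, hidden
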