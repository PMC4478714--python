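"""Canned replication experiments on synthetic data.

These functions freeze the study conditions used throughout the package's
tests and reproduction script:

* a *method-profile* experiment — bootstrap comparison of the six
  imputation methods on a scaled donor/recipient scenario;
* a *prevalence* experiment — the full-size design (11614 respondents,
  1508 examined) with 20-fold multiply imputed sequential regression and
  donor-vs-fused SD ratios;
* a *coverage* experiment — repeated scaled replications checking that
  pooled 95% intervals cover the known population prevalence;
* a *parameter-recovery* experiment — refitting the generating chain on a
  synthetic donor file and comparing coefficients with their true values.

Every experiment is deterministic given its seed, with all internal seeds
derived through :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compare import ALL_METHODS, ComparisonResult, run_comparison
from .health import _bmi_from_cm, build_clinical_scheme, estimate_prevalence
from .imputers import SequentialRegression, SubmodelSpec
from .mi import multiply_impute, pool_proportion
from .schema import FusionSpec, SurveyTable
from .synthetic import (
    PopulationParams,
    clinical_fusion_spec,
    default_fusion_spec,
    generate_population,
    make_fusion_scenario,
    true_prevalence,
)

DONOR_FRACTION = 1508 / 11614  # examined subsample share of the design


def _sub_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def comparison_scenario(
    seed: int = 0, n: int = 4600
) -> tuple[SurveyTable, SurveyTable, FusionSpec, dict]:
    """Scaled donor/recipient scenario for the method comparison.

    The specific block is the clinical measurements (conditions are imputed
    by the application pipeline, not compared here); the donor share
    matches the full design's examined fraction, giving roughly 600 donors
    at the default scale.
    """
    params = PopulationParams(n=n)
    population, _ = generate_population(params, seed=_sub_seed(seed, 0))
    donor, recipient, _ = make_fusion_scenario(
        population, DONOR_FRACTION, seed=_sub_seed(seed, 1)
    )
    spec = clinical_fusion_spec()
    scheme = [
        s for s in build_clinical_scheme(default_fusion_spec())
        if s.name in spec.specific_names
    ]
    settings = {"sqreg": {"scheme": scheme, "min_rows_per_param": 5}}
    return donor, recipient, spec, settings


def method_profile(
    seed: int = 0,
    n_boot: int = 50,
    m: int = 5,
    methods: tuple[str, ...] = ALL_METHODS,
    n: int = 4600,
) -> ComparisonResult:
    """One full bootstrap comparison run on the scaled scenario."""
    donor, recipient, spec, settings = comparison_scenario(seed, n=n)
    return run_comparison(
        donor, recipient, spec, methods, n_boot=n_boot, m=m,
        seed=_sub_seed(seed, 2), settings=settings,
    )


def family_means(result: ComparisonResult) -> pd.DataFrame:
    """Mean of each statistic per engine family (single and MI averaged)."""
    mm = result.summary().pivot(index="method", columns="statistic", values="mean")
    fams = {"knn": ("1nn", "mi-knn"), "sqreg": ("sqreg", "mi-sqreg"),
            "da": ("da", "mi-da")}
    return pd.DataFrame(
        {k: (mm.loc[a] + mm.loc[b]) / 2 for k, (a, b) in fams.items()
         if a in mm.index and b in mm.index}
    ).T


def prevalence_experiment(
    seed: int = 0,
    n: int = 11614,
    donor_fraction: float = DONOR_FRACTION,
    m: int = 20,
    subgroups: tuple[str, ...] = ("gender", "age_group", "activity"),
) -> dict[str, pd.DataFrame]:
    """Full-design prevalence estimation with MI sequential regression.

    Returns one table per condition with donor-only and fused (donor +
    multiply imputed recipients) prevalences, their SDs and the SD ratio.
    """
    params = PopulationParams(n=n)
    population, _ = generate_population(params, seed=_sub_seed(seed, 10))
    donor, recipient, _ = make_fusion_scenario(
        population, donor_fraction, seed=_sub_seed(seed, 11)
    )
    spec = default_fusion_spec()
    scheme = build_clinical_scheme(spec)
    multi = multiply_impute(
        "sqreg", donor, recipient, spec, m=m, seed=_sub_seed(seed, 12),
        scheme=scheme, min_rows_per_param=5,
    )
    return {
        cond: estimate_prevalence(donor, multi, cond, subgroups).frame
        for cond in ("cvd", "diabetes")
    }


def _coverage_spec_scheme() -> tuple[FusionSpec, list[SubmodelSpec]]:
    common = default_fusion_spec().common_names
    spec = FusionSpec(
        common, ("height", "weight", "bmi", "waist", "bp_sys", "cholesterol", "cvd")
    )
    scheme = [
        SubmodelSpec("height", ("sr_height", "sr_weight", "gender", "age")),
        SubmodelSpec("weight", ("height", "sr_weight", "gender", "age")),
        SubmodelSpec("bmi", derive=_bmi_from_cm),
        SubmodelSpec("waist", ("weight", "gender", "age")),
        SubmodelSpec("bp_sys", ("age", "weight", "gender", "declared_bp")),
        SubmodelSpec("cholesterol", ("age", "weight", "gender", "declared_chol")),
        SubmodelSpec("cvd", ("declared_cvd", "gender", "age", "bmi", "bp_sys",
                             "cholesterol")),
    ]
    return spec, scheme


def coverage_experiment(
    seed: int = 0,
    n_replications: int = 200,
    n: int = 2000,
    donor_fraction: float = 0.2,
    m: int = 10,
    level: float = 0.95,
) -> dict:
    """Interval coverage of the pooled fused prevalence on scaled data.

    Each replication draws a fresh population, splits it, multiply imputes
    the recipients with the (correctly specified) clinical chain and checks
    whether the pooled interval covers the true population prevalence of
    cardiovascular disease.  Returns the empirical coverage rate.
    """
    params = PopulationParams(n=n)
    truth = true_prevalence(params, ("cvd",), n_mc=200_000,
                            seed=_sub_seed(seed, 20))["cvd"]
    spec, scheme = _coverage_spec_scheme()
    hits = 0
    failed = 0
    for child in np.random.SeedSequence([seed, 21]).spawn(n_replications):
        s = int(child.generate_state(1)[0] % (2**31))
        population, _ = generate_population(params, seed=s)
        donor, recipient, _ = make_fusion_scenario(population, donor_fraction, seed=s)
        try:
            multi = multiply_impute(
                "sqreg", donor, recipient, spec, m=m, seed=s,
                scheme=scheme, selection=False, min_rows_per_param=2,
            )
        except Exception:
            failed += 1
            continue
        pooled = pool_proportion(multi, "cvd", extra=donor.df["cvd"])
        lo, hi = pooled.ci(level)
        hits += int(lo <= truth <= hi)
    valid = n_replications - failed
    return {
        "coverage": hits / valid if valid else float("nan"),
        "hits": hits,
        "valid": valid,
        "failed": failed,
        "truth": truth,
    }


def recovery_scheme() -> list[SubmodelSpec]:
    """Chain whose submodels match the generating models term for term."""
    return [
        SubmodelSpec("height", ("gender", "age", "gender:age")),
        SubmodelSpec("weight", ("height", "age", "gender")),
        SubmodelSpec("bmi", derive=_bmi_from_cm),
        SubmodelSpec("waist", ("weight", "gender", "age")),
        SubmodelSpec("bp_sys", ("age", "weight", "gender")),
        SubmodelSpec("bp_dia", ("bp_sys", "weight")),
        SubmodelSpec("cholesterol", ("age", "weight", "gender")),
        SubmodelSpec("glucose", ("age", "weight")),
        SubmodelSpec("hyperglycemia", ("glucose",)),
        SubmodelSpec(
            "cvd",
            ("age", "bmi", "bp_sys", "cholesterol", "gender", "activity",
             "smoking", "education"),
        ),
        SubmodelSpec(
            "diabetes",
            ("glucose", "age", "bmi", "gender", "activity", "education"),
        ),
    ]


# generating coefficients keyed by (submodel, design column name); the
# hyperglycemia link is a probit-style threshold, not a logistic
# coefficient, so it is not part of the recovery comparison
def generating_coefficients(params: PopulationParams) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for name in ("height", "weight", "waist", "bp_sys", "bp_dia",
                 "cholesterol", "glucose", "cvd", "diabetes"):
        model = getattr(params, name)
        out[(name, "const")] = model.intercept
        for term, beta in model.coef:
            out[(name, term.replace("*", ":"))] = beta
    return out


def recovery_experiment(seed: int = 0, n0: int = 2000) -> pd.DataFrame:
    """Fit the generating chain on a complete synthetic donor file.

    Returns one row per generating coefficient with the fitted estimate,
    its standard error and the standardised deviation |fit - true| / SE.
    Measurement digit preference is switched off so the fitted chain is
    exactly the generating model (heaping is an errors-in-variables
    corruption that would attenuate the blood-pressure coefficients).
    """
    params = PopulationParams(n=n0, measurement_rounding=False)
    donor, _ = generate_population(params, seed=_sub_seed(seed, 30))
    spec = default_fusion_spec()
    model = SequentialRegression(
        donor, spec, scheme=recovery_scheme(), selection=False,
        min_rows_per_param=2,
    )
    res = model.fit()
    truth = generating_coefficients(params)
    rows = []
    for (sub_name, col), true_val in truth.items():
        fitted = res.submodels_[sub_name]
        coef, bse = fitted.coef, fitted.bse
        if col not in coef.index:
            continue
        est, se = float(coef[col]), float(bse[col])
        rows.append(
            {"submodel": sub_name, "term": col, "true": true_val,
             "estimate": est, "se": se, "z": abs(est - true_val) / se}
        )
    return pd.DataFrame(rows)
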