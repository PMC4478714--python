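"""Validation statistics for fused data.

A fusion is valid when the completed file looks like an instance of the
joint distribution of common and specific variables.  Since that
distribution is unknown, quality is judged by re-imputing the *donors*
(whose specific block is observed) and comparing observed with imputed
values through eight statistics, grouped by what they probe:

====== ============================================================ ===========
stat   probes                                                       orientation
====== ============================================================ ===========
ASLm   equality of marginal means / level proportions               higher
ASLs   equality of marginal standard deviations                     higher
ACDi   associations among specific variables                        lower
ACDe   associations between specific and common variables           lower
WC     congruence of the multivariate scatter pattern               higher
ASD    closeness of marginal distributions (ECDF / total variation) lower
TAU    accuracy: error reduction / chance-corrected agreement       higher
RndRes randomness of imputation residuals w.r.t. the commons        higher
====== ============================================================ ===========

ASLm, ASLs and RndRes average achieved significance levels (p-values) of
univariate two-sample or no-association tests — averaging, not combining,
because the suite describes facets of quality rather than testing a global
hypothesis.  The exact operationalisation of each statistic is a documented
choice (see the per-function docstrings); each function is independent, so
alternative versions can be swapped in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .design import indicator_matrix
from .schema import FusionSpec, SurveyTable, check_schema_set

STAT_ORIENTATION = {
    "ASLm": "higher",
    "ASLs": "higher",
    "ACDi": "lower",
    "ACDe": "lower",
    "WC": "higher",
    "ASD": "lower",
    "TAU": "higher",
    "RndRes": "higher",
}
STAT_ORDER = tuple(STAT_ORIENTATION)


@dataclass
class ValidationReport:
    """The eight statistics plus per-variable (or per-pair) detail."""

    statistics: dict[str, float]
    detail: dict[str, dict] = field(default_factory=dict)
    degenerate: list[str] = field(default_factory=list)
    orientation: dict[str, str] = field(default_factory=lambda: dict(STAT_ORIENTATION))

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.statistics.get(k, np.nan) for k in STAT_ORDER})

    def to_json(self) -> str:
        return json.dumps(
            {
                "statistics": self.statistics,
                "detail": self.detail,
                "degenerate": self.degenerate,
                "orientation": self.orientation,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        obj = json.loads(text)
        return cls(
            statistics=obj["statistics"],
            detail=obj["detail"],
            degenerate=obj["degenerate"],
            orientation=obj["orientation"],
        )


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sample test of equal means (closed form)."""
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(2.0 * stats.t.sf(abs(t), df))


def _two_sample_mean_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample test of equal means; identical samples give p=1."""
    if np.array_equal(a, b):
        return 1.0
    return _welch_p(a, b)


def _two_sample_sd_p(a: np.ndarray, b: np.ndarray) -> float:
    """Levene-type test of equal spread (Welch on absolute deviations from
    the group mean); identical samples give p=1."""
    if np.array_equal(a, b):
        return 1.0
    if a.std() == 0 and b.std() == 0:
        return 1.0
    return _welch_p(np.abs(a - a.mean()), np.abs(b - b.mean()))


def _proportions_p(a: pd.Series, b: pd.Series, levels: tuple[str, ...]) -> float:
    """Chi-square homogeneity test of the two level-frequency vectors."""
    ca = np.array([(a == lev).sum() for lev in levels], dtype=float)
    cb = np.array([(b == lev).sum() for lev in levels], dtype=float)
    keep = (ca + cb) > 0
    table = np.vstack([ca[keep], cb[keep]])
    if table.shape[1] < 2 or np.allclose(ca, cb):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.chi2_contingency(table, correction=False)[1])


def marginal_asl(
    observed: SurveyTable, imputed: SurveyTable, spec: FusionSpec
) -> tuple[float, float, dict]:
    """A: preservation of marginal statistics.

    ASLm averages, over specific variables, the p-value of a two-sample test
    of equal means (Welch) or equal level proportions (chi-square); ASLs does
    the same for equal standard deviations (Levene).  Values near 1 mean the
    imputed marginals are indistinguishable from the observed ones.
    """
    detail: dict[str, dict] = {}
    pm, ps = [], []
    for name in spec.specific_names:
        var = observed.variable(name)
        if var.is_categorical:
            p = _proportions_p(observed.df[name], imputed.df[name], var.levels)
            pm.append(p)
            detail[name] = {"p_mean": p}
        else:
            a = observed.df[name].to_numpy(dtype=float)
            b = imputed.df[name].to_numpy(dtype=float)
            if a.std() == 0 and b.std() == 0 and a[0] == b[0]:
                warnings.warn(f"variable {name!r} constant in both blocks; skipped")
                detail[name] = {"skipped": True}
                continue
            p1, p2 = _two_sample_mean_p(a, b), _two_sample_sd_p(a, b)
            pm.append(p1)
            ps.append(p2)
            detail[name] = {"p_mean": p1, "p_sd": p2}
    aslm = float(np.mean(pm)) if pm else np.nan
    asls = float(np.mean(ps)) if ps else np.nan
    return aslm, asls, detail


def _association(
    x: pd.Series, y: pd.Series, vx, vy
) -> float:
    """Mixed-type association in [-1, 1] (magnitude comparable across pairs).

    Product-moment for continuous pairs; Spearman on level codes when either
    member is ordered-categorical; Cramer's V for nominal pairs; correlation
    ratio (eta) for a nominal/continuous pair.
    """
    cx, cy = vx is None or not vx.is_categorical, vy is None or not vy.is_categorical
    if cx and cy:
        return float(stats.pearsonr(x.astype(float), y.astype(float))[0])
    ox = (not cx) and vx.ordered
    oy = (not cy) and vy.ordered
    if (ox or cx) and (oy or cy):
        xv = x.astype(float) if cx else pd.Categorical(x, vx.levels).codes.astype(float)
        yv = y.astype(float) if cy else pd.Categorical(y, vy.levels).codes.astype(float)
        return float(stats.spearmanr(xv, yv)[0])
    if not cx and not cy:
        table = pd.crosstab(x, y).to_numpy(dtype=float)
        table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        if min(table.shape) < 2:
            return 0.0
        chi2 = stats.chi2_contingency(table, correction=False)[0]
        n = table.sum()
        return float(np.sqrt(chi2 / (n * (min(table.shape) - 1))))
    # nominal x continuous: correlation ratio
    cat, num = (x, y.astype(float)) if not cx else (y, x.astype(float))
    groups = [g.to_numpy() for _, g in num.groupby(cat.to_numpy()) if len(g) > 0]
    grand = num.to_numpy()
    ss_tot = ((grand - grand.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    ss_between = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    return float(np.sqrt(ss_between / ss_tot))


def _assoc_matrices(table: SurveyTable, names: list[str], by_name):
    """Pairwise association matrices for a variable list.

    Returns (kinds, pearson matrix, spearman matrix); the right entry per
    pair is selected afterwards: product-moment for continuous pairs,
    rank-based when either member is ordered (or binary) categorical.
    Pairs involving a multi-level nominal variable use the slow per-pair
    path in :func:`correlation_discrepancy`.
    """
    cols, kinds = [], []
    for name in names:
        var = by_name[name]
        col = table.df[name]
        if var.is_categorical:
            cols.append(pd.Categorical(col, var.levels).codes.astype(float))
            kinds.append(
                "ordinal" if (var.ordered or len(var.levels) == 2) else "nominal"
            )
        else:
            cols.append(col.to_numpy(dtype=float))
            kinds.append("numeric")
    M = np.column_stack(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        P = np.corrcoef(M, rowvar=False)
        S = np.corrcoef(stats.rankdata(M, axis=0), rowvar=False)
    return kinds, P, S


def correlation_discrepancy(
    observed: SurveyTable, imputed: SurveyTable, spec: FusionSpec
) -> tuple[float, float, dict]:
    """B2/B3: mean absolute difference of pairwise associations.

    ACDi compares observed vs imputed associations over specific-variable
    pairs; ACDe over (specific x common) pairs.  Lower is better.
    """
    by_name = check_schema_set(observed.schema)
    detail: dict[str, dict] = {"internal": {}, "external": {}}
    names = list(spec.specific_names) + list(spec.common_names)
    kinds, P_obs, S_obs = _assoc_matrices(observed, names, by_name)
    _, P_imp, S_imp = _assoc_matrices(imputed, names, by_name)
    pos = {name: i for i, name in enumerate(names)}

    def diff(n1: str, n2: str, bucket: str) -> float | None:
        i, j = pos[n1], pos[n2]
        if "nominal" in (kinds[i], kinds[j]):
            v1, v2 = by_name.get(n1), by_name.get(n2)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    a = _association(observed.df[n1], observed.df[n2], v1, v2)
                    b = _association(imputed.df[n1], imputed.df[n2], v1, v2)
            except Exception:
                return None
        elif kinds[i] == "numeric" and kinds[j] == "numeric":
            a, b = P_obs[i, j], P_imp[i, j]
        else:
            a, b = S_obs[i, j], S_imp[i, j]
        if np.isnan(a) or np.isnan(b):
            return None
        detail[bucket][f"{n1}~{n2}"] = {"observed": float(a), "imputed": float(b)}
        return abs(a - b)

    internal = [
        d
        for i, n1 in enumerate(spec.specific_names)
        for n2 in spec.specific_names[i + 1:]
        if (d := diff(n1, n2, "internal")) is not None
    ]
    external = [
        d
        for n1 in spec.specific_names
        for n2 in spec.common_names
        if (d := diff(n1, n2, "external")) is not None
    ]
    acdi = float(np.mean(internal)) if internal else np.nan
    acde = float(np.mean(external)) if external else np.nan
    return acdi, acde, detail


def multivariate_congruence(
    observed: SurveyTable, imputed: SurveyTable, spec: FusionSpec
) -> float:
    """B4 (WC): congruence of the multivariate scatter of the fused data.

    The observed file (X, Y) and the fused file (X, Y-imputed) are
    numerically encoded (indicator columns for categoricals), centred, and
    their cross-product matrices compared by the matrix congruence
    <S1, S2> / (||S1|| ||S2||), which is 1 iff the scatters are
    proportional.  Including the common block means WC rewards preserving
    the specific-by-common covariances as well as the internal structure of
    the imputed block — the full multivariate pattern of variability of the
    fused file.  Computed on the raw scale, so variables weigh in
    proportion to their share of the total scatter.
    """
    schema_map = check_schema_set(observed.schema)
    names = list(spec.common_names) + list(spec.specific_names)
    Z1, _ = indicator_matrix(observed.df, names, schema_map)
    Z2, _ = indicator_matrix(imputed.df, names, schema_map)
    Z1 = Z1 - Z1.mean(axis=0)
    Z2 = Z2 - Z2.mean(axis=0)
    S1 = Z1.T @ Z1
    S2 = Z2.T @ Z2
    n1, n2 = np.linalg.norm(S1), np.linalg.norm(S2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate (rank-0) specific block")
    return float(np.sum(S1 * S2) / (n1 * n2))


def distribution_similarity(
    observed: SurveyTable, imputed: SurveyTable, spec: FusionSpec
) -> tuple[float, dict]:
    """C5 (ASD): average marginal distribution distance.

    Two-sample empirical-CDF sup-distance (Kolmogorov-Smirnov statistic) for
    continuous variables, total-variation distance between level frequencies
    for categoricals.  0 means identical marginals.
    """
    detail: dict[str, float] = {}
    vals = []
    for name in spec.specific_names:
        var = observed.variable(name)
        if var.is_categorical:
            p = observed.df[name].value_counts(normalize=True)
            q = imputed.df[name].value_counts(normalize=True)
            levels = list(var.levels)
            d = 0.5 * sum(abs(p.get(l, 0.0) - q.get(l, 0.0)) for l in levels)
        else:
            a = observed.df[name].to_numpy(dtype=float)
            b = imputed.df[name].to_numpy(dtype=float)
            d = 0.0 if np.array_equal(a, b) else float(stats.ks_2samp(a, b).statistic)
        detail[name] = float(d)
        vals.append(d)
    return float(np.mean(vals)), detail


def imputation_accuracy(
    observed: SurveyTable,
    imputed: SurveyTable,
    spec: FusionSpec,
    floor: float = 0.0,
) -> tuple[float, dict]:
    """D6 (TAU): accuracy of imputation, higher = closer to the truth.

    Chance-corrected agreement (Cohen's kappa) for categorical variables;
    standardised error reduction 1 - MSE/Var(observed) for continuous ones,
    floored at ``floor`` so a handful of hopeless variables cannot dominate
    the average.  Perfect imputation gives 1, uninformative imputation ~0.
    """
    detail: dict[str, float] = {}
    vals = []
    for name in spec.specific_names:
        var = observed.variable(name)
        a, b = observed.df[name], imputed.df[name]
        if var.is_categorical:
            if a.nunique() == 1 and (a == b).all():
                t = 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    t = float(cohen_kappa_score(a, b, labels=list(var.levels)))
                if np.isnan(t):
                    t = 0.0
        else:
            av = a.to_numpy(dtype=float)
            bv = b.to_numpy(dtype=float)
            v = av.var()
            if v == 0:
                warnings.warn(f"variable {name!r}: zero observed variance; skipped")
                detail[name] = np.nan
                continue
            t = max(1.0 - float(np.mean((av - bv) ** 2)) / v, floor)
        detail[name] = t
        vals.append(t)
    return (float(np.mean(vals)) if vals else np.nan), detail


def residual_randomness(
    observed: SurveyTable, imputed: SurveyTable, spec: FusionSpec
) -> tuple[float, dict, bool]:
    """D7 (RndRes): do imputation residuals carry structure in X?

    For each continuous specific variable the residual observed - imputed is
    tested for association against every common variable (correlation test
    for continuous commons, one-way ANOVA across levels for categorical
    commons); RndRes is the mean achieved significance level.  Constant
    residuals (perfect imputation) are degenerate and reported as 1.
    """
    cont_names = [
        n for n in spec.specific_names if not observed.variable(n).is_categorical
    ]
    if not cont_names:
        return 1.0, {}, True
    R = (
        observed.df[cont_names].to_numpy(dtype=float)
        - imputed.df[cont_names].to_numpy(dtype=float)
    )
    live = R.std(axis=0) > 0
    detail: dict[str, dict[str, float]] = {n: {} for n in cont_names}
    if not live.any():
        return 1.0, detail, True
    R = R[:, live]
    names = [n for n, keep in zip(cont_names, live) if keep]
    n = len(R)
    Rc = R - R.mean(axis=0)
    ss_tot = (Rc**2).sum(axis=0)
    pvals: list[float] = []
    for cname in spec.common_names:
        cvar = observed.variable(cname)
        if cvar.is_categorical:
            # one-way ANOVA of each residual column across the levels
            masks = [
                (observed.df[cname] == lev).to_numpy() for lev in cvar.levels
            ]
            masks = [mk for mk in masks if mk.sum() >= 2]
            k = len(masks)
            if k < 2:
                continue
            counts = np.array([mk.sum() for mk in masks], dtype=float)
            gsum = np.vstack([R[mk].sum(axis=0) for mk in masks])
            gmean = gsum / counts[:, None]
            ss_between = (counts[:, None] * (gmean - R.mean(axis=0)) ** 2).sum(axis=0)
            ss_within = np.maximum(ss_tot - ss_between, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                F = (ss_between / (k - 1)) / (ss_within / (n - k))
                ps = stats.f.sf(F, k - 1, n - k)
        else:
            c = observed.df[cname].to_numpy(dtype=float)
            cc = c - c.mean()
            denom = np.sqrt((cc**2).sum() * ss_tot)
            with np.errstate(divide="ignore", invalid="ignore"):
                r = (cc @ Rc) / denom
                r = np.clip(r, -1.0, 1.0)
                t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
                ps = 2.0 * stats.t.sf(np.abs(t), n - 2)
        for name, p in zip(names, ps):
            if np.isnan(p):
                continue
            detail[name][cname] = float(p)
            pvals.append(float(p))
    if not pvals:
        return 1.0, detail, True
    return float(np.mean(pvals)), detail, False


def predictive_relevance(
    donor: SurveyTable, spec: FusionSpec, warn_below: float = 0.1
) -> pd.DataFrame:
    """Explanatory power of the common block for each specific variable.

    Valid matching requires the commons to account for all systematic
    variability of the specifics.  Reports R-squared (continuous) or
    McFadden's pseudo-R-squared (categorical) of Y ~ X on the donor file and
    flags weakly predicted variables.
    """
    schema_map = check_schema_set(donor.schema)
    X, _ = indicator_matrix(donor.df, list(spec.common_names), schema_map)
    X = np.column_stack([np.ones(len(X)), X])
    rows = []
    for name in spec.specific_names:
        var = donor.variable(name)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if var.is_categorical:
                levels = [l for l in var.levels if (donor.df[name] == l).any()]
                codes = pd.Categorical(donor.df[name], categories=levels).codes
                if len(levels) < 2:
                    power = 0.0
                else:
                    model = sm.Logit if len(levels) == 2 else sm.MNLogit
                    try:
                        res = model(codes, X).fit(disp=0, maxiter=200)
                        power = float(1.0 - res.llf / res.llnull)
                    except Exception:
                        power = np.nan
                kind = "pseudo_r2"
            else:
                res = sm.OLS(donor.df[name].to_numpy(dtype=float), X).fit()
                power = float(res.rsquared)
                kind = "r2"
        rows.append(
            {"variable": name, "measure": kind, "power": power,
             "weak": bool(power < warn_below) if np.isfinite(power) else True}
        )
    return pd.DataFrame(rows).set_index("variable")


def validate_fusion(
    observed: SurveyTable, imputed: SurveyTable, spec: FusionSpec
) -> ValidationReport:
    """Assemble the full eight-statistic report for one imputation.

    ``observed`` is the donor file with its true specific block; ``imputed``
    is the same file with the specific block re-imputed from the common
    block.  Rows are paired by identifier.
    """
    if not observed.df.index.equals(imputed.df.index):
        imputed = imputed.take(observed.df.index)
    aslm, asls, d_asl = marginal_asl(observed, imputed, spec)
    acdi, acde, d_acd = correlation_discrepancy(observed, imputed, spec)
    wc = multivariate_congruence(observed, imputed, spec)
    asd, d_asd = distribution_similarity(observed, imputed, spec)
    tau, d_tau = imputation_accuracy(observed, imputed, spec)
    rnd, d_rnd, rnd_degenerate = residual_randomness(observed, imputed, spec)
    report = ValidationReport(
        statistics={
            "ASLm": aslm, "ASLs": asls, "ACDi": acdi, "ACDe": acde,
            "WC": wc, "ASD": asd, "TAU": tau, "RndRes": rnd,
        },
        detail={
            "ASL": d_asl, "ACD": d_acd, "ASD": d_asd, "TAU": d_tau, "RndRes": d_rnd,
        },
    )
    if rnd_degenerate:
        report.degenerate.append("RndRes")
    return report
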