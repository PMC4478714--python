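"""Sequential (chained) regression imputation.

Each specific variable gets a submodel — linear for continuous outcomes,
binary or multicategory logistic for categorical ones — whose predictors are
common variables or *earlier* outcomes in the chain; derived variables (such
as body-mass index) are computed by formula, never fitted.  Candidate
predictor sets are supplied per submodel and pruned by backward elimination
at a configurable significance level, with a forced-in list for terms that
must stay on subject-matter grounds.

Imputation walks the chain: continuous outcomes are drawn as fitted mean
plus a normal residual draw, categorical outcomes from the fitted category
probabilities.  With ``draw_parameters=True`` the coefficients are first
perturbed by a draw from their estimated sampling distribution (residual
variance from its scaled chi-square posterior, coefficients from the normal
approximation), which is what makes repeated runs *proper* multiple
imputations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from ..design import build_design
from ..schema import (
    FusionSpec,
    SchemaError,
    SurveyDataError,
    SurveyTable,
    check_schema_set,
)


@dataclass
class SubmodelSpec:
    """Specification of one link in the chain.

    ``kind`` is inferred from the outcome schema when ``'auto'``:
    linear for continuous, logistic for two-level and multinomial for
    multi-level categoricals.  ``derive`` marks a deterministic variable
    computed from already-imputed columns.
    """

    name: str
    candidates: tuple[str, ...] = ()
    kind: str = "auto"
    forced: tuple[str, ...] = ()
    derive: Callable[[pd.DataFrame], np.ndarray] | None = None

    def __post_init__(self):
        self.candidates = tuple(self.candidates)
        self.forced = tuple(self.forced)
        if self.derive is not None:
            self.kind = "derived"
        if self.kind not in ("auto", "linear", "logistic", "multinomial", "derived"):
            raise SchemaError(f"submodel {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "derived" and self.derive is None:
            raise SchemaError(f"derived submodel {self.name!r} needs a derive function")
        if self.kind != "derived" and not self.candidates:
            raise SchemaError(f"submodel {self.name!r} has an empty candidate set")


@dataclass
class FittedSubmodel:
    spec: SubmodelSpec
    kind: str
    terms: list[str] = field(default_factory=list)
    colnames: list[str] = field(default_factory=list)
    params: np.ndarray | None = None       # flat coefficient vector
    cov_params: np.ndarray | None = None
    sigma: float | None = None             # residual SD (linear only)
    df_resid: float | None = None
    levels: tuple[str, ...] = ()           # outcome levels (categorical only)
    n_obs: int = 0

    @property
    def coef(self) -> pd.Series | pd.DataFrame:
        if self.kind == "multinomial":
            k = len(self.colnames)
            mat = self.params.reshape(-1, k).T  # (k_exog, K-1), equation-major
            return pd.DataFrame(mat, index=self.colnames, columns=list(self.levels[1:]))
        return pd.Series(self.params, index=self.colnames)

    @property
    def bse(self) -> pd.Series:
        se = np.sqrt(np.diag(self.cov_params))
        if self.kind == "multinomial":
            k = len(self.colnames)
            return pd.DataFrame(
                se.reshape(-1, k).T, index=self.colnames, columns=list(self.levels[1:])
            )
        return pd.Series(se, index=self.colnames)


def _robust_mle(model) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood fit with a quasi-separation fallback.

    Near-separated logistic outcomes make the Newton step singular; fall
    back to BFGS and a pseudo-inverse of the Hessian (with a small ridge)
    so the chain keeps a usable, if diffuse, sampling covariance.
    """
    try:
        res = model.fit(disp=0, maxiter=200)
        params = np.asarray(res.params).ravel(order="F")
        cov = np.asarray(res.cov_params())
        if np.all(np.isfinite(cov)) and np.all(np.isfinite(params)):
            return params, cov
    except (np.linalg.LinAlgError, ValueError, RuntimeError):
        pass
    res = model.fit(disp=0, maxiter=500, method="bfgs")
    params = np.asarray(res.params).ravel(order="F")
    H = model.hessian(res.params)
    cov = np.linalg.pinv(-H + 1e-6 * np.eye(len(params)))
    if not np.all(np.isfinite(cov)):
        raise np.linalg.LinAlgError("non-finite sampling covariance")
    return params, (cov + cov.T) / 2.0


def _term_pvalue(fitted: FittedSubmodel, idx: list[int]) -> float:
    """Wald test that all coefficients of one term group are zero."""
    b = fitted.params[idx]
    C = fitted.cov_params[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(C, b))
    except np.linalg.LinAlgError:
        return 1.0
    q = len(idx)
    if fitted.kind == "linear":
        return float(stats.f.sf(stat / q, q, fitted.df_resid))
    return float(stats.chi2.sf(stat, q))


class SequentialRegression:
    """Model object: fit a chain of regression submodels on the donor file.

    Parameters
    ----------
    donor : SurveyTable
    spec : FusionSpec
    scheme : sequence of SubmodelSpec, optional
        Submodel order and candidate predictors; by default one submodel per
        specific variable (in spec order) with every common variable as a
        candidate.  The order must be topological: each candidate is a
        common variable or an earlier outcome.
    alpha : float
        Significance level for backward elimination (0.05 by default).
    selection : bool
        Disable to keep every candidate term.
    min_rows_per_param : int
        Guard demanding at least this many donor rows per fitted parameter.
    """

    def __init__(self, donor, spec, scheme=None, alpha=0.05, selection=True,
                 min_rows_per_param=10):
        spec.validate_against(donor.schema)
        self.donor = donor
        self.spec = spec
        self.alpha = float(alpha)
        self.selection = bool(selection)
        self.min_rows_per_param = int(min_rows_per_param)
        self.schema_map = check_schema_set(donor.schema)
        if scheme is None:
            scheme = [
                SubmodelSpec(name, tuple(spec.common_names))
                for name in spec.specific_names
            ]
        self.scheme = list(scheme)
        self._check_order()

    def _check_order(self) -> None:
        covered = [s.name for s in self.scheme]
        if sorted(covered) != sorted(set(covered)):
            raise SchemaError("scheme lists a variable more than once")
        missing = set(self.spec.specific_names) - set(covered)
        if missing:
            raise SchemaError(f"scheme does not cover specific variables {sorted(missing)}")
        available = set(self.spec.common_names)
        for sub in self.scheme:
            for term in sub.candidates:
                for part in term.split(":"):
                    if part not in available:
                        raise SchemaError(
                            f"submodel {sub.name!r}: predictor {part!r} is not a common "
                            f"variable or an earlier outcome (chain-order violation)"
                        )
            available.add(sub.name)

    def _resolve_kind(self, sub: SubmodelSpec) -> str:
        if sub.kind != "auto":
            return sub.kind
        var = self.schema_map.get(sub.name)
        if var is None or not var.is_categorical:
            return "linear"
        return "logistic" if len(var.levels) == 2 else "multinomial"

    def _fit_one(self, sub: SubmodelSpec, df: pd.DataFrame) -> FittedSubmodel:
        kind = self._resolve_kind(sub)
        terms = list(sub.candidates)
        y_raw = df[sub.name]
        var = self.schema_map.get(sub.name)
        if kind in ("logistic", "multinomial"):
            observed = tuple(lev for lev in var.levels if (y_raw == lev).any())
            if len(observed) < 2:
                raise SurveyDataError(
                    f"submodel {sub.name!r}: outcome has a single observed level "
                    f"{observed!r}"
                )
            levels = observed
            if kind == "multinomial" and len(observed) == 2:
                kind = "logistic"
        while True:
            X, colnames, spans = build_design(df, terms, self.schema_map)
            if len(df) < self.min_rows_per_param * X.shape[1]:
                raise ValueError(
                    f"submodel {sub.name!r}: {len(df)} donor rows for {X.shape[1]} "
                    f"parameters (guard: {self.min_rows_per_param} rows/parameter)"
                )
            fitted = FittedSubmodel(sub, kind, terms, colnames, n_obs=len(df))
            try:
                with warnings.catch_warnings(), np.errstate(all="ignore"):
                    warnings.simplefilter("ignore")
                    if kind == "linear":
                        res = sm.OLS(y_raw.to_numpy(dtype=float), X).fit()
                        fitted.params = res.params
                        fitted.cov_params = np.asarray(res.cov_params())
                        fitted.sigma = float(np.sqrt(res.mse_resid))
                        fitted.df_resid = float(res.df_resid)
                    elif kind == "logistic":
                        y = (y_raw == levels[1]).to_numpy(dtype=float)
                        params, cov = _robust_mle(sm.Logit(y, X))
                        fitted.params = params
                        fitted.cov_params = cov
                        fitted.levels = levels
                    else:
                        codes = pd.Categorical(y_raw, categories=levels).codes
                        params, cov = _robust_mle(sm.MNLogit(codes, X))
                        # flat coefficients are equation-major, matching the
                        # covariance ordering
                        fitted.params = params
                        fitted.cov_params = cov
                        fitted.levels = levels
            except (np.linalg.LinAlgError, ValueError) as exc:
                raise ValueError(
                    f"submodel {sub.name!r} failed to fit with terms {terms}: {exc}"
                ) from exc
            if kind != "linear":
                fitted.levels = levels
            if not self.selection:
                return fitted
            droppable = [t for t in terms if t not in sub.forced]
            if not droppable:
                return fitted
            if fitted.kind == "multinomial":
                k = len(colnames)
                n_eq = len(levels) - 1
                pvals = {
                    t: _term_pvalue(
                        fitted,
                        [j * k + i for j in range(n_eq) for i in spans[t]],
                    )
                    for t in droppable
                }
            else:
                pvals = {t: _term_pvalue(fitted, spans[t]) for t in droppable}
            worst = max(pvals, key=pvals.get)
            if pvals[worst] <= self.alpha:
                return fitted
            # drop the least significant term; an empty list falls back to an
            # intercept-only model on the next pass
            terms = [t for t in terms if t != worst]

    def fit(self) -> "SequentialRegressionResults":
        df = self.donor.df
        if not self.donor.is_complete(self.spec.specific_names):
            raise SurveyDataError("donor file has missing specific values")
        submodels: dict[str, FittedSubmodel] = {}
        for sub in self.scheme:
            if sub.derive is not None:
                submodels[sub.name] = FittedSubmodel(sub, "derived")
                continue
            submodels[sub.name] = self._fit_one(sub, df)
        return SequentialRegressionResults(self, submodels)


class SequentialRegressionResults:
    """Fitted chain; exposes per-submodel estimates and :meth:`impute`."""

    method = "sequential_regression"

    def __init__(self, model: SequentialRegression, submodels: dict[str, FittedSubmodel]):
        self.model = model
        self.submodels_ = submodels

    def summary(self) -> str:
        lines = ["Sequential regression chain", "=" * 60]
        for name, fitted in self.submodels_.items():
            lines.append(f"\n[{fitted.kind}] {name} (n={fitted.n_obs})")
            if fitted.kind == "derived":
                lines.append("  derived by formula")
                continue
            coef, bse = fitted.coef, fitted.bse
            if isinstance(coef, pd.DataFrame):
                lines.append(coef.round(4).to_string())
            else:
                tab = pd.DataFrame({"coef": coef, "se": bse})
                if fitted.sigma is not None:
                    lines.append(f"  residual SD: {fitted.sigma:.4f}")
                lines.append(tab.round(4).to_string())
        return "\n".join(lines)

    def _draw_params(self, fitted: FittedSubmodel, rng: np.random.Generator):
        """Posterior-style draw of (coefficients, residual SD)."""
        if fitted.kind == "linear":
            df = fitted.df_resid
            sigma2_star = fitted.sigma**2 * df / rng.chisquare(df)
            scale = sigma2_star / fitted.sigma**2
            cov = fitted.cov_params * scale
        else:
            sigma2_star = None
            cov = fitted.cov_params
        try:
            L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(cov + 1e-6 * np.eye(len(cov)))
        beta = fitted.params + L @ rng.standard_normal(len(cov))
        sd = np.sqrt(sigma2_star) if sigma2_star is not None else None
        return beta, sd

    def impute(
        self,
        recipient: SurveyTable,
        seed: int = 0,
        draw_parameters: bool = False,
    ) -> SurveyTable:
        """Walk the chain and stochastically complete the recipient file."""
        m = self.model
        rng = np.random.default_rng(seed)
        work = recipient.df.copy()
        for sub in m.scheme:
            fitted = self.submodels_[sub.name]
            if fitted.kind == "derived":
                work[sub.name] = np.asarray(sub.derive(work), dtype=float)
                continue
            var = m.schema_map.get(sub.name)
            if var is not None and var.is_categorical:
                for term in fitted.terms:
                    for part in term.split(":"):
                        pv = m.schema_map.get(part)
                        if pv is not None and pv.is_categorical:
                            extra = set(work[part].dropna()) - set(pv.levels)
                            if extra:
                                raise SurveyDataError(
                                    f"recipient values {sorted(extra)} outside design "
                                    f"levels of {part!r}"
                                )
            X, _, _ = build_design(work, fitted.terms, m.schema_map)
            if draw_parameters:
                beta, sigma = self._draw_params(fitted, rng)
            else:
                beta, sigma = fitted.params, fitted.sigma
            if fitted.kind == "linear":
                mean = X @ beta
                work[sub.name] = mean + rng.normal(0.0, sigma, len(work))
            elif fitted.kind == "logistic":
                p = expit(X @ beta)
                draw = rng.random(len(work)) < p
                work[sub.name] = np.where(draw, fitted.levels[1], fitted.levels[0])
                work[sub.name] = work[sub.name].astype(object)
            else:
                k = X.shape[1]
                mat = beta.reshape(-1, k)           # (K-1, k_exog)
                eta = np.column_stack([np.zeros(len(work)), X @ mat.T])
                eta -= eta.max(axis=1, keepdims=True)
                p = np.exp(eta)
                p /= p.sum(axis=1, keepdims=True)
                u = rng.random(len(work))[:, None]
                idx = (u > np.cumsum(p, axis=1)).sum(axis=1)
                work[sub.name] = np.asarray(fitted.levels, dtype=object)[idx]
        return SurveyTable(work, recipient.schema, check=False)
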