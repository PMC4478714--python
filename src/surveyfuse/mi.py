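"""Multiple imputation and Rubin-style variance pooling.

A single stochastic imputation understates uncertainty: imputed values are
estimates, and the model parameters behind them are themselves estimated.
Repeating the imputation m times and pooling per-imputation estimates
separates the *within* variability W (average sampling variance, driven by
sample size) from the *between* variability B (spread across imputations,
driven by imputation uncertainty), combined as T = W + (1 + 1/m) B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .imputers import DataAugmentation, KNNHotDeck, SequentialRegression
from .schema import FusionSpec, SurveyTable


@dataclass
class MultiImputation:
    """m completed recipient tables from repeated stochastic imputation."""

    tables: list[SurveyTable]
    method: str
    master_seed: int
    seeds: tuple[int, ...]

    def __post_init__(self):
        if len(self.tables) < 2:
            raise ValueError("multiple imputation needs m >= 2 completed tables")
        index = self.tables[0].df.index
        for t in self.tables[1:]:
            if not t.df.index.equals(index):
                raise ValueError("completed tables must share row identifiers")

    @property
    def m(self) -> int:
        return len(self.tables)

    def concatenated(self) -> pd.DataFrame:
        """Stacked export of the m completions (an ``_imputation`` column
        identifies the draw).  Offered for convenience; pooled per-imputation
        inference is the default analysis route."""
        frames = []
        for i, t in enumerate(self.tables):
            df = t.df.copy()
            df.insert(0, "_imputation", i)
            frames.append(df)
        return pd.concat(frames, axis=0)


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin-combined estimate with within/between/total variance."""

    qbar: float
    W: float
    B: float
    m: int
    T: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        if self.W < 0 or self.B < 0:
            raise ValueError("variance components must be non-negative")
        object.__setattr__(self, "T", self.W + (1.0 + 1.0 / self.m) * self.B)
        object.__setattr__(self, "sd", float(np.sqrt(self.T)))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy import stats

        z = stats.norm.ppf(0.5 + level / 2.0)
        return self.qbar - z * self.sd, self.qbar + z * self.sd


def pool_estimates(
    estimates: Sequence[float], variances: Sequence[float]
) -> PooledEstimate:
    """Combine m per-imputation point estimates and sampling variances.

    qbar = mean estimate, W = mean variance, B = sample variance of the
    estimates (divisor m-1), T = W + (1 + 1/m) B.
    """
    q = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if q.shape != v.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length vectors")
    m = len(q)
    if m < 2:
        raise ValueError("pooling needs m >= 2 imputations")
    if (v < 0).any():
        raise ValueError("negative sampling variance")
    return PooledEstimate(
        qbar=float(q.mean()), W=float(v.mean()), B=float(q.var(ddof=1)), m=m
    )


def multiply_impute(
    method: str,
    donor: SurveyTable,
    recipient: SurveyTable,
    spec: FusionSpec,
    m: int = 20,
    seed: int = 0,
    **settings,
) -> MultiImputation:
    """Repeat one engine m times with independent per-imputation seeds.

    ``method`` is ``'knn'`` (fresh uniform draw among the k nearest, default
    k=10), ``'sqreg'`` (parameter draws enabled — proper MI) or ``'da'``
    (m spaced draws of one chain).  Deterministic given the master seed.
    """
    if m < 2:
        raise ValueError("multiple imputation needs m >= 2; use an engine "
                         "directly for single imputation")
    ss = np.random.SeedSequence(seed)
    seeds = tuple(int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(m))
    tables: list[SurveyTable] = []
    if method == "knn":
        k = settings.pop("k", 10)
        res = KNNHotDeck(donor, spec, k=k, **settings).fit()
        for i, s in enumerate(seeds):
            try:
                tables.append(res.impute(recipient, seed=s))
            except Exception as exc:
                raise RuntimeError(f"imputation {i} failed: {exc}") from exc
    elif method == "sqreg":
        res = SequentialRegression(donor, spec, **settings).fit()
        for i, s in enumerate(seeds):
            try:
                tables.append(res.impute(recipient, seed=s, draw_parameters=True))
            except Exception as exc:
                raise RuntimeError(f"imputation {i} failed: {exc}") from exc
    elif method == "da":
        burn_in = settings.pop("burn_in", 500)
        spacing = settings.pop("spacing", 100)
        res = DataAugmentation(donor, spec, **settings).fit()
        tables = res.impute(
            recipient, burn_in=burn_in, n_draws=m, spacing=spacing, seed=seeds[0]
        )
    else:
        raise ValueError(f"unknown method {method!r} (expected knn, sqreg or da)")
    return MultiImputation(tables=tables, method=method, master_seed=seed, seeds=seeds)


def pool_proportion(
    multi: MultiImputation,
    column: str,
    positive_level: str = "Yes",
    extra: pd.Series | None = None,
) -> PooledEstimate:
    """Pool a proportion across completed tables (binomial within-variance).

    ``extra`` optionally appends fully observed rows (e.g. the donor file's
    own values) to every completed table before the proportion is taken.
    """
    estimates, variances = [], []
    for t in multi.tables:
        vals = t.df[column]
        if extra is not None:
            vals = pd.concat([vals, extra])
        p = float((vals == positive_level).mean())
        n = len(vals)
        estimates.append(p)
        variances.append(p * (1.0 - p) / n)
    return pool_estimates(estimates, variances)
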