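"""Bootstrap comparison of imputation methods.

The experiment re-imputes the *donor* file (whose specific block is known)
across bootstrap resamples and records the distribution of the eight
validation statistics for each method, in single-imputation and
multiple-imputation mode.  Comparing those distributions — both their mean
and their spread — reveals each engine's profile: which preserves marginals,
which is most accurate, which keeps the multivariate structure.

Because validation is performed on donors only, the recipient file never
enters any statistic; each iteration resamples the donor file with
replacement, fits every engine on the resample, and re-imputes the original
donors' specific block from their common block (the bootstrap captures the
fitting variability of each engine).  The hot deck never lets a unit donate
to itself (bootstrap copies of the same unit are excluded as donors for it)
— without that rule nearest-neighbour validation is trivially perfect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imputers import DataAugmentation, KNNHotDeck, SequentialRegression
from .schema import FusionSpec, SurveyTable
from .validation import STAT_ORDER, STAT_ORIENTATION, validate_fusion

SINGLE_METHODS = ("1nn", "sqreg", "da")
MI_METHODS = ("mi-knn", "mi-sqreg", "mi-da")
ALL_METHODS = SINGLE_METHODS + MI_METHODS


@dataclass
class ComparisonResult:
    """Per (method, statistic) vectors of bootstrap values."""

    values: dict[str, dict[str, np.ndarray]]
    n_boot: int
    m: int
    seed: int
    n_rejected: int = 0
    settings: dict = field(default_factory=dict)

    @property
    def methods(self) -> list[str]:
        return list(self.values)

    def summary(self) -> pd.DataFrame:
        rows = []
        for method, stats_ in self.values.items():
            for stat, vec in stats_.items():
                rows.append(
                    {
                        "method": method,
                        "statistic": stat,
                        "mean": float(np.mean(vec)),
                        "sd": float(np.std(vec, ddof=1)) if len(vec) > 1 else 0.0,
                        "q05": float(np.quantile(vec, 0.05)),
                        "q95": float(np.quantile(vec, 0.95)),
                    }
                )
        return pd.DataFrame(rows)

    def long_frame(self) -> pd.DataFrame:
        rows = []
        for method, stats_ in self.values.items():
            for stat, vec in stats_.items():
                for i, v in enumerate(vec):
                    rows.append(
                        {"method": method, "statistic": stat, "iteration": i,
                         "value": float(v)}
                    )
        return pd.DataFrame(rows)


def _mask_specific(table: SurveyTable, spec: FusionSpec) -> SurveyTable:
    df = table.df.copy()
    df[list(spec.specific_names)] = np.nan
    return SurveyTable(df, table.schema, check=False)


def _bootstrap_table(
    table: SurveyTable, rng: np.random.Generator
) -> tuple[SurveyTable, np.ndarray]:
    """Resample rows with replacement; returns the resample plus the origin
    identifier of every resampled row (used for leave-own-record-out knn)."""
    idx = rng.integers(0, table.n, table.n)
    df = table.df.iloc[idx].reset_index(drop=True)
    return SurveyTable(df, table.schema, check=False), np.asarray(table.df.index[idx])


def _iteration(
    donor: SurveyTable,
    donor_boot: SurveyTable,
    boot_origin: np.ndarray,
    spec: FusionSpec,
    methods: tuple[str, ...],
    m: int,
    rng: np.random.Generator,
    settings: dict,
) -> dict[str, pd.Series]:
    """Fit every engine on the bootstrap donor resample, then re-impute the
    original donor file's specific block and compare with its actual
    values.  Hot-deck imputation excludes a unit's bootstrap copies as
    donors to itself (a unit must never donate to itself, or
    nearest-neighbour validation is trivially perfect)."""
    observed = donor
    masked = _mask_specific(donor, spec)
    rec_origin = np.asarray(donor.df.index)
    out: dict[str, pd.Series] = {}

    def seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    knn_cfg = dict(settings.get("knn", {}))
    sq_cfg = dict(settings.get("sqreg", {}))
    da_cfg = dict(settings.get("da", {}))
    mi_k = knn_cfg.pop("k", 10)
    burn_in = da_cfg.pop("burn_in", 100)
    spacing = da_cfg.pop("spacing", 20)

    sq_res = None
    if "sqreg" in methods or "mi-sqreg" in methods:
        sq_res = SequentialRegression(donor_boot, spec, **sq_cfg).fit()
    da_res = None
    if "da" in methods or "mi-da" in methods:
        da_res = DataAugmentation(donor_boot, spec, **da_cfg).fit()

    for method in methods:
        if method == "1nn":
            res = KNNHotDeck(
                donor_boot, spec, k=1, origin=boot_origin, **knn_cfg
            ).fit()
            imp = res.impute(masked, seed(), exclude_origin=rec_origin)
            out[method] = validate_fusion(observed, imp, spec).as_series()
        elif method == "sqreg":
            rep = validate_fusion(observed, sq_res.impute(masked, seed()), spec)
            out[method] = rep.as_series()
        elif method == "da":
            (completed,) = da_res.impute(
                masked, burn_in=burn_in, n_draws=1, spacing=spacing, seed=seed()
            )
            out[method] = validate_fusion(observed, completed, spec).as_series()
        elif method == "mi-knn":
            res = KNNHotDeck(
                donor_boot, spec, k=mi_k, origin=boot_origin, **knn_cfg
            ).fit()
            reps = [
                validate_fusion(
                    observed, res.impute(masked, seed(), exclude_origin=rec_origin),
                    spec,
                ).as_series()
                for _ in range(m)
            ]
            out[method] = pd.concat(reps, axis=1).mean(axis=1)
        elif method == "mi-sqreg":
            reps = [
                validate_fusion(
                    observed,
                    sq_res.impute(masked, seed(), draw_parameters=True),
                    spec,
                ).as_series()
                for _ in range(m)
            ]
            out[method] = pd.concat(reps, axis=1).mean(axis=1)
        elif method == "mi-da":
            completed = da_res.impute(
                masked, burn_in=burn_in, n_draws=m, spacing=spacing, seed=seed()
            )
            reps = [validate_fusion(observed, c, spec).as_series() for c in completed]
            out[method] = pd.concat(reps, axis=1).mean(axis=1)
        else:
            raise ValueError(f"unknown method {method!r}")
    return out


def run_comparison(
    donor: SurveyTable,
    recipient: SurveyTable | None,
    spec: FusionSpec,
    methods: tuple[str, ...] = ALL_METHODS,
    n_boot: int = 400,
    m: int = 20,
    seed: int = 0,
    settings: dict | None = None,
    max_retries: int = 20,
) -> ComparisonResult:
    """Run the full bootstrap x method x {single, MI} experiment.

    Each iteration resamples the donor file with replacement, fits every
    requested engine on the resample, imputes the resample's own specific
    block from its common block, and computes the validation statistics
    (averaged over the m completed sets for MI methods).  Degenerate
    resamples — e.g. a categorical outcome level vanishing — are rejected
    and redrawn; the count is reported.  Fully reproducible from the master
    seed.
    """
    if not methods:
        raise ValueError("method list is empty")
    if donor.n == 0:
        raise ValueError("donor file is empty")
    if any(mm in MI_METHODS for mm in methods) and m < 2:
        raise ValueError("MI methods need m >= 2")
    settings = settings or {}
    ss = np.random.SeedSequence(seed)
    store: dict[str, dict[str, list[float]]] = {
        method: {stat: [] for stat in STAT_ORDER} for method in methods
    }
    rejected = 0
    for child in ss.spawn(n_boot):
        rng = np.random.default_rng(child)
        for attempt in range(max_retries):
            donor_boot, boot_origin = _bootstrap_table(donor, rng)
            try:
                res = _iteration(
                    donor, donor_boot, boot_origin, spec, tuple(methods), m, rng,
                    settings,
                )
                break
            except Exception:
                rejected += 1
        else:
            raise RuntimeError(
                f"bootstrap iteration failed {max_retries} times in a row; "
                f"the donor file is too degenerate for the requested engines"
            )
        for method, series in res.items():
            for stat in STAT_ORDER:
                store[method][stat].append(float(series[stat]))
    values = {
        method: {stat: np.asarray(v) for stat, v in stats_.items()}
        for method, stats_ in store.items()
    }
    return ComparisonResult(
        values=values, n_boot=n_boot, m=m, seed=seed, n_rejected=rejected,
        settings=settings,
    )


def rank_methods(
    result: ComparisonResult, preferences: dict[str, str] | None = None
) -> pd.DataFrame:
    """Rank methods per statistic by mean value, respecting orientation.

    Returns a DataFrame indexed by method with one rank column per statistic
    (1 = best) plus the bootstrap SD of each statistic as stability columns
    and a ``mean_rank`` aggregate.
    """
    prefs = dict(STAT_ORIENTATION)
    if preferences:
        prefs.update(preferences)
    stats_present = {s for v in result.values.values() for s in v}
    missing = stats_present - set(prefs)
    if missing:
        raise ValueError(f"orientation missing for statistics {sorted(missing)}")
    means = pd.DataFrame(
        {
            method: {stat: float(np.mean(vec)) for stat, vec in stats_.items()}
            for method, stats_ in result.values.items()
        }
    ).T
    sds = pd.DataFrame(
        {
            method: {
                f"sd_{stat}": float(np.std(vec, ddof=1)) if len(vec) > 1 else 0.0
                for stat, vec in stats_.items()
            }
            for method, stats_ in result.values.items()
        }
    ).T
    ranks = pd.DataFrame(index=means.index)
    for stat in means.columns:
        ascending = prefs[stat] == "lower"
        ranks[stat] = means[stat].rank(ascending=ascending, method="average")
    ranks["mean_rank"] = ranks.mean(axis=1)
    return pd.concat([ranks, sds], axis=1).sort_values("mean_rank")


_LINE_STYLES = {
    "mi-da": "-",
    "da": (0, (8, 2)),
    "mi-sqreg": (0, (6, 2, 1, 2)),
    "sqreg": "--",
    "mi-knn": "-.",
    "1nn": ":",
}


def plot_densities(result: ComparisonResult, path) -> str:
    """One panel per statistic, one density curve per method (Gaussian KDE)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats as sps

    fig, axes = plt.subplots(2, 4, figsize=(16, 7))
    for ax, stat in zip(axes.ravel(), STAT_ORDER):
        for method in result.methods:
            vec = result.values[method].get(stat)
            if vec is None or len(vec) < 2 or np.std(vec) == 0:
                ax.annotate(f"{method}: omitted", xy=(0.02, 0.95),
                            xycoords="axes fraction", fontsize=6, va="top")
                continue
            grid = np.linspace(vec.min(), vec.max(), 200)
            kde = sps.gaussian_kde(vec)
            ax.plot(grid, kde(grid), label=method,
                    linestyle=_LINE_STYLES.get(method, "-"))
        ax.set_title(stat)
    handles, labels = axes.ravel()[0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels, loc="lower center", ncol=len(labels))
    fig.tight_layout(rect=(0, 0.06, 1, 1))
    out = str(path)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
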