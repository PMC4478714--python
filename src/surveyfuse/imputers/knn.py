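"""Distance hot-deck (k-nearest-neighbour) imputation.

Each recipient is matched to donors in common-variable space with a
Gower-type mixed distance: range-normalised absolute difference for
continuous variables, simple mismatch for categoricals, averaged with
configurable weights.  The entire specific block of one donor is then
transferred, preserving within-donor associations — a random draw from the
empirical conditional distribution.  With ``class_vars`` the match is
restricted to donors in the recipient's class (distance hot deck within
classes); every recipient class must be present among donors.

When donors are re-imputed to validate a fusion, a unit must not donate to
itself; ``impute(..., exclude_origin=...)`` implements that
leave-own-record-out rule via origin identifiers that survive bootstrap
resampling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..schema import FusionSpec, SchemaError, SurveyDataError, SurveyTable

_EXCLUDED = 1e9  # distance sentinel for forbidden donor/recipient pairs


class KNNHotDeck:
    """Model object for hot-deck imputation.

    Parameters
    ----------
    donor : SurveyTable
        Complete donor file.
    spec : FusionSpec
        X/Y partition.
    k : int
        Neighbour count; ``k=1`` is the classical nearest-neighbour hot deck,
        ``k>1`` draws uniformly among the k nearest (a fresh draw per
        imputation — the multiple-imputation variant).
    class_vars : list of common categorical names, optional
        Exact-match class restriction before the distance search.
    weights : mapping name -> float, optional
        Per-variable distance weights (default equal).
    origin : sequence, optional
        Origin identifier per donor row (defaults to the row index); used by
        ``exclude_origin`` at imputation time.
    """

    def __init__(self, donor, spec, k=1, class_vars=None, weights=None, origin=None):
        spec.validate_against(donor.schema)
        if k < 1:
            raise ValueError("k must be >= 1")
        if not donor.is_complete(spec.specific_names):
            raise SurveyDataError("donor file has missing specific values")
        self.donor = donor
        self.spec = spec
        self.k = int(k)
        self.origin = np.asarray(origin if origin is not None else donor.df.index)
        if len(self.origin) != donor.n:
            raise ValueError("origin must have one entry per donor row")
        self.class_vars = tuple(class_vars or ())
        for name in self.class_vars:
            var = donor.variable(name)
            if not var.is_categorical or name not in spec.common_names:
                raise SchemaError(f"class variable {name!r} must be a common categorical")
        self.match_vars = [
            name for name in spec.common_names if name not in self.class_vars
        ]
        self.weights = {name: 1.0 for name in self.match_vars}
        if weights:
            self.weights.update({k_: float(v) for k_, v in weights.items()})

    def fit(self) -> "KNNHotDeckResults":
        donor_df = self.donor.df
        ranges = {}
        for name in self.match_vars:
            if not self.donor.variable(name).is_categorical:
                lo, hi = float(donor_df[name].min()), float(donor_df[name].max())
                ranges[name] = max(hi - lo, 1e-12)
        if self.class_vars:
            counts = donor_df.groupby(list(self.class_vars), observed=True).size()
            too_small = counts[counts < self.k]
            if len(too_small):
                raise ValueError(
                    f"k={self.k} exceeds donor count in classes "
                    f"{list(too_small.index)}"
                )
        elif self.k > self.donor.n:
            raise ValueError(f"k={self.k} exceeds donor size {self.donor.n}")
        return KNNHotDeckResults(self, ranges)


class KNNHotDeckResults:
    """Fitted hot-deck rule; call :meth:`impute` on a recipient file."""

    method = "knn_hotdeck"

    def __init__(self, model: KNNHotDeck, ranges: dict[str, float]):
        self.model = model
        self.ranges = ranges
        self.donor_assignment_: pd.Series | None = None

    def _distances(self, rec_df: pd.DataFrame, donor_df: pd.DataFrame) -> np.ndarray:
        """Gower distance matrix (recipients x donors)."""
        m = self.model
        n1, n0 = len(rec_df), len(donor_df)
        total = np.zeros((n1, n0))
        wsum = 0.0
        for name in m.match_vars:
            w = m.weights[name]
            wsum += w
            if m.donor.variable(name).is_categorical:
                r = rec_df[name].to_numpy()[:, None]
                d = donor_df[name].to_numpy()[None, :]
                total += w * (r != d)
            else:
                r = rec_df[name].to_numpy(dtype=float)[:, None]
                d = donor_df[name].to_numpy(dtype=float)[None, :]
                total += w * np.abs(r - d) / self.ranges[name]
        return total / max(wsum, 1e-12)

    def _assign_block(
        self,
        rec_df: pd.DataFrame,
        donor_rows: np.ndarray,
        rng: np.random.Generator,
        exclude_origin: np.ndarray | None,
    ) -> np.ndarray:
        """Pick one donor positional index (into the full donor file) per row."""
        m = self.model
        donor_df = m.donor.df.iloc[donor_rows]
        n0 = len(donor_rows)
        k = min(m.k, n0)
        # random donor permutation => ties at equal distance broken uniformly
        perm = rng.permutation(n0)
        donor_origin = m.origin[donor_rows][perm]
        chosen = np.empty(len(rec_df), dtype=int)
        step = max(1, int(2e6 // max(n0, 1)))
        for start in range(0, len(rec_df), step):
            chunk = rec_df.iloc[start:start + step]
            dist = self._distances(chunk, donor_df.iloc[perm])
            if exclude_origin is not None:
                excl = exclude_origin[start:start + step, None] == donor_origin[None, :]
                if excl.all(axis=1).any():
                    raise SurveyDataError("a recipient row excludes every donor")
                dist = dist + _EXCLUDED * excl
            if k == 1:
                pick = np.argmin(dist, axis=1)
            else:
                kk = min(k, n0 - 1) if exclude_origin is not None else k
                nearest = np.argpartition(dist, kk - 1, axis=1)[:, :kk]
                # order within the block is arbitrary; a uniform draw over it
                # is exactly a uniform draw among the kk nearest
                pick = nearest[np.arange(len(chunk)), rng.integers(0, kk, len(chunk))]
            chosen[start:start + step] = donor_rows[perm[pick]]
        return chosen

    def impute(
        self,
        recipient: SurveyTable,
        seed: int = 0,
        exclude_origin=None,
    ) -> SurveyTable:
        """Complete the recipient file; deterministic given ``seed``.

        ``exclude_origin`` (one identifier per recipient row) forbids donors
        sharing that origin — leave-own-record-out validation.  The donor
        row used for each recipient is recorded in ``donor_assignment_``.
        """
        m = self.model
        if recipient.n == 0:
            raise SurveyDataError("recipient table is empty")
        rng = np.random.default_rng(seed)
        donor_df = m.donor.df
        rec_df = recipient.df
        if exclude_origin is not None:
            exclude_origin = np.asarray(exclude_origin)
            if len(exclude_origin) != len(rec_df):
                raise ValueError("exclude_origin must match the recipient length")
        chosen = np.empty(len(rec_df), dtype=int)
        if m.class_vars:
            donor_keys = pd.MultiIndex.from_frame(donor_df[list(m.class_vars)])
            rec_keys = pd.MultiIndex.from_frame(rec_df[list(m.class_vars)])
            for key in rec_keys.unique():
                rmask = (rec_keys == key).nonzero()[0]
                dmask = (donor_keys == key).nonzero()[0]
                if len(dmask) == 0:
                    raise SurveyDataError(f"recipient class {key!r} has no donors")
                excl = exclude_origin[rmask] if exclude_origin is not None else None
                chosen[rmask] = self._assign_block(
                    rec_df.iloc[rmask], dmask, rng, excl
                )
        else:
            chosen = self._assign_block(
                rec_df, np.arange(len(donor_df)), rng, exclude_origin
            )

        out = rec_df.copy()
        spec_names = list(m.spec.specific_names)
        out[spec_names] = donor_df.iloc[chosen][spec_names].to_numpy()
        self.donor_assignment_ = pd.Series(
            donor_df.index[chosen], index=rec_df.index, name="donor_id"
        )
        return SurveyTable(out, recipient.schema, check=False)
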